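"""Temporal profile clustering, early-riser phosphosites, motif statistics.

Protein and phosphosite profiles are clustered with k-means on log2,
per-row mean-centred profiles (complete cases only); degradation clusters
are agglomerated by the mitotic sub-stage in which their abundance trough
occurs; phosphosites that rise already in the G2-enriched fraction and peak
in mitosis are classified as 'early risers'.  Published run configurations
used k = 12 for the mitotic protein profiles and k = 6 for the interphase
phosphosite profiles; both are parameters here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "choose_k_wss",
    "kmeans_cluster",
    "agglomerate_by_trough",
    "classify_early_risers",
    "residue_frequencies",
    "motif_match",
    "compare_early_late",
    "fisher_enrichment",
    "normalize_sites_to_protein",
    "prepare_profiles",
]

log = logging.getLogger("primmus.dynamics")

MITOTIC_ORDER = ("Pro", "PM1", "PM2", "Ana")


@dataclass(frozen=True)
class ClusterAssignment:
    k: int
    labels: pd.Series            # row -> cluster index (0-based)
    centroids: pd.DataFrame      # cluster x feature, on the clustered scale
    wss: float                   # within-groups sum of squares (inertia)
    wss_curve: dict | None = None  # k -> WSS from a selection scan


def prepare_profiles(median_matrix: pd.DataFrame, log_transform=True,
                     center=True) -> pd.DataFrame:
    """Complete-case, log2, per-row mean-centred profiles for clustering."""
    X = median_matrix.dropna(axis=0, how="any").astype(float)
    if log_transform:
        X = np.log2(X)
    if center:
        X = X.sub(X.mean(axis=1), axis=0)
    return X


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(X)
    return km


def _canonical_labels(km: KMeans) -> tuple:
    """Relabel clusters by lexicographic centroid order for determinism."""
    order = np.lexsort(km.cluster_centers_.T[::-1])
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    return remap[km.labels_], km.cluster_centers_[order]


def kmeans_cluster(profiles: pd.DataFrame, k: int, seed=0,
                   n_restarts=50) -> ClusterAssignment:
    """Best-of-restarts k-means partition of complete profile rows.

    Rows are sorted by identifier before fitting and cluster indices are
    assigned in lexicographic centroid order, so the partition is a
    deterministic function of (data, k, seed, n_restarts) and invariant to
    input row order.
    """
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles must be complete (no missing values)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds {len(profiles)} rows")
    ordered = profiles.sort_index()
    km = _fit_kmeans(ordered.to_numpy(dtype=float), k, seed, n_restarts)
    labels, centers = _canonical_labels(km)
    lab = pd.Series(labels, index=ordered.index, name="cluster").reindex(profiles.index)
    centroids = pd.DataFrame(centers, columns=profiles.columns)
    centroids.index.name = "cluster"
    return ClusterAssignment(k=k, labels=lab, centroids=centroids,
                             wss=float(km.inertia_))


def choose_k_wss(profiles: pd.DataFrame, k_range, seed=0, n_restarts=10):
    """Scan k over ``k_range`` and pick the elbow of the WSS curve.

    The elbow ('inflection point') is taken as the k with the maximum
    second difference of within-groups sum of squares — the point where
    adding a cluster stops paying.  If the data collapse to (near-)zero WSS
    for every k, k = 1 is returned.  Returns ``(k, {k: wss})``.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[-1] > len(profiles):
        raise ValueError("k_range exceeds the number of rows")
    X = profiles.sort_index().to_numpy(dtype=float)
    wss = {}
    for k in k_range:
        wss[k] = float(_fit_kmeans(X, k, seed, n_restarts).inertia_)
    scale = max(wss.values())
    if scale <= 1e-12:
        return k_range[0] if k_range[0] == 1 else 1, wss
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(k_range) - 1):
        k_prev, k, k_next = k_range[i - 1], k_range[i], k_range[i + 1]
        d2 = wss[k_prev] - 2 * wss[k] + wss[k_next]
        if d2 > best_d2:
            best_k, best_d2 = k, d2
    if best_k is None:  # fewer than 3 k values scanned
        best_k = min(wss, key=wss.get)
    return best_k, wss


def agglomerate_by_trough(assignment: ClusterAssignment,
                          median_matrix: pd.DataFrame,
                          drop_threshold=0.75) -> pd.DataFrame:
    """Group degradation clusters by the mitotic sub-stage of their trough.

    Cluster mean profiles are computed on the linear ratio scale over
    Pro/PM1/PM2/Ana.  Clusters whose maximum is not at Pro (i.e. increasing
    profiles) are removed; the rest are labelled by the earliest fraction
    whose centroid value falls below ``drop_threshold`` of the Pro value.
    Returns a per-cluster frame (group label, centroid values, member
    count); raises if no decreasing cluster exists.
    """
    fractions = [f for f in MITOTIC_ORDER if f in median_matrix.columns]
    if fractions[0] != "Pro":
        raise ValueError("profiles must include the Pro fraction")
    rows = []
    for c in range(assignment.k):
        members = assignment.labels.index[assignment.labels == c]
        centroid = median_matrix.loc[members, fractions].mean(axis=0)
        rec = {"cluster": c, "n_proteins": len(members)}
        rec.update({f"centroid_{f}": float(centroid[f]) for f in fractions})
        vals = centroid.to_numpy(dtype=float)
        if np.argmax(vals) != 0:
            rec["group"] = ""  # increasing profile, removed
        else:
            below = vals < drop_threshold * vals[0]
            if below.any():
                rec["group"] = fractions[int(np.argmax(below))]
            else:
                rec["group"] = ""  # flat, no trough
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("cluster")
    if not (out["group"] != "").any():
        raise ValueError("no decreasing clusters to agglomerate")
    return out


def classify_early_risers(site_matrix: pd.DataFrame, significant: pd.Series,
                          baseline_fractions=("G1", "S"), g2_fraction="G2",
                          peak_fraction="M", z=2.0) -> pd.Series:
    """Split mitosis-peaking phosphosites into early and late risers.

    A significant site is an *early riser* if its mean log2 G2 ratio exceeds
    the G1/S baseline mean by ``z`` baseline standard deviations (computed
    across baseline fractions and replicates) and the profile peaks in M;
    mitosis-peaking sites failing the G2 criterion are *late* risers.
    Non-significant sites are excluded; sites without a G2 value are
    flagged unclassifiable.
    """
    labels = pd.Series("excluded", index=site_matrix.index, name="riser_class")
    logm = np.log2(site_matrix.astype(float))
    for sid in site_matrix.index[significant.reindex(site_matrix.index, fill_value=False)]:
        row = logm.loc[sid]
        base = row.loc[list(baseline_fractions)].to_numpy(dtype=float)
        base = base[np.isfinite(base)]
        g2 = row.loc[g2_fraction].to_numpy(dtype=float)
        g2 = g2[np.isfinite(g2)]
        if g2.size == 0 or base.size < 2:
            labels[sid] = "unclassifiable"
            continue
        frac_means = row.groupby(level="fraction").mean()
        if frac_means.idxmax() != peak_fraction:
            labels[sid] = "excluded"
            continue
        sd = float(np.std(base, ddof=1))
        early = float(g2.mean()) > float(base.mean()) + z * sd
        labels[sid] = "early" if early else "late"
    return labels


def residue_frequencies(sites: pd.DataFrame) -> pd.Series:
    """pS/pT/pY fractions over the site table (sums to 1)."""
    counts = sites["amino_acid"].value_counts()
    bad = set(counts.index) - {"S", "T", "Y"}
    if bad:
        raise ValueError(f"non-phosphorylatable residues in table: {sorted(bad)}")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty site table")
    return pd.Series({r: counts.get(r, 0) / total for r in ("S", "T", "Y")},
                     name="frequency")


def motif_match(sequence_window: str) -> dict:
    """Kinase-motif flags for a 15-mer window centred on the phosphosite.

    ``proline_directed``: centre is S or T and position +1 is P.
    ``full_cdk_consensus``: additionally position +3 is K or R
    (the optimal CDK substrate motif [S/T]-P-x-[K/R]).
    Termini may be padded with '_'.
    """
    if not isinstance(sequence_window, str) or len(sequence_window) != 15:
        raise ValueError("sequence window must be a 15-character string")
    centre = sequence_window[7]
    proline_directed = centre in "ST" and sequence_window[8] == "P"
    full_cdk = proline_directed and sequence_window[10] in "KR"
    return {"proline_directed": proline_directed, "full_cdk_consensus": full_cdk}


def compare_early_late(site_matrix: pd.DataFrame, labels: pd.Series,
                       fraction="M") -> pd.DataFrame:
    """Mean log2 ratio in one fraction for early vs late risers, with s.e.m."""
    logm = np.log2(site_matrix.astype(float))
    rows = {}
    for group in ("early", "late"):
        ids = labels.index[labels == group]
        if len(ids) == 0:
            raise ValueError(f"empty group {group!r}")
        vals = logm.loc[ids, fraction].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        rows[group] = {
            "n_sites": len(ids),
            "mean_log2": float(np.mean(vals)),
            "sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            if vals.size > 1 else np.nan,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out.attrs["difference"] = out.loc["early", "mean_log2"] - out.loc["late", "mean_log2"]
    return out


def fisher_enrichment(candidates, background, label_sets: dict,
                      apply_fdr=False) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of labels in a candidate set.

    For each label, the 2x2 table is (in/out of candidates) x (has/lacks
    the label), with the candidate set required to be a subset of the
    background.  Odds ratios and two-sided hypergeometric p-values per
    label; optional Benjamini-Hochberg correction across labels.
    """
    cand = set(candidates)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not cand <= bg:
        raise ValueError("candidate set must be a subset of the background")
    rows = []
    for label, members in label_sets.items():
        members = set(members) & bg
        a = len(cand & members)
        b = len(cand) - a
        c = len(members) - a
        d = len(bg) - len(cand) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"label": label, "in_candidates_with_label": a,
                     "in_candidates_without": b, "in_background_with_label": c,
                     "in_background_without": d,
                     "odds_ratio": float(odds), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("label")
    if apply_fdr and len(out):
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["q_value"] = adj
    return out


def normalize_sites_to_protein(site_matrix: pd.DataFrame,
                               protein_median: pd.DataFrame,
                               site_to_protein: pd.Series):
    """Divide site ratios by the parent protein's median ratio per fraction.

    Separates phosphorylation-stoichiometry changes from protein-abundance
    changes.  Sites whose protein is absent from the matrix pass through
    unchanged and are flagged; a zero protein ratio is an input error.
    Returns ``(normalized, protein_normalized_flag)``.
    """
    out = site_matrix.copy()
    flag = pd.Series(False, index=site_matrix.index, name="protein_normalized")
    fractions = site_matrix.columns.get_level_values(0).unique()
    for sid in site_matrix.index:
        pid = site_to_protein.get(sid)
        if pid is None or pid not in protein_median.index:
            continue
        prot = protein_median.loc[pid]
        for f in fractions:
            pv = prot.get(f, np.nan)
            if not np.isfinite(pv):
                continue
            if pv == 0:
                raise ValueError(f"zero protein ratio for {pid} in {f}")
            out.loc[sid, f] = (site_matrix.loc[sid, f] / pv).to_numpy()
        flag[sid] = True
    return out, flag
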