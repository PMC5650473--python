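"""Significance screening for cell-cycle-regulated proteins.

The procedure: compute each protein's max/min fold change over the sorted
fractions (replicate-median profile, complete cases only), set a one-sided
cutoff from the fold distribution itself — median + 1.96 sample standard
deviations on the log2 scale, i.e. a ~95% confidence band — and require a
design-specific second criterion: a one-way ANOVA p < 0.05 across replicates
(interphase design) or a positive Pearson correlation between at least one
pair of replicate profiles (mitotic design).  Proteins missing reproducibly
in the same single fraction in every replicate are rescued as likely
physiological down-regulation below the detection limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionConfig",
    "max_fold_change",
    "zscore_cutoff",
    "anova_across_replicates",
    "replicate_correlation_criterion",
    "missing_value_rescue",
    "select_candidates",
]

log = logging.getLogger("primmus.selection")


@dataclass(frozen=True)
class SelectionConfig:
    design: str = "mitotic"
    z_multiplier: float = 1.96
    p_cutoff: float = 0.05
    correlation_method: str = "pearson"
    min_positive_pairs: int = 1
    require_all_pairs: bool = False
    apply_fdr: bool = False

    def __post_init__(self):
        if self.design not in ("interphase", "mitotic"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.z_multiplier <= 0:
            raise ValueError("z_multiplier must be positive")
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must be in (0, 1)")


def max_fold_change(profile) -> float:
    """Max/min of a (replicate-median) profile in linear space; >= 1."""
    v = np.asarray(profile, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 quantified fractions")
    if np.any(v <= 0):
        raise ValueError("ratios must be positive")
    return float(v.max() / v.min())


def zscore_cutoff(folds, z_multiplier=1.96):
    """One-sided fold-change threshold from the fold distribution itself.

    ``threshold = 2 ** (median(log2 folds) + z * sd(log2 folds))``, returned
    in fold units.  Folds are bounded below by 1, so only the upper cutoff
    selects.  Zero variance is degenerate: the threshold collapses to the
    median and is flagged.

    Returns ``(threshold, degenerate)``.
    """
    f = np.asarray(folds, dtype=float)
    f = f[np.isfinite(f)]
    if f.size < 3:
        raise ValueError("need at least 3 fold values")
    lf = np.log2(f)
    med = float(np.median(lf))
    sd = float(np.std(lf, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        log.warning("zero-variance fold distribution; threshold degenerates to the median")
    return float(2.0 ** (med + z_multiplier * sd)), degenerate


def anova_across_replicates(rep_profiles: pd.DataFrame):
    """One-way ANOVA of log2 values grouped by fraction.

    ``rep_profiles`` is a fraction x replicate frame for one protein.
    Proteins with any missing value are excluded from testing (returns
    None), per the complete-case policy.  Groups with no between-group
    variance give p = 1 (no evidence of change).
    """
    X = rep_profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        return None
    groups = [np.log2(row) for row in X]
    between = np.var([g.mean() for g in groups])
    if between < 1e-30:
        return 1.0
    within = sum(float(np.var(g)) for g in groups)
    if within < 1e-30:
        return 0.0
    _, p = stats.f_oneway(*groups)
    return float(p)


def replicate_correlation_criterion(rep_profiles: pd.DataFrame,
                                    min_positive_pairs=1,
                                    require_all_pairs=False):
    """Pairwise Pearson correlations between replicate profiles (log2 scale).

    ``rep_profiles`` is fraction x replicate.  A pair needs >= 3 shared
    quantified fractions; constant profiles make r undefined and the pair is
    skipped.  Passes if at least ``min_positive_pairs`` pairs (or all
    defined pairs, if ``require_all_pairs``) have r > 0.

    Returns ``(passed, {('r1','r2'): r, ...})``.
    """
    reps = list(rep_profiles.columns)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    rs = {}
    for a, b in combinations(reps, 2):
        x = rep_profiles[a].to_numpy(dtype=float)
        y = rep_profiles[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        lx, ly = np.log2(x[ok]), np.log2(y[ok])
        if np.std(lx) == 0 or np.std(ly) == 0:
            continue
        rs[(a, b)] = float(np.corrcoef(lx, ly)[0, 1])
    if not rs:
        return False, rs
    n_positive = sum(r > 0 for r in rs.values())
    if require_all_pairs:
        passed = n_positive == len(rs)
    else:
        passed = n_positive >= min_positive_pairs
    return passed, rs


def missing_value_rescue(matrix: pd.DataFrame) -> list:
    """Proteins missing reproducibly in exactly one fraction, all replicates.

    Rescued proteins are missing in the same single fraction in every
    replicate and quantified everywhere else — the signature of abundance
    falling below the detection limit in that fraction rather than of
    stochastic data-dependent-acquisition dropout.
    """
    fractions = matrix.columns.get_level_values(0).unique()
    replicates = matrix.columns.get_level_values(1).unique()
    if len(replicates) < 2:
        raise ValueError("rescue requires at least 2 replicates")
    missing = matrix.isna()
    frac_all_missing = pd.DataFrame(
        {f: missing.xs(f, axis=1, level=0).all(axis=1) for f in fractions})
    frac_any_missing = pd.DataFrame(
        {f: missing.xs(f, axis=1, level=0).any(axis=1) for f in fractions})
    exactly_one_all = frac_all_missing.sum(axis=1) == 1
    no_other_missing = (frac_any_missing.sum(axis=1) == 1)
    rescued = matrix.index[exactly_one_all & no_other_missing]
    return list(rescued)


def select_candidates(matrix: pd.DataFrame, config: SelectionConfig) -> pd.DataFrame:
    """Run the full significance procedure and return one verdict per protein.

    Complete-case proteins (quantified in every fraction of the replicate-
    median profile) enter the fold-change distribution; the Z cutoff comes
    from that distribution; the design-specific second criterion is ANOVA
    (interphase) or the positive-replicate-correlation rule (mitotic).
    Reproducibly missing proteins are appended with ``rescued=True`` (they
    cannot be clustered later).  The ``reason`` column holds a
    machine-readable JSON rule trace.
    """
    from .quant import replicate_median_profile

    median = replicate_median_profile(matrix)
    complete = median.notna().all(axis=1)
    folds = pd.Series(np.nan, index=median.index)
    for pid in median.index[complete]:
        folds[pid] = max_fold_change(median.loc[pid])
    threshold, degenerate = zscore_cutoff(folds[complete].to_numpy(),
                                          config.z_multiplier)
    log.info("fold-change cutoff %.3f (z=%.2f, %d complete proteins)",
             threshold, config.z_multiplier, int(complete.sum()))

    if config.apply_fdr:
        from statsmodels.stats.multitest import multipletests

    rescued_ids = set(missing_value_rescue(matrix))
    records = []
    pvals = {}
    if config.design == "interphase":
        for pid in median.index[complete]:
            prof = matrix.loc[pid].unstack(level="replicate")
            pvals[pid] = anova_across_replicates(prof)
        if config.apply_fdr:
            ids = [k for k, v in pvals.items() if v is not None]
            if ids:
                _, adj, _, _ = multipletests([pvals[k] for k in ids], method="fdr_bh")
                pvals.update(dict(zip(ids, adj)))

    for pid in median.index:
        rec = {"protein_id": pid, "max_fold_change": folds[pid],
               "fold_threshold": threshold,
               "rescued": pid in rescued_ids, "significant": False}
        trace = {"complete": bool(complete[pid]), "degenerate_cutoff": degenerate}
        if not complete[pid]:
            trace["excluded"] = "missing values"
            if rec["rescued"]:
                rec["significant"] = True
                trace["rescued"] = "reproducibly missing in a single fraction"
        else:
            passes_fold = folds[pid] > threshold
            trace["passes_fold"] = bool(passes_fold)
            if config.design == "interphase":
                p = pvals.get(pid)
                rec["anova_p"] = p
                trace["anova_p"] = p
                rec["significant"] = bool(passes_fold and p is not None
                                          and p < config.p_cutoff)
            else:
                prof = matrix.loc[pid].unstack(level="replicate")
                passed, rs = replicate_correlation_criterion(
                    prof, config.min_positive_pairs, config.require_all_pairs)
                trace["correlations"] = {f"{a}|{b}": r for (a, b), r in rs.items()}
                trace["correlation_pass"] = passed
                rec["significant"] = bool(passes_fold and passed)
        rec["reason"] = json.dumps(trace)
        records.append(rec)
    out = pd.DataFrame(records).set_index("protein_id")
    log.info("selection: %d/%d significant (%d rescued)",
             int(out["significant"].sum()), len(out), int(out["rescued"].sum()))
    return out
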