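"""Protein accumulation across the cell cycle: summaries and growth fits.

All inputs are linear-space ratio matrices (proteins x fractions, or
proteins x (fraction, replicate)); log2 transforms are applied here, at
analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ergodic import ASYNC_MEAN_CONTENT, CellCycleTimeline

__all__ = [
    "GrowthFit",
    "fraction_distribution_summary",
    "bulk_mean_profile",
    "fit_exponential",
    "growth_fit_from_ratios",
    "group_mean_profiles",
    "per_protein_fold",
]


@dataclass(frozen=True)
class GrowthFit:
    """Through-origin exponential growth fit ``y = exp(m t)``.

    ``m`` is the accumulation rate per unit cell-cycle time, so
    ``fold_over_cycle = exp(m)`` is the fold increase from birth to
    division (2.0 for perfect content doubling).  ``r2`` is the coefficient
    of determination on the ln scale.
    """

    m: float
    r2: float
    t: tuple
    log_y: tuple

    @property
    def fold_over_cycle(self) -> float:
        return float(np.exp(self.m))


def fraction_distribution_summary(matrix: pd.DataFrame, fraction: str) -> dict:
    """Quartile summary of the log2 ratio distribution in one fraction.

    Quartiles use linear interpolation (the type-7 convention).  These are
    the per-fraction statistics drawn on violin ('neeps') plots.
    """
    if fraction not in matrix.columns.get_level_values(0):
        raise KeyError(f"fraction {fraction!r} not in matrix")
    vals = matrix[fraction].to_numpy(dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"fraction {fraction!r} has no values")
    if vals.size < 4:
        raise ValueError(f"fraction {fraction!r} has fewer than 4 values")
    logv = np.log2(vals)
    q1, med, q3 = np.percentile(logv, [25, 50, 75])  # numpy 'linear' = type 7
    return {
        "fraction": fraction, "n": int(vals.size),
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def bulk_mean_profile(matrix: pd.DataFrame, reference: str | None = "G1") -> pd.DataFrame:
    """Mean log2 measurement across all proteins, per fraction.

    Available-case means (missing values ignored per fraction).  When
    ``reference`` is given, the reference fraction's mean is subtracted on
    the log scale so the profile is anchored at the reference; pass
    ``reference=None`` to keep the raw asynchronous-standard scale (needed
    for growth fitting).  Returns a fraction-indexed frame with columns
    ``mean_log2``, ``sem`` and ``n``.
    """
    logm = np.log2(matrix.astype(float))
    # pool all replicate measurements of a fraction
    mean, sem, n = {}, {}, {}
    for f in logm.columns.get_level_values(0).unique():
        v = logm.xs(f, axis=1, level=0).to_numpy().ravel()
        v = v[np.isfinite(v)]
        n[f] = v.size
        mean[f] = float(np.mean(v)) if v.size else np.nan
        sem[f] = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
    out = pd.DataFrame({"mean_log2": pd.Series(mean), "sem": pd.Series(sem),
                        "n": pd.Series(n)})
    out.index.name = "fraction"
    if reference is not None:
        if reference not in out.index:
            raise KeyError(f"reference fraction {reference!r} not present")
        out["mean_log2"] = out["mean_log2"] - out.loc[reference, "mean_log2"]
    return out


def fit_exponential(t, y) -> GrowthFit:
    """Least-squares fit of ``y = exp(m t)`` through the origin.

    The fit is linear in ``ln(y)`` with the intercept fixed at 0, i.e. the
    caller must supply ``y`` on a scale where a newborn cell (t=0) has unit
    content (see :func:`growth_fit_from_ratios`).  ``r2`` is computed on the
    ln scale against the mean of ln(y); for a degenerate flat input with a
    perfect fit, r2 is 1.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need at least 3 (t, y) points")
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    ly = np.log(y)
    m = float(np.dot(t, ly) / np.dot(t, t))
    resid = ly - m * t
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return GrowthFit(m=m, r2=float(np.clip(r2, 0.0, 1.0)),
                     t=tuple(t), log_y=tuple(ly))


def growth_fit_from_ratios(timeline: CellCycleTimeline,
                           mean_ratio_profile: pd.Series) -> GrowthFit:
    """Fit bulk growth from mean sorted-fraction / asynchronous-standard ratios.

    A ratio against the asynchronous internal standard equals per-cell
    content divided by the population mean content 2 ln2, so multiplying by
    2 ln2 restores the per-newborn-cell scale (y(0) = 1 under exponential
    doubling), which the through-origin fit requires.
    """
    fractions = [p for p in timeline.phases if p in mean_ratio_profile.index]
    if len(fractions) < 3:
        raise ValueError("timeline and profile share fewer than 3 phases")
    t = np.array([timeline.position(p) for p in fractions])
    y = mean_ratio_profile.loc[fractions].to_numpy(dtype=float) * ASYNC_MEAN_CONTENT
    return fit_exponential(t, y)


def group_mean_profiles(median_matrix: pd.DataFrame, labels: dict) -> pd.DataFrame:
    """Mean profile per annotation label (heatmap-ready), with member counts.

    ``labels`` maps a label string to its member protein identifiers; every
    label must have at least one member present in the matrix.
    """
    rows = {}
    counts = {}
    for label, members in labels.items():
        present = median_matrix.index.intersection(pd.Index(members))
        if len(present) == 0:
            raise KeyError(f"label {label!r} has no members in the matrix")
        rows[label] = median_matrix.loc[present].mean(axis=0, skipna=True)
        counts[label] = len(present)
    out = pd.DataFrame(rows).T
    out.index.name = "label"
    out["n_proteins"] = pd.Series(counts)
    return out


def per_protein_fold(median_matrix: pd.DataFrame) -> pd.DataFrame:
    """Max/min fold change of each protein's median profile.

    Returns ``fold`` (>= 1), the fractions where the max and min occur, and
    ``n_fractions`` present.  Rows with fewer than 2 quantified fractions
    get NaN fold; an entirely missing row is an input error.
    """
    X = median_matrix.to_numpy(dtype=float)
    finite = np.isfinite(X)
    if np.any(~finite.any(axis=1)):
        bad = list(median_matrix.index[~finite.any(axis=1)])
        raise ValueError(f"rows with no quantified fraction: {bad[:10]}")
    n_present = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vmax = np.nanmax(X, axis=1)
        vmin = np.nanmin(X, axis=1)
    fold = np.where(n_present >= 2, vmax / vmin, np.nan)
    cols = np.asarray(median_matrix.columns)
    imax = np.nanargmax(np.where(finite, X, -np.inf), axis=1)
    imin = np.nanargmin(np.where(finite, X, np.inf), axis=1)
    return pd.DataFrame({
        "fold": fold,
        "max_fraction": cols[imax],
        "min_fraction": cols[imin],
        "n_fractions": n_present,
    }, index=median_matrix.index)
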