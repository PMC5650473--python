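"""SILAC and TMT quantitation: impurity correction, normalisation, merging.

Profile matrices are pandas DataFrames indexed by the leading razor protein
identifier with MultiIndex columns ``(fraction, replicate)`` holding strictly
positive relative abundances; missing measurements are NaN, never zero.
Ratios live in linear space throughout — log2 transforms happen at analysis
time only — so every contract here is multiplicative.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "correct_isotope_impurities",
    "normalize_reporters",
    "reference_ratios",
    "normalize_silac",
    "replicate_median_profile",
    "merge_datasets",
    "MergeStats",
]

log = logging.getLogger("primmus.quant")


def correct_isotope_impurities(reporters: pd.DataFrame, impurity_matrix):
    """Undo isotope-impurity cross-talk between TMT reporter channels.

    Solves the linear system ``impurity_matrix @ true = observed`` per
    protein (column j of the matrix gives the distribution of channel j's
    signal over observed channels).  Negative solutions — possible when
    noise exceeds a small true signal — are clamped to zero and flagged.

    Returns ``(corrected, clamped)`` where ``clamped`` is a boolean Series
    marking rows in which any channel was clamped.
    """
    M = np.asarray(impurity_matrix, dtype=float)
    n = reporters.shape[1]
    if M.shape != (n, n):
        raise ValueError(f"impurity matrix must be {n}x{n} to match channels, got {M.shape}")
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("impurity matrix is singular")
    X = reporters.to_numpy(dtype=float)
    true = np.linalg.solve(M, X.T).T
    clamped_mask = true < 0
    true = np.where(clamped_mask, 0.0, true)
    corrected = pd.DataFrame(true, index=reporters.index, columns=reporters.columns)
    clamped = pd.Series(clamped_mask.any(axis=1), index=reporters.index, name="clamped")
    if clamped.any():
        log.info("impurity correction clamped negatives in %d rows", int(clamped.sum()))
    return corrected, clamped


def normalize_reporters(corrected: pd.DataFrame) -> pd.DataFrame:
    """Divide each reporter by the per-protein sum of reporter intensities.

    Output rows sum to exactly 1.  Rows that are entirely zero carry no
    quantitative information and raise.
    """
    X = corrected.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("reporter intensities must be non-negative")
    totals = X.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = list(corrected.index[zero])
        raise ValueError(f"all-zero reporter rows: {bad[:10]}")
    return corrected.div(totals, axis=0)


def reference_ratios(normalized: pd.DataFrame, channel_map: dict,
                     reference_fraction: str) -> pd.DataFrame:
    """Convert channel fractions to ratios against a reference fraction.

    Channel labels are replaced by fraction labels via ``channel_map`` (a
    bijection) and every value is divided by the reference fraction's value,
    so the reference column equals 1.  Rows whose reference channel is zero
    or missing are kept but set entirely missing (flagged in the log), never
    silently dropped.
    """
    channels = list(normalized.columns)
    mapped = [channel_map.get(c, None) for c in channels]
    if None in mapped or len(set(mapped)) != len(mapped):
        raise ValueError("channel_map must be a bijection covering all channels")
    if reference_fraction not in mapped:
        raise ValueError(f"reference fraction {reference_fraction!r} absent from channel map")
    out = normalized.copy()
    out.columns = mapped
    ref = out[reference_fraction]
    bad = ~(ref > 0) | ref.isna()
    result = out.div(ref, axis=0)
    if bad.any():
        result.loc[bad, :] = np.nan
        log.info("reference fraction missing/zero for %d rows; marked missing",
                 int(bad.sum()))
    return result


def _require_profile_matrix(matrix: pd.DataFrame):
    if not isinstance(matrix.columns, pd.MultiIndex) or matrix.columns.nlevels != 2:
        raise ValueError("expected MultiIndex (fraction, replicate) columns")


def normalize_silac(matrix: pd.DataFrame, mode: str,
                    reference_fraction: str | None = None) -> pd.DataFrame:
    """Normalise SILAC ratios to a reference fraction.

    ``mode='per-replicate-to-reference'`` (interphase design) divides each
    replicate's profile by that replicate's own reference-fraction value
    (default reference G1); a replicate missing its reference is excluded
    (set missing) for that protein and logged.  ``mode='to-reference-of-
    replicate-1'`` (mitotic design) divides all replicates by replicate 1's
    reference value (default reference Pro).  Idempotent: the reference
    value is exactly 1 afterwards, wherever present.
    """
    _require_profile_matrix(matrix)
    fractions = list(matrix.columns.get_level_values(0).unique())
    replicates = list(matrix.columns.get_level_values(1).unique())
    if mode in ("per-replicate-to-reference", "silac-g1"):
        ref = reference_fraction or "G1"
        if ref not in fractions:
            raise ValueError(f"reference fraction {ref!r} not in matrix")
        out = matrix.copy()
        for r in replicates:
            refv = matrix[(ref, r)]
            bad = ~(refv > 0) | refv.isna()
            block = matrix.xs(r, axis=1, level=1, drop_level=False)
            normed = block.div(refv, axis=0)
            normed[bad] = np.nan
            out.loc[:, block.columns] = normed.to_numpy()
            if bad.any():
                log.info("replicate %s: %d rows lack reference %s; excluded",
                         r, int(bad.sum()), ref)
        return out
    if mode in ("to-reference-of-replicate-1", "silac-pro1"):
        ref = reference_fraction or "Pro"
        r1 = replicates[0]
        if (ref, r1) not in matrix.columns:
            raise ValueError(f"reference ({ref!r}, {r1!r}) not in matrix")
        refv = matrix[(ref, r1)]
        bad = ~(refv > 0) | refv.isna()
        out = matrix.div(refv, axis=0)
        out[bad] = np.nan
        if bad.any():
            log.info("%d rows lack reference (%s, %s); excluded", int(bad.sum()), ref, r1)
        return out
    raise ValueError(f"unknown normalisation mode {mode!r}")


def replicate_median_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median over replicates per fraction; fractions with no replicate are NaN."""
    _require_profile_matrix(matrix)
    return matrix.T.groupby(level="fraction", sort=False).median().T


class MergeStats(NamedTuple):
    n_left: int
    n_right: int
    n_overlap: int

    @property
    def overlap_fraction(self) -> float:
        denom = min(self.n_left, self.n_right)
        return self.n_overlap / denom if denom else 0.0


def merge_datasets(silac: pd.DataFrame, tmt: pd.DataFrame,
                   sources=("silac", "tmt")):
    """Outer-join two profile matrices on the protein identifier.

    Replicate labels are prefixed with their source so both streams'
    columns survive the merge intact.  Duplicate identifiers within one
    source are an input error.  Returns ``(merged, MergeStats)``.
    """
    for name, df in zip(sources, (silac, tmt)):
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate protein identifiers in {name}: {list(dup)[:10]}")

    def _tag(df, tag):
        _require_profile_matrix(df)
        out = df.copy()
        out.columns = pd.MultiIndex.from_tuples(
            [(f, f"{tag}_{r}") for f, r in df.columns],
            names=["fraction", "replicate"])
        return out

    left, right = _tag(silac, sources[0]), _tag(tmt, sources[1])
    merged = left.join(right, how="outer")
    merged = merged.sort_index(axis=1, level=0, sort_remaining=False)
    stats = MergeStats(
        n_left=len(silac), n_right=len(tmt),
        n_overlap=len(silac.index.intersection(tmt.index)),
    )
    log.info("merged %d + %d proteins, overlap %d (%.1f%%)",
             stats.n_left, stats.n_right, stats.n_overlap,
             100 * stats.overlap_fraction)
    return merged, stats
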