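"""Reading and writing the tabular dialects used across the pipeline.

Protein-groups and phospho-site tables are tab-separated text with a header
row; quantitative columns are named ``ratio_<fraction>_<replicate>`` and
missing values are empty cells.  In memory they become DataFrames with
MultiIndex ``(fraction, replicate)`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "matrix_to_wide",
    "wide_to_matrix",
    "write_protein_groups",
    "read_protein_groups",
    "write_phosphosites",
    "read_phosphosites",
    "read_impurity_matrix",
    "write_impurity_matrix",
    "read_phase_frequencies",
]

RATIO_PREFIX = "ratio_"


def matrix_to_wide(matrix: pd.DataFrame) -> pd.DataFrame:
    """Flatten (fraction, replicate) columns to ``ratio_<fraction>_<rep>``."""
    out = matrix.copy()
    out.columns = [f"{RATIO_PREFIX}{f}_{r}" for f, r in matrix.columns]
    return out


def wide_to_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Rebuild MultiIndex columns from ``ratio_<fraction>_<rep>`` names."""
    tuples = []
    cols = []
    for c in df.columns:
        if not c.startswith(RATIO_PREFIX):
            continue
        frac, _, rep = c[len(RATIO_PREFIX):].rpartition("_")
        if not frac:
            raise ValueError(f"malformed ratio column {c!r}")
        tuples.append((frac, rep))
        cols.append(c)
    out = df[cols].astype(float)
    out.columns = pd.MultiIndex.from_tuples(tuples, names=["fraction", "replicate"])
    return out


def write_protein_groups(path, matrix: pd.DataFrame, meta: pd.DataFrame | None = None):
    wide = matrix_to_wide(matrix)
    if meta is not None:
        wide = meta.join(wide)
    wide.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def read_protein_groups(path):
    """Read a protein-groups TSV; returns ``(matrix, meta)``."""
    try:
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
    except Exception as exc:  # noqa: BLE001 - report file context
        raise ValueError(f"malformed protein-groups TSV {path}: {exc}") from exc
    matrix = wide_to_matrix(df)
    meta = df[[c for c in df.columns if not c.startswith(RATIO_PREFIX)]]
    return matrix, meta


def write_phosphosites(path, meta: pd.DataFrame, quant: pd.DataFrame):
    wide = meta.join(matrix_to_wide(quant))
    wide.to_csv(path, sep="\t", index_label="site_id", na_rep="")


def read_phosphosites(path):
    try:
        df = pd.read_csv(path, sep="\t", index_col="site_id")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed phospho-site TSV {path}: {exc}") from exc
    quant = wide_to_matrix(df)
    meta = df[[c for c in df.columns if not c.startswith(RATIO_PREFIX)]]
    return meta, quant


def write_impurity_matrix(path, matrix, channels):
    pd.DataFrame(np.asarray(matrix, float), index=list(channels),
                 columns=list(channels)).to_csv(path)


def read_impurity_matrix(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def read_phase_frequencies(path):
    """Phase-frequency table from JSON ({phases, cumulative_freq,
    doubling_time}) or CSV (phase, cumulative_freq columns)."""
    from .ergodic import PhaseFrequencyTable

    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return PhaseFrequencyTable(
            phases=tuple(payload["phases"]),
            cumulative_freq=tuple(payload["cumulative_freq"]),
            doubling_time=float(payload.get("doubling_time", 24.0)),
        )
    df = pd.read_csv(path)
    dt = float(df["doubling_time"].iloc[0]) if "doubling_time" in df else 24.0
    return PhaseFrequencyTable(
        phases=tuple(df["phase"]),
        cumulative_freq=tuple(df["cumulative_freq"].astype(float)),
        doubling_time=dt,
    )
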