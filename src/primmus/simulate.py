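"""Synthetic generator for FACS-sorted cell-cycle proteomics experiments.

The generator emulates the measurement process of sorting an asynchronous,
exponentially growing culture into cell-cycle (G1/S/G2/M) or intra-mitotic
(Pro/PM1/PM2/Ana) gates and quantifying each sorted fraction against an
asynchronous internal standard:

* cell ages are drawn from the ergodic age density ``2 ln2 * 2**(-t)``;
* per-protein abundance follows one of six cell-cycle trajectory classes
  (bulk exponential accumulation, histone-like plateau after S phase,
  mitotic peaking, prometaphase or anaphase degradation, constant per cell);
* sort gates have configurable composition purity, with contaminating cells
  drawn from adjacent phases;
* the SILAC-style readout of a gate is the mean per-cell abundance over the
  gated cells divided by the mean over the whole (asynchronous) population —
  equal-cell-number 1:1 mixing with the standard;
* measurement noise is multiplicative lognormal, values drop out at random
  (per protein and MS run) or dependent on abundance, and TMT reporter ions
  additionally suffer isotope-impurity cross-talk and ratio compression.

Ground-truth class labels are returned alongside every simulated table so
that downstream selection and clustering can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .ergodic import age_density, cumulative_to_time

__all__ = [
    "TrajectoryModel",
    "SimulationConfig",
    "CycleGeometry",
    "sample_population",
    "assign_gates",
    "simulate_silac_matrix",
    "simulate_tmt_reporters",
    "simulate_phosphosites",
    "expected_profile_matrix",
    "simulate_interphase_dataset",
    "simulate_mitotic_dataset",
    "default_interphase_panel",
    "default_mitotic_panel",
    "default_impurity_matrix",
    "INTERPHASE_FRACTIONS",
    "MITOTIC_FRACTIONS",
    "TMT_CHANNELS",
    "DEFAULT_CHANNEL_MAP",
]

INTERPHASE_FRACTIONS = ("G1", "S", "G2", "M")
MITOTIC_FRACTIONS = ("Pro", "PM1", "PM2", "Ana")

#: 6-plex reporter channels and the channel -> sorted-fraction assignment
#: used in the mitotic design.
TMT_CHANNELS = ("126", "127N", "128C", "129N", "130C", "131")
DEFAULT_CHANNEL_MAP = {
    "126": "G2",
    "127N": "M",
    "128C": "Pro",
    "129N": "PM2",
    "130C": "PM1",
    "131": "Ana",
}

TRAJECTORY_CLASSES = (
    "bulk_exponential",
    "histone_plateau",
    "mitotic_peak",
    "prometaphase_degraded",
    "anaphase_degraded",
    "constant_per_cell",
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal: cv^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class TrajectoryModel:
    """One protein's relative per-cell abundance across the cell cycle.

    ``abundance(t)`` is strictly positive on [0, 1].  Shape parameters are
    class specific:

    bulk_exponential
        none — abundance is ``baseline * 2**t`` (doubles over one cycle).
    histone_plateau
        ``s_start``, ``s_end`` — abundance doubles linearly across the DNA
        synthesis window and stays flat afterwards (histones track DNA).
    mitotic_peak
        ``peak_fold`` (default 8), ``onset``, ``width`` — logistic rise to
        ``peak_fold`` late in the cycle (AURKA-like).
    prometaphase_degraded / anaphase_degraded
        ``residual`` (default 0.4 / 0.3) and ``drop_window=(t0, t1)`` —
        constant per-cell level (mitotic synthesis shut-off) with a linear
        decrease to ``residual`` of the pre-drop level across the drop
        window, constant afterwards (cyclin-A- / cyclin-B-like).  Place the
        window just before a sorted sub-stage to put that stage exactly at
        the residual level.
    constant_per_cell
        none — constant ``baseline`` per cell (stress-response-like).
    """

    name: str
    class_label: str
    baseline: float = 1.0
    shape: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.class_label not in TRAJECTORY_CLASSES:
            raise ValueError(f"unknown trajectory class {self.class_label!r}")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    def abundance(self, t):
        t = np.asarray(t, dtype=float)
        b, s = self.baseline, self.shape
        if self.class_label == "bulk_exponential":
            out = b * np.exp2(t)
        elif self.class_label == "constant_per_cell":
            out = np.full_like(t, b)
        elif self.class_label == "histone_plateau":
            s0 = s.get("s_start", 0.16)
            s1 = s.get("s_end", 0.57)
            frac = np.clip((t - s0) / (s1 - s0), 0.0, 1.0)
            out = b * (1.0 + frac)
        elif self.class_label == "mitotic_peak":
            fold = s.get("peak_fold", 8.0)
            onset = s.get("onset", 0.80)
            width = s.get("width", 0.05)
            rise = 1.0 / (1.0 + np.exp(-(t - onset) / width))
            out = b * (1.0 + (fold - 1.0) * rise)
        elif self.class_label in ("prometaphase_degraded", "anaphase_degraded"):
            default_res = 0.4 if self.class_label == "prometaphase_degraded" else 0.3
            residual = s.get("residual", default_res)
            t0, t1 = s.get("drop_window", (0.91, 0.94))
            frac = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
            out = b * (1.0 - (1.0 - residual) * frac)
        else:  # pragma: no cover
            raise AssertionError(self.class_label)
        return out if out.ndim else float(out)

    def population_mean(self) -> float:
        """Age-density-weighted mean abundance (the asynchronous standard)."""
        if self.class_label == "bulk_exponential":
            # integral of 2**t * f(t) over one cycle is exactly 2 ln2
            return self.baseline * 2.0 * np.log(2.0)
        if self.class_label == "constant_per_cell":
            return self.baseline
        val, _ = quad(
            lambda x: self.abundance(x) * age_density(x), 0.0, 1.0,
            limit=200, epsabs=1e-12, epsrel=1e-12,
        )
        return float(val)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    ``phase_boundaries`` are cumulative phase frequencies (the flow-cytometry
    observable), not positions in time; defaults are the NB4 measurements
    21/65/92/98% for G1/S/G2/M with a 24 h doubling time.
    """

    n_cells: int = 50_000
    n_proteins: dict | None = None
    doubling_time: float = 24.0
    phase_boundaries: tuple = (0.21, 0.65, 0.92, 0.98)
    gate_purity: float = 0.96
    noise_cv: float = 0.15
    dropout_rate: float = 0.05
    dropout_mode: str = "mcar"
    compression: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        F = np.asarray(self.phase_boundaries, dtype=float)
        if np.any(np.diff(F) <= 0) or np.any(F <= 0) or F[-1] > 1.0:
            raise ValueError("phase_boundaries must be strictly increasing in (0, 1]")
        if not (0.5 < self.gate_purity <= 1.0):
            raise ValueError("gate_purity must be in (0.5, 1]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dropout_mode not in ("mcar", "abundance"):
            raise ValueError("dropout_mode must be 'mcar' or 'abundance'")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CycleGeometry:
    """Gate boundaries mapped into normalised cell-cycle time.

    Interphase gates span [0, 1] at the ergodic positions of the cumulative
    phase frequencies (the last gate is extended to t=1 so every cell falls
    in a gate).  The four intra-mitotic stages are modelled as ordered,
    equal-width sub-intervals of the M window.
    """

    interphase_edges: tuple
    mitotic_edges: tuple
    boundary_positions: tuple

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "CycleGeometry":
        F = np.asarray(config.phase_boundaries, dtype=float)
        t = cumulative_to_time(F)
        # gates must cover [0, 1]: the last gate absorbs the unclassified
        # tail, but the ergodic boundary positions keep their true values
        inter = (0.0,) + tuple(float(x) for x in t[:-1]) + (1.0,)
        m_start = inter[-2]
        sub = np.linspace(m_start, 1.0, 5)
        return cls(interphase_edges=inter,
                   mitotic_edges=tuple(float(x) for x in sub),
                   boundary_positions=tuple(float(x) for x in t))

    def subphase_window(self, fraction: str) -> tuple:
        i = MITOTIC_FRACTIONS.index(fraction)
        return (self.mitotic_edges[i], self.mitotic_edges[i + 1])

    def timeline_positions(self) -> dict:
        """Ergodic position (cumulative upper boundary) per interphase gate."""
        return dict(zip(INTERPHASE_FRACTIONS, self.boundary_positions))

    def mitotic_positions(self) -> dict:
        """Midpoint position of each intra-mitotic sub-interval."""
        e = np.asarray(self.mitotic_edges)
        mid = (e[:-1] + e[1:]) / 2.0
        return dict(zip(MITOTIC_FRACTIONS, mid))


def sample_population(config: SimulationConfig, rng=None, n=None) -> np.ndarray:
    """Draw cell-cycle ages for an asynchronous exponentially growing culture.

    Inverse-CDF sampling from ``f(t) = 2 ln2 * 2**(-t)``.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_cells if n is None else int(n)
    if n <= 0:
        raise ValueError("number of cells must be positive")
    u = rng.random(n)
    return -np.log2(1.0 - u / 2.0)


def sample_mitotic_population(config: SimulationConfig, geometry=None, rng=None, n=None):
    """Ages conditional on the M window (the H3S28ph-positive sort input)."""
    rng = config.rng() if rng is None else rng
    geometry = geometry or CycleGeometry.from_config(config)
    n = config.n_cells if n is None else int(n)
    m0 = geometry.mitotic_edges[0]
    F0 = 2.0 * (1.0 - np.exp2(-m0))
    u = F0 + rng.random(n) * (1.0 - F0)
    return -np.log2(1.0 - u / 2.0)


def assign_gates(ages, edges, labels, gate_purity, rng) -> np.ndarray:
    """Sort cells into gates defined by age-space boundaries.

    With ``gate_purity`` p, each gate is composed of a fraction p of cells
    truly in its window plus (1-p) contaminants drawn from adjacent windows;
    surplus cells remain unsorted (empty label), as in a real sort where not
    every cell is collected.
    """
    ages = np.asarray(ages, dtype=float)
    edges = np.asarray(edges, dtype=float)
    labels = list(labels)
    if len(edges) != len(labels) + 1:
        raise ValueError("need len(labels) + 1 gate boundaries")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("gate boundaries must be strictly increasing (non-overlapping)")
    if not (0.5 < gate_purity <= 1.0):
        raise ValueError("gate_purity must be in (0.5, 1]")
    k = len(labels)
    true_gate = np.searchsorted(edges, ages, side="right") - 1
    true_gate[ages == edges[-1]] = k - 1
    outside = (ages < edges[0]) | (ages > edges[-1])
    true_gate[outside] = -1

    out = np.full(ages.shape, "", dtype=object)
    if gate_purity == 1.0:
        for i, lab in enumerate(labels):
            sel = true_gate == i
            if not sel.any():
                raise ValueError(f"empty gate {lab!r}")
            out[sel] = lab
        return out

    idx_by_gate = [np.flatnonzero(true_gate == i) for i in range(k)]
    claimed = np.zeros(ages.shape, dtype=bool)
    for i, lab in enumerate(labels):
        own = idx_by_gate[i]
        if own.size == 0:
            raise ValueError(f"empty gate {lab!r}")
        n_correct = int(round(gate_purity * own.size))
        correct = rng.choice(own, size=min(n_correct, own.size), replace=False)
        out[correct] = lab
        claimed[correct] = True
        n_cont = own.size - correct.size
        if n_cont > 0:
            neighbours = [j for j in (i - 1, i + 1) if 0 <= j < k]
            pool = np.concatenate([idx_by_gate[j] for j in neighbours]) if neighbours else np.array([], int)
            pool = pool[~claimed[pool]]
            if pool.size:
                cont = rng.choice(pool, size=min(n_cont, pool.size), replace=False)
                out[cont] = lab
                claimed[cont] = True
    return out


def _apply_noise(values: np.ndarray, cv: float, rng) -> np.ndarray:
    if cv <= 0:
        return values
    sigma = _lognormal_sigma(cv)
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def _apply_dropout(df: pd.DataFrame, config: SimulationConfig, rng) -> pd.DataFrame:
    if config.dropout_rate <= 0:
        return df
    if config.dropout_mode == "mcar":
        mask = rng.random(df.shape) < config.dropout_rate
    else:  # abundance-dependent (logistic in log-abundance, DDA-like)
        logv = np.log2(df.to_numpy(dtype=float))
        centre = np.nanmedian(logv)
        # low-abundance values drop out more; calibrated so the marginal
        # rate is roughly config.dropout_rate at slope 1
        p = config.dropout_rate * 2.0 / (1.0 + np.exp(logv - centre))
        mask = rng.random(df.shape) < p
    out = df.copy()
    out.values[mask] = np.nan
    return out


def simulate_silac_matrix(ages, gates, trajectories, config, rng=None,
                          fractions=None, standard_ages=None):
    """Measure one replicate run: per-protein sorted-fraction SILAC ratios.

    The readout per gate is mean per-cell abundance over gated cells divided
    by the mean over the asynchronous standard population (equal cell-number
    1:1 mixing), with multiplicative lognormal noise and dropout.  Returns
    ``(matrix, truth)``: a protein x fraction DataFrame and the noise-free
    ground-truth values.
    """
    rng = config.rng() if rng is None else rng
    ages = np.asarray(ages, dtype=float)
    gates = np.asarray(gates, dtype=object)
    if fractions is None:
        fractions = [f for f in INTERPHASE_FRACTIONS if (gates == f).any()]
        if not fractions:
            fractions = sorted(set(gates) - {""})
    std_ages = ages if standard_ages is None else np.asarray(standard_ages, float)

    gate_idx = {}
    for f in fractions:
        sel = np.flatnonzero(gates == f)
        if sel.size == 0:
            raise ValueError(f"empty gate {f!r}")
        gate_idx[f] = sel

    names = [tr.name for tr in trajectories]
    true = np.empty((len(trajectories), len(fractions)))
    for i, tr in enumerate(trajectories):
        ab = tr.abundance(ages)
        std_mean = float(np.mean(tr.abundance(std_ages)))
        for j, f in enumerate(fractions):
            true[i, j] = float(np.mean(ab[gate_idx[f]])) / std_mean
    truth = pd.DataFrame(true, index=pd.Index(names, name="protein_id"), columns=list(fractions))
    noisy = pd.DataFrame(
        _apply_noise(true.copy(), config.noise_cv, rng),
        index=truth.index, columns=list(fractions),
    )
    noisy = _apply_dropout(noisy, config, rng)
    return noisy, truth


def simulate_tmt_reporters(true_fraction_abundances: pd.DataFrame,
                           impurity_matrix, compression, config,
                           rng=None, intensity_scale=1e6) -> pd.DataFrame:
    """Forward model for raw TMT reporter intensities.

    True relative signals are ratio-compressed (observed ratio =
    true ratio ** compression, anchored at the row geometric mean, emulating
    co-isolation interference), scaled to reporter intensities, and mixed by
    the isotope-impurity matrix (column j gives the distribution of channel
    j's signal over observed channels).  With an identity matrix and
    compression 1 the output is proportional to the input.
    """
    rng = config.rng() if rng is None else rng
    X = true_fraction_abundances.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("true abundances must be non-negative")
    M = np.asarray(impurity_matrix, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] != X.shape[1]:
        raise ValueError("impurity matrix shape must match channel count")
    if np.any(M < 0) or np.any(M.sum(axis=0) > 1.0 + 1e-9):
        raise ValueError("impurity matrix must be non-negative with column sums <= 1")
    if not (0.0 < compression <= 1.0):
        raise ValueError("compression must be in (0, 1]")

    if compression < 1.0:
        with np.errstate(divide="ignore"):
            logx = np.log(X)
        pos = np.isfinite(logx)
        g = np.exp(np.where(pos, logx, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1))
        X = g[:, None] * (X / g[:, None]) ** compression
        X[~pos] = 0.0
    signal = X * intensity_scale
    observed = signal @ M.T
    observed = _apply_noise(observed, config.noise_cv, rng)
    return pd.DataFrame(observed, index=true_fraction_abundances.index,
                        columns=true_fraction_abundances.columns)


def default_impurity_matrix(n_channels=6, spill=0.03) -> np.ndarray:
    """A plausible +/-1 Da isotope-impurity matrix (few-percent spill).

    Lot-specific values belong in the run configuration; this default exists
    so the simulator and round-trip tests have a realistic non-trivial matrix.
    """
    M = np.zeros((n_channels, n_channels))
    for j in range(n_channels):
        M[j, j] = 1.0 - spill * ((j > 0) + (j < n_channels - 1))
        if j > 0:
            M[j - 1, j] = spill
        if j < n_channels - 1:
            M[j + 1, j] = spill
    return M


# --------------------------------------------------------------------------
# expected-profile ("placed at the timeline") mode

def expected_profile_matrix(trajectories, positions: dict, config,
                            rng=None, n_replicates=1):
    """Deterministic expected sorted-fraction ratios at given timeline positions.

    Each fraction's value is the trajectory evaluated at the fraction's
    ergodic timeline position divided by the age-weighted population mean
    (the asynchronous standard), times lognormal noise.  This is the
    model-expected profile rather than a Monte-Carlo gate average; use it
    when the quantity of interest is the timeline itself (growth fits).
    Returns ``(matrix, truth)`` with (fraction, replicate) columns.
    """
    rng = config.rng() if rng is None else rng
    fractions = list(positions)
    t = np.array([positions[f] for f in fractions])
    names = [tr.name for tr in trajectories]
    true = np.empty((len(trajectories), len(fractions)))
    for i, tr in enumerate(trajectories):
        true[i] = tr.abundance(t) / tr.population_mean()
    truth = pd.DataFrame(true, index=pd.Index(names, name="protein_id"),
                         columns=fractions)
    cols = pd.MultiIndex.from_product(
        [fractions, [f"r{i+1}" for i in range(n_replicates)]],
        names=["fraction", "replicate"],
    )
    vals = np.repeat(true[:, :, None], n_replicates, axis=2).reshape(len(names), -1)
    mat = pd.DataFrame(_apply_noise(vals, config.noise_cv, rng),
                       index=truth.index, columns=cols)
    mat = _apply_dropout(mat, config, rng)
    return mat, truth


# --------------------------------------------------------------------------
# trajectory panels

def _panel_counts(config, defaults: dict) -> dict:
    counts = dict(defaults)
    if config.n_proteins:
        counts.update(config.n_proteins)
    return counts


def default_interphase_panel(config: SimulationConfig, geometry=None):
    """Trajectory panel for the interphase (G1/S/G2/M) design."""
    geometry = geometry or CycleGeometry.from_config(config)
    tpos = geometry.timeline_positions()
    counts = _panel_counts(config, {
        "bulk_exponential": 1000,
        "histone_plateau": 50,
        "mitotic_peak": 30,
        "constant_per_cell": 50,
    })
    shape = {
        "histone_plateau": {"s_start": tpos["G1"], "s_end": tpos["S"]},
        "mitotic_peak": {"peak_fold": 8.0},
    }
    panel = []
    for cls, n in counts.items():
        for i in range(n):
            panel.append(TrajectoryModel(
                name=f"{cls.upper()[:4]}_{i:04d}", class_label=cls,
                shape=dict(shape.get(cls, {})),
            ))
    return panel


def default_mitotic_panel(config: SimulationConfig, geometry=None):
    """Trajectory panel for the intra-mitotic (Pro/PM1/PM2/Ana) design.

    2,000 unregulated (constant per cell) proteins plus 60 planted degraded
    proteins: 30 dropping in PM1 (cyclin-A/RRM2-like, residual 0.4), 10 in
    PM2 (residual 0.4) and 20 in anaphase (cyclin-B-like, residual 0.3).
    """
    geometry = geometry or CycleGeometry.from_config(config)
    counts = _panel_counts(config, {
        "constant_per_cell": 2000,
        "pm1_degraded": 30,
        "pm2_degraded": 10,
        "anaphase_degraded": 20,
    })
    panel = []
    for i in range(counts.get("constant_per_cell", 0)):
        panel.append(TrajectoryModel(name=f"FLAT_{i:04d}", class_label="constant_per_cell"))
    planted = [
        ("pm1_degraded", "prometaphase_degraded", "PM1", 0.4),
        ("pm2_degraded", "prometaphase_degraded", "PM2", 0.4),
        ("anaphase_degraded", "anaphase_degraded", "Ana", 0.3),
    ]
    for key, cls, frac, residual in planted:
        t0, _t1 = geometry.subphase_window(frac)
        width = geometry.mitotic_edges[1] - geometry.mitotic_edges[0]
        # degradation completes at the sub-stage boundary, so the named
        # fraction sits exactly at the residual level
        w = (t0 - 0.15 * width, t0)
        for i in range(counts.get(key, 0)):
            panel.append(TrajectoryModel(
                name=f"{frac.upper()}DEG_{i:04d}", class_label=cls,
                shape={"residual": residual, "drop_window": w, "trough": frac},
            ))
    return panel


class SimulatedDataset(NamedTuple):
    matrix: pd.DataFrame        # proteins x (fraction, replicate)
    truth: pd.DataFrame         # per-protein class label + true fraction values
    tmt_reporters: pd.DataFrame | None = None  # raw reporters (mitotic design)


def _truth_frame(panel, true_values: pd.DataFrame) -> pd.DataFrame:
    meta = pd.DataFrame({
        "class_label": [tr.class_label for tr in panel],
        "trough": [tr.shape.get("trough", "") for tr in panel],
    }, index=pd.Index([tr.name for tr in panel], name="protein_id"))
    return meta.join(true_values.add_prefix("true_"))


def simulate_interphase_dataset(config: SimulationConfig, n_replicates=4,
                                mode="cells") -> SimulatedDataset:
    """Full interphase experiment: G1/S/G2/M ratios over replicates + truth.

    ``mode='cells'`` sorts a sampled population per replicate (gate purity,
    finite-cell averaging); ``mode='expected'`` places fractions exactly at
    their ergodic timeline positions (noise and dropout still apply).
    """
    geometry = CycleGeometry.from_config(config)
    panel = default_interphase_panel(config, geometry)
    rng = config.rng()
    if mode == "expected":
        mat, truth_vals = expected_profile_matrix(
            panel, geometry.timeline_positions(), config, rng=rng,
            n_replicates=n_replicates)
        return SimulatedDataset(mat, _truth_frame(panel, truth_vals))
    if mode != "cells":
        raise ValueError("mode must be 'cells' or 'expected'")
    reps = {}
    truth_vals = None
    for r in range(n_replicates):
        ages = sample_population(config, rng=rng)
        gates = assign_gates(ages, geometry.interphase_edges,
                             INTERPHASE_FRACTIONS, config.gate_purity, rng)
        m, truth_vals = simulate_silac_matrix(
            ages, gates, panel, config, rng=rng, fractions=INTERPHASE_FRACTIONS)
        reps[f"r{r+1}"] = m
    mat = pd.concat(reps, axis=1, names=["replicate", "fraction"])
    mat = mat.swaplevel(axis=1)
    mat.columns.names = ["fraction", "replicate"]
    mat = mat.reindex(columns=pd.MultiIndex.from_product(
        [list(INTERPHASE_FRACTIONS), sorted(reps)],
        names=["fraction", "replicate"]))
    return SimulatedDataset(mat, _truth_frame(panel, truth_vals))


def simulate_mitotic_dataset(config: SimulationConfig, n_silac_replicates=2,
                             with_tmt=True, impurity_matrix=None) -> SimulatedDataset:
    """Intra-mitotic experiment: Pro/PM1/PM2/Ana over three replicates.

    Two replicates are SILAC ratios against the asynchronous standard; the
    third is a raw 6-plex TMT run (channels mapped per DEFAULT_CHANNEL_MAP)
    that the quantitation module must impurity-correct, sum-normalise and
    reference to Pro.  The returned ``matrix`` holds the SILAC replicates;
    ``tmt_reporters`` holds the raw TMT channel intensities.
    """
    geometry = CycleGeometry.from_config(config)
    panel = default_mitotic_panel(config, geometry)
    rng = config.rng()
    reps = {}
    truth_vals = None
    for r in range(n_silac_replicates):
        ages = sample_mitotic_population(config, geometry, rng=rng)
        std_ages = sample_population(config, rng=rng)
        gates = assign_gates(ages, geometry.mitotic_edges, MITOTIC_FRACTIONS,
                             config.gate_purity, rng)
        m, truth_vals = simulate_silac_matrix(
            ages, gates, panel, config, rng=rng,
            fractions=MITOTIC_FRACTIONS, standard_ages=std_ages)
        reps[f"r{r+1}"] = m
    mat = pd.concat(reps, axis=1, names=["replicate", "fraction"])
    mat = mat.swaplevel(axis=1)
    mat.columns.names = ["fraction", "replicate"]
    mat = mat.reindex(columns=pd.MultiIndex.from_product(
        [list(MITOTIC_FRACTIONS), sorted(reps)],
        names=["fraction", "replicate"]))

    tmt = None
    if with_tmt:
        if impurity_matrix is None:
            impurity_matrix = default_impurity_matrix(len(TMT_CHANNELS))
        ages = sample_mitotic_population(config, geometry, rng=rng)
        std_ages = sample_population(config, rng=rng)
        gates = assign_gates(ages, geometry.mitotic_edges, MITOTIC_FRACTIONS,
                             config.gate_purity, rng)
        # the 6-plex also carries G2 and M fractions; emulate them at the
        # ergodic boundary positions of the full-cycle geometry
        noise_free = dataclasses.replace(config, noise_cv=0.0, dropout_rate=0.0)
        m4, _ = simulate_silac_matrix(ages, gates, panel, noise_free, rng=rng,
                                      fractions=MITOTIC_FRACTIONS,
                                      standard_ages=std_ages)
        tG2 = geometry.interphase_edges[-2]
        tM = (geometry.mitotic_edges[0] + geometry.mitotic_edges[-1]) / 2.0
        extra = {}
        for lab, tv in (("G2", tG2), ("M", tM)):
            extra[lab] = [tr.abundance(tv) / tr.population_mean() for tr in panel]
        frac_ab = pd.concat([m4, pd.DataFrame(extra, index=m4.index)], axis=1)
        chan_ab = pd.DataFrame(
            {ch: frac_ab[DEFAULT_CHANNEL_MAP[ch]] for ch in TMT_CHANNELS})
        tmt = simulate_tmt_reporters(chan_ab, impurity_matrix,
                                     config.compression, config, rng=rng)
    return SimulatedDataset(mat, _truth_frame(panel, truth_vals), tmt)


# --------------------------------------------------------------------------
# phosphosite simulation

#: Linear-space profile templates (G1, S, G2, M) per planted site class.
#: Early risers reach higher mitotic ratios than late risers, reflecting
#: their higher CDK phosphorylation propensity.
DEFAULT_SITE_PROFILES = {
    "early_riser": (1.0, 1.1, 3.0, 10.0),
    "late_riser": (1.0, 1.0, 1.0, 5.0),
    "flat": (1.0, 1.0, 1.0, 1.0),
}


def _random_window(rng, centre: str) -> str:
    aa = rng.choice(_AMINO_ACIDS, size=15)
    aa[7] = centre
    return "".join(aa)


def simulate_phosphosites(config: SimulationConfig, rng=None,
                          n_sites=None, n_replicates=2,
                          residue_freqs=(0.832, 0.158, 0.010),
                          cdk_enrichment=0.7, background_proline=0.35):
    """Generate a phospho-site table with planted temporal classes.

    Site classes: ``early_riser`` (already elevated in the G2 fraction,
    maximal in M; sequence windows enriched for the full CDK consensus
    [S/T]-P-x-[K/R]), ``late_riser`` (flat until M) and ``flat``.  Residue
    identities (S/T/Y) are drawn from ``residue_freqs``.  Returns
    ``(meta, quant, truth)``: site metadata with 15-mer windows, a
    site x (fraction, replicate) ratio matrix, and ground-truth labels.
    """
    rng = config.rng() if rng is None else rng
    counts = dict(n_sites or {"early_riser": 120, "late_riser": 240, "flat": 640})
    p = np.asarray(residue_freqs, dtype=float)
    p = p / p.sum()
    fractions = INTERPHASE_FRACTIONS

    rows, profiles, labels = [], [], []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            centre = rng.choice(np.array(["S", "T", "Y"]), p=p)
            window = list(_random_window(rng, centre))
            if cls == "early_riser" and rng.random() < cdk_enrichment:
                if centre == "Y":
                    centre = "S"
                    window[7] = "S"
                window[8] = "P"
                window[10] = rng.choice(np.array(["K", "R"]))
            elif rng.random() < background_proline and centre in ("S", "T"):
                window[8] = "P"
            site_id = f"SITE_{i:05d}"
            rows.append({
                "site_id": site_id,
                "protein_id": f"PHOS_{i % max(counts_total_proteins(counts), 1):04d}",
                "amino_acid": window[7],
                "position": int(rng.integers(1, 900)),
                "sequence_window": "".join(window),
                "localization_prob": float(rng.uniform(0.76, 1.0)),
            })
            profiles.append(DEFAULT_SITE_PROFILES[cls])
            labels.append(cls)
            i += 1

    meta = pd.DataFrame(rows).set_index("site_id")
    true = np.asarray(profiles, dtype=float)
    cols = pd.MultiIndex.from_product(
        [fractions, [f"r{r+1}" for r in range(n_replicates)]],
        names=["fraction", "replicate"])
    vals = np.repeat(true[:, :, None], n_replicates, axis=2).reshape(len(meta), -1)
    quant = pd.DataFrame(_apply_noise(vals, config.noise_cv, rng),
                         index=meta.index, columns=cols)
    quant = _apply_dropout(quant, config, rng)
    truth = pd.DataFrame({"class_label": labels}, index=meta.index).join(
        pd.DataFrame(true, index=meta.index, columns=[f"true_{f}" for f in fractions]))
    return meta, quant, truth


def counts_total_proteins(counts: dict) -> int:
    # a few sites share a protein, as in real phosphoproteomes
    return max(int(sum(counts.values()) * 0.6), 1)
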