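"""Ergodic timing of an asynchronous, exponentially growing cell population.

In a steady-state exponentially growing culture the cell-cycle ages of the
cells are not uniform: newly born cells are twice as frequent as dividing
ones, because every division produces two newborns.  With age expressed as a
fraction ``t`` of the division time (``t = 0`` newborn, ``t = 1`` division),
the age density is

    f(t) = 2 ln2 * 2**(-t),        t in [0, 1],

with CDF ``F(t) = 2 (1 - 2**(-t))``.  Inverting the CDF converts a cumulative
flow-cytometry phase frequency into the population-average cell-cycle
position of that phase's upper boundary,

    t(F) = -log2(1 - F / 2).

Under per-cell exponential content doubling, a cell of age ``t`` carries
``2**t`` relative content units and the population-mean content is
``integral 2**t f(t) dt = 2 ln2``, so the expected measured ratio of a sorted
fraction at position ``t`` against an asynchronous internal standard is
``2**t / (2 ln2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LN2",
    "ASYNC_MEAN_CONTENT",
    "age_density",
    "age_cdf",
    "cumulative_to_time",
    "expected_relative_content",
    "PhaseFrequencyTable",
    "CellCycleTimeline",
    "build_timeline",
]

LN2 = float(np.log(2.0))

#: Population-mean per-cell content of an exponentially doubling species,
#: i.e. the value of the asynchronous internal standard: 2*ln(2).
ASYNC_MEAN_CONTENT = 2.0 * LN2


def _check_unit_interval(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return x


def age_density(t):
    """Probability density of cell-cycle age ``t`` in an asynchronous culture.

    ``f(t) = 2 ln2 * 2**(-t)``; integrates to 1 over [0, 1].
    """
    t = _check_unit_interval(t, "t")
    return 2.0 * LN2 * np.exp2(-t)


def age_cdf(t):
    """CDF of the ergodic age distribution: ``F(t) = 2 (1 - 2**(-t))``."""
    t = _check_unit_interval(t, "t")
    return 2.0 * (1.0 - np.exp2(-t))


def cumulative_to_time(F):
    """Invert the age CDF: cumulative phase frequency -> cell-cycle position.

    ``t = -log2(1 - F/2)``.  Monotone on [0, 1] with t(0)=0 and t(1)=1.
    """
    F = _check_unit_interval(F, "F")
    return -np.log2(1.0 - F / 2.0)


def expected_relative_content(t):
    """Expected sorted-fraction / asynchronous-standard ratio at position ``t``.

    Per-cell content ``2**t`` divided by the population mean ``2 ln2``.
    """
    t = _check_unit_interval(t, "t")
    return np.exp2(t) / ASYNC_MEAN_CONTENT


@dataclass(frozen=True)
class PhaseFrequencyTable:
    """Cumulative phase frequencies from flow cytometry plus the doubling time.

    ``cumulative_freq[i]`` is the fraction of cells at or before the upper
    boundary of ``phases[i]`` (e.g. 0.21, 0.65, 0.92, 0.98 for G1, S, G2, M).
    """

    phases: tuple
    cumulative_freq: tuple
    doubling_time: float = 24.0

    def __post_init__(self):
        if len(self.phases) != len(self.cumulative_freq):
            raise ValueError("phases and cumulative_freq must have equal length")
        F = np.asarray(self.cumulative_freq, dtype=float)
        if np.any(np.diff(F) <= 0):
            raise ValueError("cumulative_freq must be strictly increasing")
        if np.any(F <= 0) or F[-1] > 1.0:
            raise ValueError("cumulative_freq must lie in (0, 1]")
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be positive")
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "cumulative_freq", tuple(float(f) for f in F))


@dataclass(frozen=True)
class CellCycleTimeline:
    """Normalised cell-cycle positions per phase, anchored at birth/division.

    ``t = 0`` is a newly divided cell and ``t = 1`` is cytokinesis; absolute
    time in hours is ``t * doubling_time``.
    """

    phases: tuple
    t: tuple
    doubling_time: float
    hours: tuple = field(init=False)

    def __post_init__(self):
        tv = np.asarray(self.t, dtype=float)
        if np.any(np.diff(tv) <= 0):
            raise ValueError("timeline positions must be strictly increasing")
        _check_unit_interval(tv, "t")
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "t", tuple(float(x) for x in tv))
        object.__setattr__(
            self, "hours", tuple(float(x) * self.doubling_time for x in tv)
        )

    def position(self, phase: str) -> float:
        return self.t[self.phases.index(phase)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"phase": self.phases, "t": self.t, "hours": self.hours}
        )


def build_timeline(freqs: PhaseFrequencyTable) -> CellCycleTimeline:
    """Map a phase-frequency table onto the normalised cell-cycle timeline.

    Each phase is placed at the ergodic position of its cumulative upper
    boundary, with anchors t=0 (newborn) and t=1 (division) prepended and
    appended.  Note that measured frequencies are means over replicates, so a
    printed cumulative frequency rounded at the percent level can shift the
    resulting position by ~0.01.
    """
    t = cumulative_to_time(np.asarray(freqs.cumulative_freq))
    phases = ("newborn",) + tuple(freqs.phases)
    positions = (0.0,) + tuple(float(x) for x in t)
    if positions[-1] < 1.0:
        phases = phases + ("division",)
        positions = positions + (1.0,)
    return CellCycleTimeline(
        phases=phases, t=positions, doubling_time=freqs.doubling_time
    )
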