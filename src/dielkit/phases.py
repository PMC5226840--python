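"""Circular (mod-24) phase arithmetic.

Peak times on a 24 h clock live on a circle, so naive averages and Pearson
correlations misbehave for dawn-straddling values: the average of ZT2 and
ZT22 is ZT0, not ZT12.  This module provides the vector-averaging circular
mean, the dawn-adjustment rule for phase pairs (add 24 h to the smaller
phase when the pair differs by more than 12 h), circular distances,
agreement fractions, 2-D phase-bin contour grids and the adjusted R^2 used
to compare phases between two detectors or datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "PhasePairTable",
    "CircularMeanResult",
    "circular_mean",
    "adjust_pair",
    "phase_distance",
    "phase_intervals",
    "agreement_fraction",
    "phase_histogram",
    "contour_grid",
    "adjusted_r_squared",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class Phase:
    """A time-of-day in ZT hours, reduced mod 24 on construction."""

    hours: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "hours", float(self.hours) % HOURS_PER_DAY)

    def __float__(self) -> float:
        return self.hours


def _as_hours(p) -> float:
    return float(p) % HOURS_PER_DAY


@dataclass(frozen=True)
class PhasePairTable:
    """Rows of (id, phase in dataset A, phase in dataset B)."""

    ids: tuple[str, ...]
    phase_a: np.ndarray
    phase_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.mod(np.asarray(self.phase_a, dtype=float), HOURS_PER_DAY)
        b = np.mod(np.asarray(self.phase_b, dtype=float), HOURS_PER_DAY)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "phase_a", a)
        object.__setattr__(self, "phase_b", b)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in phase pair table")
        if not (len(self.ids) == len(a) == len(b)):
            raise ValueError("ids and phase columns must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float, float]]) -> "PhasePairTable":
        ids, pa, pb = [], [], []
        for i, a, b in records:
            ids.append(i)
            pa.append(a)
            pb.append(b)
        return cls(tuple(ids), np.array(pa, float), np.array(pb, float))


class CircularMeanResult(NamedTuple):
    phase: Phase
    antipodal_tie: bool


def circular_mean(phases: Sequence, return_flag: bool = False):
    """Mean direction of phases on the 24 h circle.

    Each phase maps to a unit vector at angle ``2*pi*h/24``; the mean is
    the direction of the vector sum mapped back to hours.  This reproduces
    the dawn-aware manual rule (ZT2 and ZT22 average to ZT0, not ZT12).
    A perfectly antipodal set has no mean direction; the smaller input
    phase is returned and flagged.
    """
    hours = [_as_hours(p) for p in phases]
    if not hours:
        raise ValueError("circular_mean of empty phase list")
    ang = np.array(hours) * (2 * np.pi / HOURS_PER_DAY)
    s, c = np.sin(ang).sum(), np.cos(ang).sum()
    resultant = math.hypot(s, c) / len(hours)
    if resultant < 1e-9:
        warnings.warn(
            "antipodal phase set has no mean direction; returning the "
            "smaller input phase",
            stacklevel=2,
        )
        result = CircularMeanResult(Phase(min(hours)), True)
    else:
        mean_h = (math.atan2(s, c) * HOURS_PER_DAY / (2 * np.pi)) % HOURS_PER_DAY
        result = CircularMeanResult(Phase(mean_h), False)
    return result if return_flag else result.phase


def adjust_pair(a, b) -> tuple[float, float]:
    """Dawn adjustment for a phase pair before linear correlation.

    When the raw difference exceeds 12 h the pair straddles dawn; 24 h is
    added to the smaller phase, extending the scale past 24 so that e.g.
    (23, 1) becomes (23, 25).  Pairs differing by 12 h or less pass
    through unchanged.
    """
    a, b = _as_hours(a), _as_hours(b)
    if abs(a - b) > 12.0:
        if a < b:
            a += HOURS_PER_DAY
        else:
            b += HOURS_PER_DAY
    return a, b


def phase_distance(a, b) -> float:
    """Shorter arc between two phases, in hours on [0, 12]."""
    d = abs(_as_hours(a) - _as_hours(b)) % HOURS_PER_DAY
    return min(d, HOURS_PER_DAY - d)


class PhaseIntervals(NamedTuple):
    short: float  # shorter arc, [0, 12]
    complement: float  # 24 - short


def phase_intervals(a, b) -> PhaseIntervals:
    """Both circular intervals separating two phases (short arc and its
    24 h complement), e.g. two phase clusters split the day into a
    day-interval and a night-interval."""
    d = phase_distance(a, b)
    return PhaseIntervals(d, HOURS_PER_DAY - d)


def agreement_fraction(pairs: PhasePairTable, window: float = 4.0) -> float:
    """Fraction of pairs whose circular phase distance is within `window`
    hours (the sampling interval, by default)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if len(pairs) == 0:
        raise ValueError("agreement_fraction of empty table")
    d = np.abs(pairs.phase_a - pairs.phase_b) % HOURS_PER_DAY
    d = np.minimum(d, HOURS_PER_DAY - d)
    return float(np.mean(d <= window + 1e-12))


def phase_histogram(phases: Sequence, bin_hours: float = 1.0) -> pd.Series:
    """Counts of phases per half-open bin [lo, lo + bin) labelled by the
    lower edge."""
    if HOURS_PER_DAY % bin_hours:
        raise ValueError("24 must be divisible by bin_hours")
    edges = np.arange(0, HOURS_PER_DAY + bin_hours, bin_hours)
    hours = np.array([_as_hours(p) for p in phases])
    counts, _ = np.histogram(hours, bins=edges)
    return pd.Series(counts, index=edges[:-1], name="count")


def contour_grid(pairs: PhasePairTable, bin_hours: float = 1.0) -> pd.DataFrame:
    """2-D phase-bin count matrix (rows: dataset-A bins, columns:
    dataset-B bins); the tabular equivalent of a phase contour plot.
    Grid total equals the number of pairs."""
    if HOURS_PER_DAY % bin_hours:
        raise ValueError("24 must be divisible by bin_hours")
    edges = np.arange(0, HOURS_PER_DAY + bin_hours, bin_hours)
    counts, _, _ = np.histogram2d(pairs.phase_a, pairs.phase_b, bins=(edges, edges))
    return pd.DataFrame(
        counts.astype(int), index=edges[:-1], columns=edges[:-1]
    )


def adjusted_r_squared(pairs: PhasePairTable) -> float:
    """Squared Pearson correlation of dawn-adjusted phase pairs.

    Every row is passed through `adjust_pair` first, so dawn-straddling
    pairs (e.g. ZT23 vs ZT1) are compared on an extended scale instead of
    appearing maximally discordant.
    """
    if len(pairs) < 3:
        raise ValueError("adjusted_r_squared needs at least 3 pairs")
    adj = np.array([adjust_pair(a, b) for a, b in zip(pairs.phase_a, pairs.phase_b)])
    xa, xb = adj[:, 0], adj[:, 1]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("zero variance after dawn adjustment; R^2 undefined")
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)
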