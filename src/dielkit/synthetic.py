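"""Synthetic diurnal expression time courses with known ground truth.

The generator emulates the statistical structure the detectors assume: a
48 h series sampled every 4 h (ZT0..ZT44), a configurable fraction of
rhythmic genes drawn from five waveform families (cosine, spike, box and
two ramps), periods on [20, 28] h, phases either uniform over the day or
clustered (wrapped normal), additive i.i.d. Gaussian noise, and
multi-dataset scenarios with controlled set overlap and phase shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import TimeCourse

__all__ = [
    "SHAPES",
    "DEFAULT_TIMEPOINTS",
    "PhaseCluster",
    "SyntheticSpec",
    "GroundTruth",
    "make_waveform",
    "generate_dataset",
    "generate_comparative_scenario",
]

SHAPES = ("cosine", "spike", "box", "ramp_up", "ramp_down")

#: 48 h sampled every 4 h: the 12-timepoint ZT0..ZT44 grid.
DEFAULT_TIMEPOINTS: tuple[float, ...] = tuple(float(t) for t in range(0, 48, 4))


@dataclass(frozen=True)
class PhaseCluster:
    """A wrapped-normal phase cohort: mean ZT hour, SD in hours, weight."""

    mean: float
    sd: float
    weight: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a liver-style diurnal time course: 2000 genes of
    which ~11% are rhythmic, 24 h cosine-dominated shape mix, uniform
    phases, amplitude 1 around baseline 8 (log2-intensity scale) and
    noise SD 0.25.
    """

    n_genes: int = 2000
    frac_rhythmic: float = 0.11
    shapes: dict[str, float] = field(
        default_factory=lambda: {
            "cosine": 0.6,
            "spike": 0.1,
            "box": 0.1,
            "ramp_up": 0.1,
            "ramp_down": 0.1,
        }
    )
    period_choices: tuple[float, ...] = (24.0,)
    phase_clusters: tuple[PhaseCluster, ...] | None = None  # None = uniform
    phase_grid: float | None = None  # snap true phases to this step (hours)
    amplitude: float = 1.0
    baseline: float = 8.0
    noise_sd: float = 0.25
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_rhythmic <= 1:
            raise ValueError("frac_rhythmic must be in [0, 1]")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        unknown = set(self.shapes) - set(SHAPES)
        if unknown:
            raise ValueError(f"unknown shapes: {sorted(unknown)}")
        total = sum(self.shapes.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"shape weights must sum to 1, got {total}")
        for p in self.period_choices:
            if not 20 <= p <= 28:
                raise ValueError(f"period {p} outside [20, 28] h")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene truth: rhythmicity flag, shape, period, phase, amplitude."""

    table: pd.DataFrame  # index: gene id; columns below

    COLUMNS = ("is_rhythmic", "shape", "period", "phase", "amplitude")

    def rhythmic_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_rhythmic"]])

    def phase_of(self, gene_id: str) -> float:
        return float(self.table.loc[gene_id, "phase"])


def make_waveform(
    shape: str,
    period: float,
    phase: float,
    timepoints: Sequence[float],
) -> np.ndarray:
    """Evaluate a unit-amplitude periodic waveform on a sampling grid.

    All shapes peak at ``t == phase (mod period)``:

    - ``cosine``: cos(2*pi*(t - phase)/period).
    - ``spike``: 1 at the grid position nearest the phase within each
      cycle (ties to the earlier position), 0 elsewhere.
    - ``box``: 1 on the half-open half-period [phase, phase + period/2)
      on the circle, 0 elsewhere.
    - ``ramp_up``: sawtooth rising linearly over one period to its
      maximum at the phase.
    - ``ramp_down``: sawtooth decaying linearly from its maximum at the
      phase over one period.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 <= phase < 24:
        raise ValueError("phase must be in [0, 24)")
    t = np.asarray(timepoints, dtype=float)
    rel = np.mod(t - phase, period)  # hours since the last peak
    if shape == "cosine":
        return np.cos(2 * np.pi * rel / period)
    if shape == "box":
        return (rel < period / 2).astype(float)
    if shape == "ramp_up":
        # sawtooth rising over one period; maximum reached exactly at the peak
        return np.where(rel == 0, 1.0, rel / period)
    if shape == "ramp_down":
        return 1.0 - rel / period
    if shape == "spike":
        # assign each sample to its nearest peak occurrence, then mark the
        # closest sample of each occurrence; ties resolve to the earlier one
        dist = np.minimum(rel, period - rel)
        peak_time = np.round(t - np.where(rel <= period / 2, rel, rel - period), 9)
        out = np.zeros_like(t)
        for pk in np.unique(peak_time):
            idx = np.where(peak_time == pk)[0]
            out[idx[np.argmin(dist[idx])]] = 1.0
        return out
    raise ValueError(f"unknown shape {shape!r}")


def _draw_phases(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.phase_clusters is None:
        phases = rng.uniform(0.0, 24.0, size=n)
    else:
        weights = np.array([c.weight for c in spec.phase_clusters], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(spec.phase_clusters), size=n, p=weights)
        means = np.array([c.mean for c in spec.phase_clusters])
        sds = np.array([c.sd for c in spec.phase_clusters])
        phases = np.mod(rng.normal(means[which], sds[which]), 24.0)
    if spec.phase_grid is not None:
        phases = np.mod(np.round(phases / spec.phase_grid) * spec.phase_grid, 24.0)
    return phases


def generate_dataset(
    spec: SyntheticSpec, id_prefix: str = "g"
) -> tuple[TimeCourse, GroundTruth]:
    """Generate one expression matrix plus its ground truth.

    Rhythmic rows are ``baseline + amplitude * waveform + N(0, noise_sd)``;
    arrhythmic rows are ``baseline + N(0, noise_sd)``.  The number of
    rhythmic genes is ``round(frac_rhythmic * n_genes)`` and the same seed
    always reproduces the same matrix bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    n_rhythmic = int(round(spec.frac_rhythmic * spec.n_genes))
    ids = tuple(f"{id_prefix}{i:05d}" for i in range(spec.n_genes))
    t = np.asarray(spec.timepoints, dtype=float)

    shape_names = list(spec.shapes)
    shape_w = np.array([spec.shapes[s] for s in shape_names], dtype=float)
    shapes = [shape_names[k] for k in rng.choice(len(shape_names), size=n_rhythmic, p=shape_w)]
    periods = np.asarray(spec.period_choices, dtype=float)[
        rng.integers(0, len(spec.period_choices), size=n_rhythmic)
    ]
    phases = _draw_phases(spec, n_rhythmic, rng)

    signal = np.full((spec.n_genes, len(t)), float(spec.baseline))
    for i in range(n_rhythmic):
        signal[i] += spec.amplitude * make_waveform(shapes[i], periods[i], phases[i], t)
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
    values = signal + noise

    truth = pd.DataFrame(
        {
            "is_rhythmic": [i < n_rhythmic for i in range(spec.n_genes)],
            "shape": [shapes[i] if i < n_rhythmic else "" for i in range(spec.n_genes)],
            "period": [periods[i] if i < n_rhythmic else np.nan for i in range(spec.n_genes)],
            "phase": [phases[i] if i < n_rhythmic else np.nan for i in range(spec.n_genes)],
            "amplitude": [
                spec.amplitude if i < n_rhythmic else 0.0 for i in range(spec.n_genes)
            ],
        },
        index=list(ids),
    )
    interval = float(t[1] - t[0])
    return TimeCourse(ids, tuple(t), values, interval), GroundTruth(truth)


def generate_comparative_scenario(
    n_shared: int,
    n_only_a: int,
    n_only_b: int,
    phase_shift: float,
    spec: SyntheticSpec,
) -> tuple[TimeCourse, TimeCourse, GroundTruth, GroundTruth]:
    """Two datasets with a controlled rhythmic-set overlap and phase shift.

    Shared genes are rhythmic in both datasets with dataset-B phase equal
    to dataset-A phase plus `phase_shift` (mod 24); exclusive genes are
    rhythmic in exactly one dataset (flat baseline + noise in the other).
    Shapes, periods, amplitude, baseline, noise and timepoints come from
    `spec`; `spec.n_genes` and `spec.frac_rhythmic` are ignored in favour
    of the explicit counts.
    """
    if min(n_shared, n_only_a, n_only_b) < 0:
        raise ValueError("counts must be non-negative")
    n_total = n_shared + n_only_a + n_only_b
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    interval = float(t[1] - t[0])

    ids = tuple(
        [f"s{i:05d}" for i in range(n_shared)]
        + [f"a{i:05d}" for i in range(n_only_a)]
        + [f"b{i:05d}" for i in range(n_only_b)]
    )
    shape_names = list(spec.shapes)
    shape_w = np.array([spec.shapes[s] for s in shape_names], dtype=float)
    shapes = [shape_names[k] for k in rng.choice(len(shape_names), size=n_total, p=shape_w)]
    periods = np.asarray(spec.period_choices, dtype=float)[
        rng.integers(0, len(spec.period_choices), size=n_total)
    ]
    phases_a = _draw_phases(spec, n_total, rng)
    phases_b = np.mod(phases_a + phase_shift, 24.0)
    if spec.phase_grid is not None:
        phases_b = np.mod(np.round(phases_b / spec.phase_grid) * spec.phase_grid, 24.0)

    rhythmic_in_a = np.array([True] * (n_shared + n_only_a) + [False] * n_only_b)
    rhythmic_in_b = np.array(
        [True] * n_shared + [False] * n_only_a + [True] * n_only_b
    )

    def build(rhythmic: np.ndarray, phases: np.ndarray) -> tuple[TimeCourse, GroundTruth]:
        signal = np.full((n_total, len(t)), float(spec.baseline))
        for i in range(n_total):
            if rhythmic[i]:
                signal[i] += spec.amplitude * make_waveform(
                    shapes[i], periods[i], phases[i], t
                )
        noise = (
            rng.normal(0.0, spec.noise_sd, size=signal.shape)
            if spec.noise_sd > 0
            else 0.0
        )
        truth = pd.DataFrame(
            {
                "is_rhythmic": rhythmic,
                "shape": [shapes[i] if rhythmic[i] else "" for i in range(n_total)],
                "period": [periods[i] if rhythmic[i] else np.nan for i in range(n_total)],
                "phase": [phases[i] if rhythmic[i] else np.nan for i in range(n_total)],
                "amplitude": [spec.amplitude if rhythmic[i] else 0.0 for i in range(n_total)],
            },
            index=list(ids),
        )
        return TimeCourse(ids, tuple(t), signal + noise, interval), GroundTruth(truth)

    tc_a, truth_a = build(rhythmic_in_a, phases_a)
    tc_b, truth_b = build(rhythmic_in_b, phases_b)
    return tc_a, tc_b, truth_a, truth_b
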