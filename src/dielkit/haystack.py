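"""Model-based pattern-matching rhythm detection.

Each gene's series is regressed (ordinary least squares) against a library
of candidate diurnal waveforms — five shape families (cosine, spike, box,
ramp up, ramp down) at 24 possible peak phases, period fixed at 24 h — and
scored by the Pearson correlation with the best-fitting pattern.  A gene
is called rhythmic when its best correlation clears both the fixed cutoff
(0.81 by default) and, optionally, a permutation-derived top-percentile
threshold: row time labels are shuffled to build a null distribution of
best-pattern correlations and the observed correlation must land in the
top q% of that null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import RhythmCall, TimeCourse
from .synthetic import SHAPES, make_waveform

logger = logging.getLogger("dielkit")

__all__ = [
    "ModelPattern",
    "HaystackFit",
    "HaystackConfig",
    "build_model_library",
    "score_gene",
    "best_fits",
    "permutation_threshold",
    "call_rhythmic_haystack",
]

DEFAULT_CUTOFF = 0.81
DEFAULT_TOP_PERCENT = 5.0
PHASES = tuple(range(24))
PERIOD = 24.0


@dataclass(frozen=True)
class ModelPattern:
    """One candidate waveform evaluated on the sampling grid."""

    shape: str
    period: float
    phase: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.ptp(v) == 0:
            raise ValueError(f"constant pattern {self.shape}@{self.phase}")


@dataclass(frozen=True)
class HaystackFit:
    """Best-pattern fit for one gene."""

    id: str
    shape: str
    phase: int
    r: float
    slope: float
    intercept: float
    pass_cutoff: bool = False


@dataclass(frozen=True)
class HaystackConfig:
    cutoff: float = DEFAULT_CUTOFF
    top_percent: float = DEFAULT_TOP_PERCENT
    n_perm: int = 200
    seed: int = 0
    shapes: tuple[str, ...] = SHAPES
    # "conjunction": r >= max(cutoff, permutation threshold)  [default]
    # "cutoff_only": fixed correlation cutoff alone
    # "permutation_only": permutation top-percentile alone
    # "top_fraction": top q% of genes ranked by r (no permutations)
    criterion: str = "conjunction"
    min_fold_change: float | None = None  # optional amplitude filter, off by default


def build_model_library(
    timepoints: Sequence[float], shapes: Sequence[str] = SHAPES
) -> list[ModelPattern]:
    """All (shape, phase) candidate patterns on the given grid, ordered by
    shape then phase.  Patterns that are constant on the grid are dropped
    with a logged warning."""
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints")
    library: list[ModelPattern] = []
    for shape in shapes:
        for phase in PHASES:
            values = make_waveform(shape, PERIOD, float(phase), t)
            if np.ptp(values) == 0:
                logger.warning("dropping constant pattern %s@ZT%d", shape, phase)
                continue
            library.append(ModelPattern(shape, PERIOD, phase, values))
    return library


def score_gene(y: np.ndarray, pattern: ModelPattern) -> tuple[float, float, float]:
    """OLS fit of an expression series on one pattern.

    Returns (Pearson r, slope, intercept).  A constant series has no
    defined correlation and scores r = 0.
    """
    y = np.asarray(y, dtype=float)
    x = pattern.values
    if len(y) != len(x):
        raise ValueError("series and pattern are on different grids")
    if np.ptp(y) == 0:
        return 0.0, 0.0, float(y[0])
    sx, sy = x.std(), y.std()
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    slope = r * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return r, float(slope), intercept


def _correlation_matrix(values: np.ndarray, library: Sequence[ModelPattern]) -> np.ndarray:
    """Pearson r of every gene (rows) against every pattern (columns)."""
    pat = np.stack([p.values for p in library])  # P x T
    n = values.shape[1]
    yz = values - values.mean(axis=1, keepdims=True)
    ysd = yz.std(axis=1)
    constant = ysd == 0
    ysd[constant] = 1.0
    yz /= ysd[:, None]
    pz = pat - pat.mean(axis=1, keepdims=True)
    pz /= pz.std(axis=1)[:, None]
    r = yz @ pz.T / n
    r[constant] = 0.0
    return r


def best_fits(tc: TimeCourse, library: Sequence[ModelPattern]) -> list[HaystackFit]:
    """Best-correlating pattern per gene; ties broken by library order
    (shape order, then lower phase)."""
    r = _correlation_matrix(tc.values, library)
    best_idx = np.argmax(r, axis=1)  # argmax takes the first maximum: tie rule
    fits = []
    for g, gene_id in enumerate(tc.ids):
        p = library[best_idx[g]]
        rg, slope, intercept = score_gene(tc.values[g], p)
        fits.append(HaystackFit(gene_id, p.shape, p.phase, rg, slope, intercept))
    return fits


def permutation_threshold(
    tc: TimeCourse,
    library: Sequence[ModelPattern],
    n_perm: int = 200,
    q: float = DEFAULT_TOP_PERCENT,
    seed: int = 0,
) -> float:
    """Correlation threshold from a within-gene permutation null.

    For each permutation round the time labels of every row are shuffled
    independently and the best-pattern correlation recomputed; the
    threshold is the (100 - q)th percentile of the pooled null best
    correlations, so observed correlations above it sit in the top q% of
    what label-shuffled (arrhythmic) data achieves.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    null_best = np.empty((n_perm, tc.n_genes))
    for k in range(n_perm):
        shuffled = rng.permuted(tc.values, axis=1)
        null_best[k] = _correlation_matrix(shuffled, library).max(axis=1)
    return float(np.percentile(null_best.ravel(), 100.0 - q))


def call_rhythmic_haystack(
    tc: TimeCourse, config: HaystackConfig = HaystackConfig()
) -> list[RhythmCall]:
    """Run the pattern-matching detector over a full time course.

    Under the default conjunctive criterion a gene is rhythmic iff its
    best correlation r satisfies ``r >= max(cutoff, permutation
    threshold)``; the call records the winning pattern's phase and shape,
    the 24 h model period and r as the score.
    """
    library = build_model_library(tc.timepoints, config.shapes)
    fits = best_fits(tc, library)
    r_values = np.array([f.r for f in fits])

    if config.criterion == "cutoff_only":
        threshold = config.cutoff
    elif config.criterion == "permutation_only":
        threshold = permutation_threshold(
            tc, library, config.n_perm, config.top_percent, config.seed
        )
    elif config.criterion == "conjunction":
        perm = permutation_threshold(
            tc, library, config.n_perm, config.top_percent, config.seed
        )
        threshold = max(config.cutoff, perm)
    elif config.criterion == "top_fraction":
        threshold = max(
            config.cutoff, float(np.percentile(r_values, 100.0 - config.top_percent))
        )
    else:
        raise ValueError(f"unknown criterion {config.criterion!r}")

    calls: list[RhythmCall] = []
    for fit, r in zip(fits, r_values):
        if r < threshold or r <= 0:
            continue
        if config.min_fold_change is not None:
            y = tc.values[tc.ids.index(fit.id)]
            low = max(y.min(), 1e-12)
            if y.max() / low < config.min_fold_change:
                continue
        calls.append(
            RhythmCall(
                id=fit.id,
                method="haystack",
                phase=float(fit.phase),
                period=PERIOD,
                shape=fit.shape,
                score=fit.r,
            )
        )
    return calls
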