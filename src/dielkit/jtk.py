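"""Nonparametric periodicity detection with Kendall's S and exact p-values.

Each gene's series is compared by rank concordance (Kendall's S, the
signed count of concordant minus discordant pairs) against reference
orderings derived from cosines over a lattice of candidate periods (the
4 h-grid-representable periods in 20-28 h: 20, 24, 28) and lags (one per
timepoint within the period).  Because the reference orderings are fixed,
the null distribution of S under random untied data is known exactly and
is computed by generating-function convolution (the Jonckheere-Terpstra
construction over the reference's tie groups).  Per gene the (period, lag)
pair maximising |S| is chosen, its two-sided exact p-value is
Bonferroni-adjusted for the number of combinations tested, and the gene is
called rhythmic when the adjusted p falls below alpha (0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .dataio import RhythmCall, TimeCourse

__all__ = [
    "ReferenceOrdering",
    "JtkResult",
    "reference_ordering",
    "build_reference_set",
    "kendall_s",
    "exact_null",
    "sf_abs_s",
    "call_rhythmic_jtk",
    "DEFAULT_PERIODS",
    "DEFAULT_ALPHA",
]

DEFAULT_PERIODS = (20.0, 24.0, 28.0)
DEFAULT_ALPHA = 0.05
MAX_N = 60  # guard for the exact-null convolution


@dataclass(frozen=True)
class ReferenceOrdering:
    """Rank template of a reference cosine at one (period, lag)."""

    period: float
    lag: float
    ranks: np.ndarray  # average ranks, ties shared
    tie_groups: tuple[int, ...]  # sizes of tie groups in rank order

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=float))


@dataclass(frozen=True)
class JtkResult:
    id: str
    period: float
    lag: float  # reported phase = lag mod 24, ZT hours
    s: int
    p_value: float
    adjusted_p: float


def reference_ordering(
    period: float, lag: float, timepoints: Sequence[float]
) -> ReferenceOrdering:
    """Ranks of ``cos(2*pi*(t - lag)/period)`` on the sampling grid, with
    average ranks for ties.  The reference peaks at t = lag, so a gene
    concordant with it has acrophase at the lag."""
    t = np.asarray(timepoints, dtype=float)
    interval = t[1] - t[0]
    if period <= 0 or abs(period / interval - round(period / interval)) > 1e-9:
        raise ValueError(f"period {period} not representable on a {interval} h grid")
    ref = np.cos(2 * np.pi * (t - lag) / period)
    ref = np.round(ref, 12)  # collapse floating noise so symmetric points tie
    ranks = rankdata(ref, method="average")
    _, counts = np.unique(ref, return_counts=True)
    return ReferenceOrdering(period, float(lag), ranks, tuple(int(c) for c in counts))


def build_reference_set(
    timepoints: Sequence[float], periods: Sequence[float] = DEFAULT_PERIODS
) -> list[ReferenceOrdering]:
    """One ordering per (period, lag): lags step through the period at the
    sampling interval."""
    t = np.asarray(timepoints, dtype=float)
    interval = float(t[1] - t[0])
    refs = []
    for period in periods:
        n_lags = int(round(period / interval))
        for k in range(n_lags):
            refs.append(reference_ordering(period, k * interval, t))
    return refs


def kendall_s(y: Sequence[float], ref: ReferenceOrdering) -> int:
    """Kendall's S of a series against a reference ordering: the sum over
    pairs of ``sign(y_j - y_i) * sign(ref_j - ref_i)``; pairs tied in
    either vector contribute zero."""
    y = np.asarray(y, dtype=float)
    r = ref.ranks
    if len(y) != len(r):
        raise ValueError("series and reference are on different grids")
    dy = np.sign(y[None, :] - y[:, None])
    dr = np.sign(r[None, :] - r[:, None])
    return int(np.sum(np.triu(dy * dr, k=1)))


@lru_cache(maxsize=128)
def exact_null(tie_groups: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of S under uniformly random untied data.

    With the reference's tie groups fixed, only the M pairs untied in the
    reference contribute; the concordant-pair count is distributed as the
    Jonckheere-Terpstra statistic, whose generating function is the
    Gaussian (q-) multinomial coefficient over the group sizes.  Returns
    ``(support, pmf)`` with S = 2*C - M on support of step 2.
    """
    n = sum(tie_groups)
    if n > MAX_N:
        raise ValueError(f"n={n} exceeds exact-null guard {MAX_N}")
    # integer polynomial in q: product of Gaussian binomials
    # [m + g choose g]_q accumulated over the groups
    coeffs = [1]
    m = 0
    for g in tie_groups:
        coeffs = _gauss_binom_multiply(coeffs, m, g)
        m += g
    total = sum(coeffs)
    n_pairs = n * (n - 1) // 2
    tied_pairs = sum(g * (g - 1) // 2 for g in tie_groups)
    max_c = n_pairs - tied_pairs  # M
    assert len(coeffs) == max_c + 1
    support = 2 * np.arange(max_c + 1) - max_c  # S values
    pmf = np.array([c / total for c in coeffs], dtype=float)
    return support, pmf


def _gauss_binom_multiply(coeffs: list[int], m: int, g: int) -> list[int]:
    """Multiply an integer polynomial by the Gaussian binomial
    [m+g choose g]_q (exact integer convolution)."""
    gb = [1]
    # [a+1 choose 1]_q = 1 + q + ... + q^a ; build up the binomial by the
    # q-Pascal recurrence over g factors with denominator cancellation:
    # [m+k choose k]_q = [m+k-1 choose k-1]_q * (1-q^{m+k})/(1-q^k)
    for k in range(1, g + 1):
        num_exp = m + k
        # multiply by (1 - q^num_exp)
        prod = [0] * (len(gb) + num_exp)
        for i, c in enumerate(gb):
            prod[i] += c
            prod[i + num_exp] -= c
        # divide by (1 - q^k): synthetic division, exact
        quot = [0] * (len(prod) - k)
        for i in range(len(quot)):
            quot[i] = prod[i] + (quot[i - k] if i >= k else 0)
        # verify remainder is zero on the trailing k coefficients
        for i in range(len(quot), len(prod)):
            rem = prod[i] + (quot[i - k] if 0 <= i - k < len(quot) else 0)
            if rem != 0:
                raise AssertionError("non-exact Gaussian binomial division")
        gb = quot
    # convolve running polynomial with the binomial
    out = [0] * (len(coeffs) + len(gb) - 1)
    for i, a in enumerate(coeffs):
        if a:
            for j, b in enumerate(gb):
                out[i + j] += a * b
    return out


def sf_abs_s(s: int, tie_groups: tuple[int, ...]) -> float:
    """Two-sided exact p-value: P(|S| >= |s|) under the null."""
    support, pmf = exact_null(tuple(tie_groups))
    return float(pmf[np.abs(support) >= abs(s)].sum())


def _sign_diff_tensor(values: np.ndarray) -> np.ndarray:
    return np.sign(values[:, None, :] - values[:, :, None])


def call_rhythmic_jtk(
    tc: TimeCourse,
    periods: Sequence[float] = DEFAULT_PERIODS,
    alpha: float = DEFAULT_ALPHA,
    return_results: bool = False,
):
    """Run the rank-concordance detector over a full time course.

    Per gene, S is computed against every (period, lag) reference; the
    combination maximising |S| wins (ties: lower period, then lower lag).
    The exact two-sided p-value of the winning S is multiplied by the
    number of combinations tested (Bonferroni) and the gene is called
    rhythmic when the adjusted p is below `alpha`.  Reported phase is the
    winning lag mod 24.
    """
    refs = build_reference_set(tc.timepoints, periods)
    n_combo = len(refs)
    dy = _sign_diff_tensor(tc.values)  # G x T x T
    iu = np.triu_indices(len(tc.timepoints), k=1)
    dy_u = dy[:, iu[0], iu[1]]  # G x P(pairs)

    s_matrix = np.empty((tc.n_genes, n_combo))
    for j, ref in enumerate(refs):
        dr = np.sign(ref.ranks[None, :] - ref.ranks[:, None])[iu]
        s_matrix[:, j] = dy_u @ dr

    best_j = np.argmax(np.abs(s_matrix), axis=1)  # first max: (period, lag) tie rule
    results: list[JtkResult] = []
    calls: list[RhythmCall] = []
    for g, gene_id in enumerate(tc.ids):
        ref = refs[best_j[g]]
        s = int(s_matrix[g, best_j[g]])
        p = sf_abs_s(s, ref.tie_groups)
        adj = min(1.0, p * n_combo)
        results.append(JtkResult(gene_id, ref.period, ref.lag, s, p, adj))
        if adj < alpha:
            phase = ref.lag % 24.0
            if s < 0:  # anti-phase concordance: peak half a period away
                phase = (ref.lag + ref.period / 2.0) % 24.0
            calls.append(
                RhythmCall(
                    id=gene_id,
                    method="jtk",
                    phase=phase,
                    period=ref.period,
                    shape=None,
                    score=float(s),
                    p_value=adj,
                )
            )
    if return_results:
        return calls, results
    return calls
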