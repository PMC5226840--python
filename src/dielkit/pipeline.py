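"""End-to-end orchestration: run both detectors, merge their calls, and
compare call sets across datasets into a machine-readable report.

The run report is a plain dict (JSON-serialisable) whose every number is
recomputable from the emitted call tables: per-detector counts and genome
fractions, the Venn partition of the two hit sets, the merged call list,
a phase histogram, and — when two datasets are compared — the Jaccard
index, phase agreement fraction, contour grid and dawn-adjusted R^2.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .dataio import GeneSet, IdMapping, RhythmCall, TimeCourse
from .haystack import HaystackConfig, call_rhythmic_haystack
from .idmap import map_orthologs
from .jtk import DEFAULT_ALPHA, DEFAULT_PERIODS, call_rhythmic_jtk
from .phases import (
    PhasePairTable,
    adjusted_r_squared,
    agreement_fraction,
    circular_mean,
    contour_grid,
    phase_histogram,
)
from .setcompare import jaccard100_from_sizes, round_half_up, venn_counts

logger = logging.getLogger("dielkit")

__all__ = ["PipelineConfig", "genome_fraction", "merge_calls", "run_detection", "run_comparison"]


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults follow standard settings for a 4 h diurnal series:
    correlation cutoff 0.81 with a top-5% permutation rule, rank-test
    periods 20-28 h at alpha 0.05, and a 4 h phase-agreement window."""

    haystack: HaystackConfig = field(default_factory=HaystackConfig)
    jtk_periods: tuple[float, ...] = DEFAULT_PERIODS
    jtk_alpha: float = DEFAULT_ALPHA
    agreement_window: float = 4.0
    contour_bin: float = 1.0
    histogram_bin: float = 1.0
    common_threshold: int = 4
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {**asdict(self), "haystack": asdict(self.haystack)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def genome_fraction(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of the interrogated transcriptome, half-up rounded the
    way summary fractions are printed (one decimal unless it lands on an
    integer, so 2175/23635 -> 9.2 and 1192/23635 -> 5.0)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def merge_calls(
    haystack_calls: list[RhythmCall], jtk_calls: list[RhythmCall]
) -> list[RhythmCall]:
    """Union of the two detectors' calls, one record per id.

    For ids found by both, the pattern-matching call supplies phase and
    shape (its 1 h phase lattice is finer than the rank test's 4 h lag
    lattice) and the rank test supplies the period; the method is tagged
    "haystack+jtk".
    """
    by_id_h = {c.id: c for c in haystack_calls}
    by_id_j = {c.id: c for c in jtk_calls}
    merged: list[RhythmCall] = []
    for gene_id in sorted(set(by_id_h) | set(by_id_j)):
        h, j = by_id_h.get(gene_id), by_id_j.get(gene_id)
        if h and j:
            merged.append(
                RhythmCall(
                    id=gene_id,
                    method="haystack+jtk",
                    phase=h.phase,
                    period=j.period,
                    shape=h.shape,
                    score=h.score,
                    p_value=j.p_value,
                )
            )
        else:
            merged.append(h or j)
    return merged


def run_detection(
    tc: TimeCourse, config: PipelineConfig = PipelineConfig()
) -> dict:
    """Run both detectors on one time course and assemble the run report."""
    logger.info(
        "run_detection: %d genes, seed=%d, config=%s",
        tc.n_genes,
        config.seed,
        config.digest(),
    )
    h_calls = call_rhythmic_haystack(tc, config.haystack)
    j_calls = call_rhythmic_jtk(tc, config.jtk_periods, config.jtk_alpha)
    merged = merge_calls(h_calls, j_calls)

    h_set = {c.id for c in h_calls}
    j_set = {c.id for c in j_calls}
    both = h_set & j_set
    total = tc.n_genes
    hist = phase_histogram([c.phase for c in merged], config.histogram_bin)
    report = {
        "n_genes": total,
        "haystack": {
            "n_calls": len(h_calls),
            "genome_fraction_pct": genome_fraction(len(h_calls), total),
        },
        "jtk": {
            "n_calls": len(j_calls),
            "genome_fraction_pct": genome_fraction(len(j_calls), total),
        },
        "common": len(both),
        "union": len(h_set | j_set),
        "union_fraction_pct": genome_fraction(len(h_set | j_set), total),
        "haystack_only": len(h_set - j_set),
        "jtk_only": len(j_set - h_set),
        "phase_histogram": {f"{k:g}": int(v) for k, v in hist.items()},
        "config": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    assert (
        report["haystack_only"] + report["common"] + report["jtk_only"]
        == report["union"]
    )
    return {"report": report, "haystack_calls": h_calls, "jtk_calls": j_calls, "merged_calls": merged}


def run_comparison(
    calls_a: list[RhythmCall],
    calls_b: list[RhythmCall],
    ortholog_mapping: IdMapping | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Compare two call tables: Venn partition, Jaccard index, and — on the
    shared genes — phase agreement, contour grid and dawn-adjusted R^2.

    If `ortholog_mapping` is given, dataset-A ids are first translated to
    their (deduplicated) ortholog targets so cross-species sets live in a
    common identifier space; the phase of a multi-target gene propagates
    to each target, and targets hit by several sources take the circular
    mean phase.
    """
    if not calls_a or not calls_b:
        raise ValueError("both call tables must be non-empty")
    phases_a: dict[str, float] = {}
    if ortholog_mapping is not None:
        targets = ortholog_mapping.as_dict()
        collected: dict[str, list[float]] = {}
        for c in calls_a:
            for t in targets.get(c.id, []):
                collected.setdefault(t, []).append(c.phase)
        phases_a = {t: float(circular_mean(v)) for t, v in collected.items()}
        set_a, _ = map_orthologs(
            GeneSet("a", frozenset(c.id for c in calls_a)), ortholog_mapping
        )
    else:
        phases_a = {c.id: c.phase for c in calls_a}
        set_a = GeneSet("a", frozenset(phases_a))
    phases_b = {c.id: c.phase for c in calls_b}
    set_b = GeneSet("b", frozenset(phases_b))

    venn = venn_counts(set_a, set_b)
    block: dict = {
        "a_only": venn.a_only,
        "common": venn.common,
        "b_only": venn.b_only,
        "union": venn.union,
    }
    if venn.common == 0:
        block["jaccard100"] = 0.0
        block["agreement_fraction"] = None
        block["agreement_undefined"] = True
        return block
    block["jaccard100"] = jaccard100_from_sizes(len(set_a), len(set_b), venn.common)
    shared = sorted(set_a.members & set_b.members)
    pairs = PhasePairTable(
        tuple(shared),
        np.array([phases_a[g] for g in shared]),
        np.array([phases_b[g] for g in shared]),
    )
    block["agreement_fraction"] = agreement_fraction(pairs, config.agreement_window)
    grid = contour_grid(pairs, config.contour_bin)
    block["contour_grid"] = grid.values.tolist()
    if len(pairs) >= 3:
        try:
            block["adjusted_r_squared"] = round_half_up(
                adjusted_r_squared(pairs), 2
            )
        except ValueError:
            block["adjusted_r_squared"] = None
    return block
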