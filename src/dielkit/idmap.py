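"""Identifier collapsing: transcripts to genes, genes to orthologs.

Array probesets interrogate transcripts; comparative analysis happens at
the gene (and cross-species at the ortholog) level.  Transcript-level
rhythm calls collapsing to one gene are merged into a single record whose
phase is the circular mean of the member phases (dawn-aware); a transcript
mapped to several genes contributes to each of them.  Ortholog joining
takes the deduplicated union of mapped targets.  Both operations report
input/mapped/multi-mapped/unmapped counts that reconcile exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .dataio import GeneSet, IdMapping, RhythmCall
from .phases import circular_mean

__all__ = ["CollapseReport", "collapse_transcripts_to_genes", "map_orthologs"]

#: preference order when merged transcripts disagree on the detection method
_METHOD_PRIORITY = {"haystack": 0, "jtk": 1}


@dataclass(frozen=True)
class CollapseReport:
    input_count: int
    output_count: int
    multi_mapped_count: int
    unmapped_count: int

    def __post_init__(self) -> None:
        if min(
            self.input_count,
            self.output_count,
            self.multi_mapped_count,
            self.unmapped_count,
        ) < 0:
            raise ValueError("negative report count")


def _modal(values, keys):
    """Most frequent value; ties broken by the paired sort keys."""
    counts = Counter(values)
    top = max(counts.values())
    candidates = [v for v in counts if counts[v] == top]
    return min(candidates, key=lambda v: keys[v])


def collapse_transcripts_to_genes(
    calls: list[RhythmCall], mapping: IdMapping
) -> tuple[list[RhythmCall], CollapseReport]:
    """Merge transcript-level calls into gene-level records.

    Phases merge by circular mean (so ZT2 and ZT22 average to ZT0, not
    ZT12).  When members disagree on period or shape the modal value wins;
    ties prefer the pattern-matching (haystack) entry, then the lower
    period.  Unmapped transcripts are dropped and counted; a transcript
    with k gene targets feeds k gene records.
    """
    targets = mapping.as_dict()
    per_gene: dict[str, list[RhythmCall]] = {}
    unmapped = 0
    multi = 0
    for call in calls:
        genes = targets.get(call.id, [])
        if not genes:
            unmapped += 1
            continue
        if len(genes) > 1:
            multi += 1
        for g in genes:
            per_gene.setdefault(g, []).append(call)
    if not per_gene and calls:
        raise ValueError("mapping covers none of the calls")

    merged: list[RhythmCall] = []
    for gene in sorted(per_gene):
        members = per_gene[gene]
        phase = float(circular_mean([m.phase for m in members]))
        period_keys = {m.period: (m.period,) for m in members}
        period = _modal([m.period for m in members], period_keys)
        shape_keys: dict = {}
        for m in members:
            key = (_METHOD_PRIORITY.get(m.method, 9), m.period)
            if m.shape not in shape_keys or key < shape_keys[m.shape]:
                shape_keys[m.shape] = key
        shape = _modal([m.shape for m in members], shape_keys)
        method = "+".join(sorted({m.method for m in members}))
        scores = [m.score for m in members if m.score is not None]
        merged.append(
            RhythmCall(
                id=gene,
                method=method,
                phase=phase,
                period=period,
                shape=shape,
                score=max(scores) if scores else None,
            )
        )
    report = CollapseReport(
        input_count=len(calls),
        output_count=len(merged),
        multi_mapped_count=multi,
        unmapped_count=unmapped,
    )
    return merged, report


def map_orthologs(
    genes: GeneSet, orthologs: IdMapping
) -> tuple[GeneSet, CollapseReport]:
    """Map a gene set to the non-redundant union of its ortholog targets.

    A gene with several putative orthologs contributes all of them; two
    genes sharing a target yield that target once.  Genes without any
    target are counted as unmapped.
    """
    targets = orthologs.as_dict()
    out: set[str] = set()
    unmapped = 0
    multi = 0
    for g in genes.members:
        t = targets.get(g, [])
        if not t:
            unmapped += 1
            continue
        if len(t) > 1:
            multi += 1
        out.update(t)
    report = CollapseReport(
        input_count=len(genes),
        output_count=len(out),
        multi_mapped_count=multi,
        unmapped_count=unmapped,
    )
    return GeneSet(f"{genes.name}_orthologs", frozenset(out)), report
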