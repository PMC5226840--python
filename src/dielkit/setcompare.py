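"""Gene-set comparison: Venn partitions, Tanimoto-Jaccard similarity,
panel ranking and tissue-presence binning.

The Tanimoto-Jaccard index here follows the convention of circadian
cross-dataset comparisons: ``100 * |A n B| / |A u B|``, reported to one
decimal (half-up), so a perfect overlap scores 100 and e.g. set sizes
(2609, 2882) with 489 shared members score 9.8.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple

import pandas as pd

from .dataio import GeneSet

__all__ = [
    "VennCounts",
    "venn_counts",
    "jaccard100",
    "jaccard100_from_sizes",
    "rank_similarity",
    "presence_bins",
    "specific_subset",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), matching how
    printed summary indexes are conventionally rounded."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class VennCounts(NamedTuple):
    a_only: int
    common: int
    b_only: int

    @property
    def union(self) -> int:
        return self.a_only + self.common + self.b_only


def venn_counts(a: GeneSet, b: GeneSet) -> VennCounts:
    """Two-set Venn partition sizes; the three parts sum to |A u B|."""
    common = len(a.members & b.members)
    return VennCounts(len(a) - common, common, len(b) - common)


def jaccard100_from_sizes(size_a: int, size_b: int, intersection: int) -> float:
    """Tanimoto-Jaccard index from printed set sizes: 100*|AnB|/|AuB|,
    one decimal, half-up."""
    if intersection > min(size_a, size_b):
        raise ValueError("intersection exceeds a set size")
    union = size_a + size_b - intersection
    if union <= 0:
        raise ValueError("empty union")
    return round_half_up(100.0 * intersection / union, 1)


def jaccard100(a: GeneSet, b: GeneSet) -> float:
    """Tanimoto-Jaccard index of two membership sets."""
    inter = len(a.members & b.members)
    return jaccard100_from_sizes(len(a), len(b), inter)


def rank_similarity(
    query: GeneSet, panel: Mapping[str, GeneSet]
) -> pd.DataFrame:
    """Jaccard index of the query against each panel dataset, descending;
    ties in the index break alphabetically by dataset name."""
    if not panel:
        raise ValueError("empty panel")
    rows = [(name, jaccard100(query, gs)) for name, gs in panel.items()]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["name", "jaccard100"])


def presence_bins(
    matrix: pd.DataFrame, common_threshold: int = 4
) -> pd.DataFrame:
    """Per-dataset counts and proportions of member genes by how many
    datasets they appear in.

    Classes are "1", "2", ..., up to ``>=common_threshold`` ("common"
    genes, e.g. present in 4 to 12 tissues vs tissue-specific genes
    present in 1 to 3).  Proportions sum to 1 per dataset.
    """
    if common_threshold < 2:
        raise ValueError("common_threshold must be >= 2")
    presence = matrix.astype(bool)
    n_datasets = presence.sum(axis=1)
    classes = [str(k) for k in range(1, common_threshold)] + [f">={common_threshold}"]

    def class_of(n: int) -> str:
        return str(n) if n < common_threshold else f">={common_threshold}"

    records = []
    for dataset in presence.columns:
        member_counts = n_datasets[presence[dataset]]
        tally = {c: 0 for c in classes}
        for n in member_counts:
            tally[class_of(int(n))] += 1
        total = sum(tally.values())
        for c in classes:
            records.append(
                {
                    "dataset": dataset,
                    "class": c,
                    "count": tally[c],
                    "proportion": tally[c] / total if total else 0.0,
                }
            )
    return pd.DataFrame(records)


def specific_subset(matrix: pd.DataFrame, dataset: str, k: int = 1) -> GeneSet:
    """Genes present in `dataset` and in at most `k` datasets overall
    (k=1: strictly dataset-specific genes)."""
    if dataset not in matrix.columns:
        raise KeyError(f"unknown dataset {dataset!r}")
    presence = matrix.astype(bool)
    n_datasets = presence.sum(axis=1)
    members = matrix.index[presence[dataset] & (n_datasets <= k)]
    return GeneSet(f"{dataset}_specific_k{k}", frozenset(members))
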