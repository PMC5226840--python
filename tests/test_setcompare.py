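import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielkit import (
    GeneSet,
    jaccard100,
    jaccard100_from_sizes,
    presence_bins,
    rank_similarity,
    specific_subset,
    venn_counts,
)
from dielkit.dataio import read_presence_matrix

ids = st.sets(st.integers(0, 200), max_size=60).map(
    lambda s: frozenset(f"g{i}" for i in s)
)


def gs(name, members):
    return GeneSet(name, frozenset(members))


class TestVenn:
    def test_printed_sizes_union(self):
        a = gs("h", (f"g{i}" for i in range(2175)))
        b = gs("j", (f"g{i}" for i in range(1415, 1415 + 1192)))
        counts = venn_counts(a, b)
        assert counts.common == 760
        assert counts.union == 2607

    def test_disjoint(self):
        assert venn_counts(gs("a", {"x"}), gs("b", {"y"})).common == 0

    def test_identical(self):
        c = venn_counts(gs("a", {"x", "y"}), gs("b", {"x", "y"}))
        assert (c.a_only, c.b_only) == (0, 0)

    @settings(derandomize=True, max_examples=60)
    @given(ids, ids)
    def test_partition_conserves_cardinalities(self, ma, mb):
        a, b = GeneSet("a", ma), GeneSet("b", mb)
        c = venn_counts(a, b)
        assert c.a_only + c.common == len(a)
        assert c.b_only + c.common == len(b)
        assert c.union == len(ma | mb)


class TestJaccard:
    @pytest.mark.parametrize(
        "sizes,expected",
        [((2609, 2882, 489), 9.8), ((2530, 2951, 486), 9.7)],
    )
    def test_cross_dataset_worked_examples(self, sizes, expected):
        assert jaccard100_from_sizes(*sizes) == expected

    def test_identical_and_disjoint_extremes(self):
        a = gs("a", {"x", "y", "z"})
        assert jaccard100(a, gs("b", {"x", "y", "z"})) == 100.0
        assert jaccard100(a, gs("c", {"q"})) == 0.0

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            jaccard100_from_sizes(0, 0, 0)

    def test_impossible_intersection_rejected(self):
        with pytest.raises(ValueError):
            jaccard100_from_sizes(5, 5, 6)

    @settings(derandomize=True, max_examples=60)
    @given(ids, ids)
    def test_bounds_symmetry_identity(self, ma, mb):
        if not (ma | mb):
            return
        a, b = GeneSet("a", ma), GeneSet("b", mb)
        j = jaccard100(a, b)
        assert 0.0 <= j <= 100.0
        assert j == jaccard100(b, a)
        if j == 100.0:
            assert ma == mb


class TestRanking:
    def test_query_copy_ranks_first(self):
        q = gs("q", {"a", "b", "c"})
        panel = {"self": q, "other": gs("o", {"a"})}
        table = rank_similarity(q, panel)
        assert table.iloc[0]["name"] == "self"
        assert table.iloc[0]["jaccard100"] == 100.0

    def test_disjoint_panel_alphabetical(self):
        q = gs("q", {"a"})
        panel = {
            "zeta": gs("z", {"z1"}),
            "alpha": gs("a", {"a1"}),
            "mid": gs("m", {"m1"}),
        }
        table = rank_similarity(q, panel)
        assert list(table["name"]) == ["alpha", "mid", "zeta"]
        assert (table["jaccard100"] == 0.0).all()

    def test_engineered_overlaps_rank_by_construction(self):
        q = gs("q", (f"g{i}" for i in range(100)))
        panel = {}
        for name, overlap in [("high", 50), ("mid", 30), ("low", 10)]:
            members = {f"g{i}" for i in range(overlap)} | {
                f"{name}{i}" for i in range(100 - overlap)
            }
            panel[name] = gs(name, members)
        table = rank_similarity(q, panel)
        assert list(table["name"]) == ["high", "mid", "low"]
        # indexes computed by hand: 100*o/(200-o)
        assert list(table["jaccard100"]) == [
            round(100 * o / (200 - o), 1) for o in (50, 30, 10)
        ]


def presence_fixture():
    # 8 genes x 5 datasets with engineered presence counts
    data = {
        "liver": [1, 1, 1, 1, 0, 0, 1, 0],
        "kidney": [0, 1, 1, 1, 1, 0, 0, 0],
        "lung": [0, 0, 1, 1, 0, 1, 0, 0],
        "heart": [0, 0, 0, 1, 0, 0, 0, 1],
        "brain": [0, 0, 0, 1, 0, 0, 0, 0],
    }
    return pd.DataFrame(data, index=[f"g{i}" for i in range(8)])


class TestPresenceBins:
    def test_every_gene_single_dataset(self):
        m = pd.DataFrame(
            np.eye(4, dtype=int), index=list("abcd"), columns=["d1", "d2", "d3", "d4"]
        )
        bins = presence_bins(m)
        class1 = bins[bins["class"] == "1"]
        assert (class1["proportion"] == 1.0).all()

    def test_every_gene_everywhere(self):
        m = pd.DataFrame(
            np.ones((3, 12), dtype=int),
            index=list("abc"),
            columns=[f"t{i}" for i in range(12)],
        )
        bins = presence_bins(m, common_threshold=4)
        common = bins[bins["class"] == ">=4"]
        assert (common["proportion"] == 1.0).all()

    def test_fixture_tally_matches_row_sum_oracle(self):
        m = presence_fixture()
        bins = presence_bins(m, common_threshold=4)
        n_sets = m.sum(axis=1)
        for dataset in m.columns:
            members = m.index[m[dataset] == 1]
            for cls in ("1", "2", "3", ">=4"):
                expected = sum(
                    1
                    for g in members
                    if (str(n_sets[g]) == cls if n_sets[g] < 4 else cls == ">=4")
                )
                got = bins[(bins["dataset"] == dataset) & (bins["class"] == cls)][
                    "count"
                ].item()
                assert got == expected

    def test_proportions_sum_to_one(self):
        bins = presence_bins(presence_fixture())
        for _, sub in bins.groupby("dataset"):
            assert sub["proportion"].sum() == pytest.approx(1.0)

    def test_threshold_guard(self):
        with pytest.raises(ValueError):
            presence_bins(presence_fixture(), common_threshold=1)


class TestSpecificSubset:
    def test_k1_strictly_specific(self):
        m = presence_fixture()
        out = specific_subset(m, "liver", k=1)
        assert out.members == {"g0", "g6"}

    def test_k2_admits_doubles(self):
        m = presence_fixture()
        assert "g1" in specific_subset(m, "liver", k=2)
        assert "g1" not in specific_subset(m, "liver", k=1)

    def test_unknown_dataset_rejected(self):
        with pytest.raises(KeyError):
            specific_subset(presence_fixture(), "pineal")

    def test_round_trip_through_tsv(self):
        m = presence_fixture()
        buf = io.StringIO(m.to_csv(sep="\t"))
        back = read_presence_matrix(buf)
        pd.testing.assert_frame_equal(back, m, check_names=False)
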