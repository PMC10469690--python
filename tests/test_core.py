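import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgconserve import (
    Phylogeny,
    TraitTable,
    align_tree_table,
    binarize,
    sim_tree,
)
from bgconserve.core import TreeError


class TestNewickIO:
    def test_four_tip_parse(self, balanced4):
        assert balanced4.n_tips == 4
        assert sorted(balanced4.labels) == ["A", "B", "C", "D"]
        assert balanced4.total_branch_length() == pytest.approx(6.0)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            Phylogeny.from_newick("((A:1,A:2):1,B:1);")

    def test_unparseable_input_rejected(self):
        with pytest.raises(TreeError, match="parse"):
            Phylogeny.from_newick("((A:1,B:1)")

    def test_missing_lengths_policy(self):
        with pytest.raises(TreeError, match="branch length"):
            Phylogeny.from_newick("((A,B),C);")
        t = Phylogeny.from_newick("((A,B),C);", assume_unit_lengths=True)
        assert t.total_branch_length() == pytest.approx(4.0)

    def test_internal_labels_and_quotes_tolerated(self):
        t = Phylogeny.from_newick("(('sp one':1,B:2)inner:0.5,C:1)root;")
        assert "sp one" in t.labels
        assert t.total_branch_length() == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_random_trees(self, yule_factory, seed):
        """write -> read preserves topology and lengths to 1e-9."""
        t = yule_factory(40, seed=seed)
        t2 = Phylogeny.from_newick(t.to_newick())
        assert t2.labels == sorted(t2.labels) or set(t2.labels) == set(t.labels)
        d1 = t.cophenetic()
        d2 = t2.cophenetic().filter(t.labels)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-9)


class TestCophenetic:
    def test_hand_path_sums(self, balanced4):
        dm = balanced4.cophenetic()
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["C", "D"] == pytest.approx(2.0)
        assert np.all(np.diag(dm.data) == 0)

    def test_star_tree_uniform(self):
        t = Phylogeny.from_newick("(A:2,B:2,C:2,D:2);")
        dm = t.cophenetic().data
        off = dm[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_point_condition(self, yule_factory, seed):
        """Any tree metric satisfies the four-point condition."""
        t = yule_factory(12, seed=seed)
        d = t.cophenetic().data
        rng = np.random.default_rng(seed)
        for _ in range(50):
            i, j, k, l = rng.choice(12, size=4, replace=False)
            sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
            assert sums[2] - sums[1] <= 1e-9

    def test_shared_path_matrix_diag_is_depth(self, balanced4):
        c = balanced4.shared_path_matrix()
        np.testing.assert_allclose(np.diag(c), 2.0)
        a, b = balanced4.tip_index(["A", "B"])
        assert c[a, b] == pytest.approx(1.0)


class TestPolytomies:
    def test_binary_input_unchanged(self, balanced4):
        assert balanced4.resolve_polytomies(seed=1) is balanced4

    def test_trifurcation_resolved_with_zero_edge(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1);")
        r = t.resolve_polytomies(seed=3)
        assert r.is_binary()
        assert r.n_nodes == 5
        assert r.total_branch_length() == pytest.approx(3.0)

    def test_seeded_resolution_reproducible(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        r1 = t.resolve_polytomies(seed=7)
        r2 = t.resolve_polytomies(seed=7)
        assert r1.to_newick() == r2.to_newick()

    def test_cophenetic_unchanged(self):
        t = Phylogeny.from_newick("((A:1,B:2,C:3,D:1):1,E:4);")
        r = t.resolve_polytomies(seed=0)
        d1 = t.cophenetic()
        d2 = r.cophenetic().filter(t.labels)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)


class TestTraitTable:
    def test_binarize_thresholds_at_one(self):
        counts = pd.DataFrame({"c": [0, 1, 5, 0]}, index=list("wxyz"))
        b = binarize(TraitTable(counts))
        assert list(b.counts["c"]) == [0, 1, 1, 0]

    def test_binarize_idempotent_and_zero_rows(self, small_table):
        b1 = small_table.binarize()
        b2 = b1.binarize()
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        zero = TraitTable(pd.DataFrame({"c": [0, 0]}, index=["a", "b"]))
        assert zero.binarize().counts["c"].sum() == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=30))
    def test_binarize_properties_hold_for_any_counts(self, counts):
        """binarize maps to {0,1}, thresholds at 1, and is idempotent."""
        t = TraitTable(
            pd.DataFrame({"c": counts}, index=[f"g{i}" for i in range(len(counts))])
        )
        b = t.binarize()
        assert set(b.counts["c"].unique()) <= {0, 1}
        assert ((b.counts["c"] == 1) == (t.counts["c"] >= 1)).all()
        pd.testing.assert_frame_equal(b.binarize().counts, b.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            TraitTable(pd.DataFrame({"c": [-1, 2]}, index=["a", "b"]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TraitTable(pd.DataFrame({"c": [1, 2]}, index=["a", "a"]))

    def test_tsv_roundtrip(self, small_table, tmp_path):
        cp, mp = str(tmp_path / "c.tsv"), str(tmp_path / "m.tsv")
        small_table.to_tsv(cp, mp)
        back = TraitTable.from_tsv(cp, mp)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)
        assert list(back.metadata["genus"]) == list(small_table.metadata["genus"])


class TestAlignment:
    def test_identical_sets_unchanged(self, balanced4, small_table):
        t, tab = align_tree_table(balanced4, small_table, policy="strict")
        assert set(t.labels) == set(tab.genome_ids)
        assert list(tab.genome_ids) == list(t.labels)

    def test_intersect_prunes_both(self, small_table):
        t5 = Phylogeny.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")
        t, tab = align_tree_table(t5, small_table, policy="intersect")
        assert set(t.labels) == {"A", "B", "C", "D"}
        assert tab.counts.shape[0] == 4
        # intersect output passes strict alignment
        align_tree_table(t, tab, policy="strict")

    def test_strict_mismatch_errors(self, small_table):
        t5 = Phylogeny.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")
        with pytest.raises(ValueError, match="differ"):
            align_tree_table(t5, small_table, policy="strict")

    def test_disjoint_sets_error(self, balanced4):
        other = TraitTable(pd.DataFrame({"c": [1, 2]}, index=["x", "y"]))
        with pytest.raises(ValueError, match="no labels"):
            align_tree_table(balanced4, other)
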