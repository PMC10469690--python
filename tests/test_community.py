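from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from bgconserve import (
    TraitTable,
    bray_curtis,
    group_ellipses,
    mantel,
    pcoa,
    permanova,
)


def table_from(rows: dict) -> TraitTable:
    return TraitTable(pd.DataFrame(rows).T)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = table_from({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_support_one(self):
        t = table_from({"a": [2, 0], "b": [0, 2]})
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_hand_value(self):
        t = table_from({"a": [1, 1], "b": [3, 1]})
        assert bray_curtis(t)["a", "b"] == pytest.approx(2 / 6)

    def test_double_zero_warns(self):
        t = table_from({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
        with pytest.warns(UserWarning, match="all-zero"):
            dm = bray_curtis(t)
        assert dm["a", "b"] == 0.0

    def test_binary_matches_sorensen(self, rng):
        x = (rng.random((6, 5)) < 0.5).astype(int)
        x[:, 0] = 1
        t = TraitTable(pd.DataFrame(x, index=[f"g{i}" for i in range(6)]))
        dm = bray_curtis(t).data
        for i in range(6):
            for j in range(6):
                a, b = x[i].sum(), x[j].sum()
                shared = (x[i] & x[j]).sum()
                assert dm[i, j] == pytest.approx(1 - 2 * shared / (a + b))


class TestMantel:
    def make_dms(self, rng, n=8):
        pts = rng.random((n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        return DistanceMatrix(d, ids=ids)

    def test_self_correlation_is_one(self, rng):
        dm = self.make_dms(rng)
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r_obs == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        dm = self.make_dms(rng)
        dm2 = DistanceMatrix(2.5 * dm.data + (1 - np.eye(8)), ids=dm.ids)
        assert mantel(dm, dm2, n_perm=9, seed=0).r_obs == pytest.approx(1.0)

    def test_exhaustive_five_labels(self, rng):
        """Sampled permutation p agrees with the full 120-permutation null."""
        a = self.make_dms(rng, n=5)
        b = self.make_dms(rng, n=5)
        il, jl = np.tril_indices(5, k=-1)
        va = a.data[il, jl]
        exact_rs = []
        for perm in permutations(range(5)):
            p = np.array(perm)
            vb = b.data[p[:, None], p[None, :]][il, jl]
            exact_rs.append(np.corrcoef(va, vb)[0, 1])
        r_obs = np.corrcoef(va, b.data[il, jl])[0, 1]
        p_exact = np.mean(np.array(exact_rs) >= r_obs - 1e-12)
        res = mantel(a, b, n_perm=2000, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / 2000)
        assert res.r_obs == pytest.approx(r_obs)
        assert abs(res.p_value - p_exact) <= max(2 * se, 0.02)

    def test_matches_skbio_r(self, rng):
        a = self.make_dms(rng, n=12)
        b = self.make_dms(rng, n=12)
        res = mantel(a, b, n_perm=99, seed=0)
        r_sk, _, _ = skbio_mantel(a, b, permutations=0)
        assert res.r_obs == pytest.approx(float(r_sk), abs=1e-10)

    def test_label_mismatch_and_zero_variance(self, rng):
        a = self.make_dms(rng)
        bad = DistanceMatrix(a.data, ids=[f"x{i}" for i in range(8)])
        with pytest.raises(ValueError, match="labels"):
            mantel(a, bad)
        flat = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="variance"):
            mantel(flat, flat, n_perm=9)


class TestPcoa:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        assert abs(res.eigenvalues[-1]) < 1e-9

    def test_roundtrip_known_points(self, rng):
        pts = rng.random((10, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
        res = pcoa(dm)
        c = res.coordinates.to_numpy()
        rec = np.sqrt(((c[:, None] - c[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_duplicated_point_duplicated_row(self, rng):
        pts = np.vstack([rng.random((4, 2)), rng.random((1, 2))])
        pts[4] = pts[0]
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=list("abcde")))
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["e"], atol=1e-8
        )

    def test_eigenvalues_match_skbio(self, rng):
        pts = rng.random((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        mine = pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=7)
        np.testing.assert_allclose(
            mine.eigenvalues[:5], np.asarray(theirs.eigvals)[:5], atol=1e-8
        )

    def test_inertia_conservation(self, rng):
        pts = rng.random((9, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(9)]))
        pos_sum = res.eigenvalues[res.eigenvalues > 0].sum()
        coord_norm = (res.coordinates.to_numpy() ** 2).sum()
        assert pos_sum >= coord_norm - 1e-8


class TestPermanova:
    def test_two_clean_groups_hand_values(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=20, seed=0)
        assert res.ss_total == pytest.approx(1.0)
        assert res.ss_within == pytest.approx(0.0)
        assert res.ss_between == pytest.approx(1.0)
        assert res.R2 == pytest.approx(1.0)

    def test_matches_skbio_pseudo_f(self, rng):
        pts = rng.random((15, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(15)])
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        mine = permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_f_consistent_with_ss(self, rng):
        pts = rng.random((12, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=1)
        f = (res.ss_between / res.df_between) / (res.ss_within / res.df_within)
        assert res.pseudo_F == pytest.approx(f)
        assert res.R2 == pytest.approx(res.ss_between / res.ss_total)

    def test_single_group_rejected(self, rng):
        dm = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dm, ["g"] * 4)


class TestEllipses:
    def test_parameters_cover_spread(self, rng):
        coords = pd.DataFrame(
            rng.standard_normal((60, 2)), columns=["PC1", "PC2"],
            index=[f"s{i}" for i in range(60)],
        )
        groups = ["x"] * 30 + ["y"] * 30
        df = group_ellipses(coords, groups, mass=0.8)
        assert set(df["group"]) == {"x", "y"}
        assert (df["semi_major"] >= df["semi_minor"]).all()
        assert (df["n"] == 30).all()
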