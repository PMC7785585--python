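import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel

from bentheco.community_stats import (
    anosim,
    distance_decay,
    env_distance,
    geo_distance,
    mantel,
    partial_mantel,
    simper,
    spearman_screen,
)
from bentheco.data_model import OtuTable
from bentheco.diversity import bray_curtis
from conftest import random_table


def _env_frame(values: dict) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    return pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], **values})


def _random_dm(rng, n, ids=None):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)),
                         ids=ids or [f"s{i}" for i in range(n)])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        resp = pd.DataFrame({"alpha": np.exp(x / 10)},
                            index=[f"s{i}" for i in range(5)])
        env = _env_frame({"v": x})
        out = spearman_screen(resp, env, ["v"])
        assert out["spearman_r"][0] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        resp = pd.DataFrame({"alpha": -x}, index=[f"s{i}" for i in range(5)])
        out = spearman_screen(resp, _env_frame({"v": x}), ["v"])
        assert out["spearman_r"][0] == pytest.approx(-1.0)

    def test_hand_value_point_eight(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 4.0, 5.0])
        resp = pd.DataFrame({"alpha": y}, index=[f"s{i}" for i in range(5)])
        out = spearman_screen(resp, _env_frame({"v": x}), ["v"])
        expected, _ = stats.spearmanr(x, y)
        assert out["spearman_r"][0] == pytest.approx(expected)

    def test_constant_variable_flagged(self):
        resp = pd.DataFrame({"alpha": [1.0, 2, 3, 4, 5]},
                            index=[f"s{i}" for i in range(5)])
        out = spearman_screen(resp, _env_frame({"v": [2.0] * 5}), ["v"])
        assert out["flag"][0] == "constant"
        assert np.isnan(out["spearman_r"][0])


class TestEnvGeoDistance:
    def test_identical_rows_zero_and_scale_invariance(self):
        env = _env_frame({"a": [1.0, 1.0, 3.0], "b": [2.0, 2.0, 9.0]})
        d1 = env_distance(env, ["a", "b"])
        assert d1["s0", "s1"] == pytest.approx(0.0)
        env2 = env.assign(a=env["a"] * 100)
        d2 = env_distance(env2, ["a", "b"])
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)

    def test_zero_variance_variable_dropped(self):
        env = _env_frame({"a": [1.0, 2.0, 3.0], "b": [5.0] * 3})
        d = env_distance(env, ["a", "b"])
        z = (env["a"] - env["a"].mean()) / env["a"].std(ddof=1)
        assert d["s0", "s2"] == pytest.approx(abs(z[0] - z[2]))

    def test_geo_same_point_and_one_degree(self):
        meta = pd.DataFrame({
            "sample_id": ["p", "q", "r"],
            "latitude": [0.0, 0.0, 1.0],
            "longitude": [0.0, 0.0, 0.0],
        })
        d = geo_distance(meta)
        assert d["p", "q"] == pytest.approx(0.0)
        assert d["p", "r"] == pytest.approx(111.19, abs=0.01)
        assert np.allclose(d.data, d.data.T, atol=1e-12)

    def test_out_of_range_coordinates_rejected(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"],
                             "latitude": [0.0, 95.0], "longitude": [0.0, 0.0]})
        with pytest.raises(ValueError, match="out of range"):
            geo_distance(meta)


class TestAnosim:
    def test_perfect_separation_gives_one(self):
        # two tight clusters far apart: all between > all within
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.01, (4, 2)),
                         np.random.default_rng(1).normal(100, 0.01, (4, 2))])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(8)])
        r, p = anosim(dm, ["g1"] * 4 + ["g2"] * 4, n_perm=199, seed=5)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 200

    def test_null_labels_centered_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(100):
            dm = _random_dm(rng, 10)
            labels = list(rng.permutation(["a"] * 5 + ["b"] * 5))
            r, _ = anosim(dm, labels, n_perm=99, seed=int(rng.integers(2**31)))
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_r_bounded_and_p_floor(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            dm = _random_dm(rng, 8)
            r, p = anosim(dm, ["a"] * 4 + ["b"] * 4, n_perm=99,
                          seed=int(rng.integers(2**31)))
            assert -1 <= r <= 1
            assert p >= 1 / 100

    def test_singleton_group_rejected(self):
        dm = _random_dm(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(dm, ["a", "a", "a", "a", "b"], 99, 1)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(17)
        dm = _random_dm(rng, 9)
        labels = ["a"] * 4 + ["b"] * 5
        r, _ = anosim(dm, labels, n_perm=99, seed=1)
        ref = skbio_anosim(dm, grouping=labels, permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)


class TestSimper:
    def test_single_discriminating_otu(self):
        table = OtuTable(["a1", "a2", "b1", "b2"], ["x", "y"],
                         np.array([[5, 0], [5, 0], [5, 9], [5, 9]]))
        res = simper(table, ["A", "A", "B", "B"])
        df = res[("A", "B")]
        assert df.loc[df["otu_id"] == "y", "percent"].iloc[0] == pytest.approx(100.0)

    def test_decomposition_identity_and_percent_sum(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            table = random_table(rng, 6, 7)
            labels = ["A", "A", "A", "B", "B", "B"]
            df = simper(table, labels)[("A", "B")]
            bc = bray_curtis(table)
            between = [bc[f"s{i}", f"s{j}"] for i in range(3) for j in range(3, 6)]
            assert df["contribution"].sum() == pytest.approx(np.mean(between), abs=1e-10)
            assert df["percent"].sum() == pytest.approx(100.0, abs=0.01)
            assert (np.diff(df["cumulative_percent"]) >= -1e-9).all()

    def test_hand_computed_contributions(self):
        table = OtuTable(["a1", "a2", "b1", "b2"], ["x", "y", "z"],
                         np.array([[4, 2, 0], [2, 4, 0], [0, 2, 4], [0, 0, 6]]))
        labels = ["A", "A", "B", "B"]
        df = simper(table, labels)[("A", "B")].set_index("otu_id")
        x = table.counts.astype(float)
        expected = np.zeros(3)
        for i in (0, 1):
            for j in (2, 3):
                expected += np.abs(x[i] - x[j]) / (x[i].sum() + x[j].sum())
        expected /= 4
        for k, otu in enumerate(["x", "y", "z"]):
            assert df.loc[otu, "contribution"] == pytest.approx(expected[k], abs=1e-12)

    def test_empty_group_rejected(self, small_table):
        with pytest.raises(ValueError):
            simper(small_table, ["A", "A", "A"])


class TestMantel:
    def test_proportional_matrices_give_r_one(self):
        dm = _random_dm(np.random.default_rng(3), 8)
        dm3 = DistanceMatrix(dm.data * 3.0, ids=dm.ids)
        res = mantel(dm, dm3, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_r_equals_direct_pearson(self):
        rng = np.random.default_rng(23)
        a, b = _random_dm(rng, 9), _random_dm(rng, 9)
        res = mantel(a, b, n_perm=99, seed=2)
        va = squareform(np.asarray(a.data), checks=False)
        vb = squareform(np.asarray(b.data), checks=False)
        assert res.r == pytest.approx(np.corrcoef(va, vb)[0, 1], abs=1e-12)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(29)
        a, b = _random_dm(rng, 10), _random_dm(rng, 10)
        res = mantel(a, b, n_perm=99, seed=3)
        ref_r, _, _ = skbio_mantel(a, b, permutations=0, alternative="greater")
        assert res.r == pytest.approx(ref_r, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(200):
            a, b = _random_dm(rng, 10), _random_dm(rng, 10)
            ps.append(mantel(a, b, n_perm=199, seed=int(rng.integers(2**31))).p_value)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_constant_matrix_rejected(self):
        flat = DistanceMatrix(1 - np.eye(5), ids=list("abcde"))
        dm = _random_dm(np.random.default_rng(1), 5, ids=list("abcde"))
        with pytest.raises(ValueError, match="constant"):
            mantel(flat, dm, 99, 1)


class TestPartialMantel:
    def test_control_equal_to_b_removes_signal(self):
        rng = np.random.default_rng(37)
        a = _random_dm(rng, 10)
        b = _random_dm(rng, 10)
        res = partial_mantel(a, b, b, n_perm=99, seed=1)
        assert abs(res.r) < 1e-10

    def test_constant_control_equals_simple_mantel(self):
        rng = np.random.default_rng(41)
        a, b = _random_dm(rng, 9), _random_dm(rng, 9)
        flat = DistanceMatrix(1 - np.eye(9), ids=a.ids)
        partial = partial_mantel(a, b, flat, n_perm=99, seed=1)
        simple = mantel(a, b, n_perm=99, seed=1)
        assert partial.r == pytest.approx(simple.r, abs=1e-6)

    def test_symmetric_in_first_two_arguments(self):
        rng = np.random.default_rng(43)
        a, b, c = (_random_dm(rng, 8) for _ in range(3))
        r1 = partial_mantel(a, b, c, n_perm=99, seed=1).r
        r2 = partial_mantel(b, a, c, n_perm=99, seed=1).r
        assert r1 == pytest.approx(r2, abs=1e-10)


class TestDistanceDecay:
    def test_exact_line(self):
        rng = np.random.default_rng(47)
        geo = _random_dm(rng, 8)
        sim_matrix = 1.0 - 0.01 * np.asarray(geo.data)
        comm = DistanceMatrix(1.0 - sim_matrix, ids=geo.ids)
        slope, intercept, r = distance_decay(comm, geo)
        assert slope == pytest.approx(-0.01, abs=1e-12)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_zero_geographic_variance_rejected(self):
        comm = _random_dm(np.random.default_rng(2), 5)
        flat = DistanceMatrix(np.zeros((5, 5)), ids=comm.ids)
        with pytest.raises(ValueError, match="geographic"):
            distance_decay(comm, flat)

    def test_slope_sign_matches_mantel_sign(self):
        rng = np.random.default_rng(53)
        pts = rng.normal(size=(10, 2))
        geo = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        comm = DistanceMatrix(np.asarray(geo.data) / geo.data.max() * 0.8
                              + 0.01 * squareform(rng.random(45)), ids=geo.ids)
        slope, _, _ = distance_decay(comm, geo)
        res = mantel(comm, geo, n_perm=99, seed=1)
        assert np.sign(slope) == -np.sign(res.r)
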