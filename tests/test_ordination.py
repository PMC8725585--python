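import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel

from vanadiome.ordination import (
    anosim,
    bray_curtis,
    mantel,
    nmds,
    per_factor_fractions,
    vpa,
)
from vanadiome.tables import CommunityTable


def _dm_from_points(X):
    ids = [str(i) for i in range(len(X))]
    return DistanceMatrix(squareform(pdist(X)), ids=ids)


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        df = pd.DataFrame(
            [[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        dm = bray_curtis(CommunityTable(df))
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_hand_computed(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"], columns=list("xyz"))
        dm = bray_curtis(CommunityTable(df))
        assert dm["a", "b"] == pytest.approx(4 / 12)

    def test_feature_order_invariance(self, rng):
        vals = rng.integers(0, 20, size=(4, 6))
        df = pd.DataFrame(vals, index=list("abcd"), columns=list("uvwxyz"))
        perm = rng.permutation(6)
        df2 = df.iloc[:, perm]
        d1 = bray_curtis(CommunityTable(df))
        d2 = bray_curtis(CommunityTable(df2))
        np.testing.assert_allclose(d1.data, d2.data)

    def test_zero_sample_rejected(self):
        df = pd.DataFrame([[0, 0], [1, 1]], index=["z", "s"], columns=["a", "b"])
        with pytest.raises(ValueError):
            bray_curtis(CommunityTable(df))


class TestNMDS:
    def test_recovers_embeddable_configuration(self, rng):
        X = rng.normal(size=(15, 2))
        res = nmds(_dm_from_points(X), k=2, n_starts=5, seed=0)
        assert res.stress < 1e-3

    def test_stress_trace_non_increasing(self, rng):
        X = rng.normal(size=(12, 4))
        res = nmds(_dm_from_points(X), k=2, n_starts=3, seed=1)
        assert np.all(np.diff(res.stress_trace) <= 1e-8)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(10, 3))
        dm = _dm_from_points(X)
        a = nmds(dm, n_starts=4, seed=7)
        b = nmds(dm, n_starts=4, seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert np.allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_k_too_large(self, rng):
        dm = _dm_from_points(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError):
            nmds(dm, k=3)


class TestAnosim:
    def test_separated_clusters_R_equals_one(self, rng):
        X = np.vstack([rng.normal(0, 0.01, size=(4, 2)),
                       rng.normal(10, 0.01, size=(4, 2))])
        res = anosim(_dm_from_points(X), ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 0.05

    def test_statistic_matches_skbio(self, rng):
        X = rng.normal(size=(12, 3))
        dm = _dm_from_points(X)
        labels = np.repeat(["a", "b", "c"], 4)
        mine = anosim(dm, labels, n_perm=99, seed=0)
        ref = skbio_anosim(dm, list(labels), permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_R_bounded(self, rng):
        for s in range(10):
            X = np.random.default_rng(s).normal(size=(9, 2))
            res = anosim(_dm_from_points(X), ["a", "b", "c"] * 3, n_perm=99, seed=s)
            assert -1.0 - 1e-12 <= res.statistic <= 1.0 + 1e-12

    def test_p_convention_and_reproducibility(self, rng):
        X = rng.normal(size=(10, 2))
        dm = _dm_from_points(X)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = anosim(dm, labels, n_perm=99, seed=3)
        r2 = anosim(dm, labels, n_perm=99, seed=3)
        assert r1.p == r2.p and np.array_equal(r1.null_values, r2.null_values)
        assert r1.p >= 1 / 100  # add-one convention: never 0
        assert len(r1.null_values) == 99

    def test_singleton_group_rejected(self, rng):
        dm = _dm_from_points(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            anosim(dm, ["a", "a", "a", "a", "b"], n_perm=99)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = _dm_from_points(rng.normal(size=(8, 2)))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_matches_skbio_statistic(self, rng):
        d1 = _dm_from_points(rng.normal(size=(10, 3)))
        d2 = _dm_from_points(rng.normal(size=(10, 3)))
        mine = mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert mine.statistic == pytest.approx(r_ref, abs=1e-12)

    def test_monotone_transform_positive(self, rng):
        dm = _dm_from_points(rng.normal(size=(9, 2)))
        sq = DistanceMatrix(dm.data ** 2, ids=dm.ids)
        assert mantel(dm, sq, n_perm=99, seed=0).statistic > 0

    def test_id_mismatch_rejected(self, rng):
        d1 = _dm_from_points(rng.normal(size=(5, 2)))
        d2 = DistanceMatrix(d1.data, ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestVPA:
    @staticmethod
    def _response(rng, n, X, strength=1.0):
        signal = X @ rng.normal(size=(X.shape[1], 8))
        Y = np.exp(rng.normal(1.5, 0.2, size=(n, 8)) + strength * signal)
        df = pd.DataFrame(Y, index=[f"s{i}" for i in range(n)],
                          columns=[f"f{j}" for j in range(8)])
        return CommunityTable(df.div(df.sum(axis=1), axis=0), mode="relative")

    def test_recovers_driving_block(self, rng):
        n = 30
        X, W = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        fr = vpa(self._response(rng, n, X), {"X": X, "W": W})
        assert fr["X"] > 0.5
        assert abs(fr["W"]) < 0.1
        assert fr["X"] > 10 * abs(fr["W"])

    def test_identical_blocks_share_fraction(self, rng):
        n = 30
        X = rng.normal(size=(n, 2))
        fr = vpa(self._response(rng, n, X), {"A": X, "B": X.copy()})
        assert abs(fr["A"]) < 1e-9 and abs(fr["B"]) < 1e-9
        assert fr["A&B"] > 0.5

    def test_noise_response_residual_near_one(self, rng):
        n = 30
        X, W = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        Y = np.exp(rng.normal(size=(n, 8)))
        df = pd.DataFrame(Y, index=[f"s{i}" for i in range(n)],
                          columns=[f"f{j}" for j in range(8)])
        tab = CommunityTable(df.div(df.sum(axis=1), axis=0), mode="relative")
        fr = vpa(tab, {"X": X, "W": W})
        assert fr["residual"] > 0.85

    def test_fractions_sum_to_one(self, rng):
        n = 25
        blocks = {k: rng.normal(size=(n, 2)) for k in "ABC"}
        fr = vpa(self._response(rng, n, blocks["A"]), blocks)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_too_many_predictors_rejected(self, rng):
        n = 6
        X = rng.normal(size=(n, 4))
        W = rng.normal(size=(n, 4))
        with pytest.raises(ValueError):
            vpa(self._response(rng, n, X[:, :1]), {"X": X, "W": W})

    def test_per_factor_fractions_ranks_driver_first(self, rng):
        n = 30
        F = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"),
                         index=[f"s{i}" for i in range(n)])
        resp = self._response(rng, n, F[["a"]].to_numpy())
        fr = per_factor_fractions(resp, F)
        assert fr.idxmax() == "a"
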