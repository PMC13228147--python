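"""Locally weighted PLS variants: weight kernel, nesting reductions,
cluster-locality behavior, and cross-validated tuning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fecalnirs as fn
from fecalnirs.local import LocalModelSpec


class TestLocalWeights:
    def test_infinite_h_uniform(self):
        np.testing.assert_array_equal(
            fn.local_weights(np.array([0.0, 1.0, 9.0]), math.inf), [1, 1, 1]
        )

    def test_zero_distance_weight_one(self):
        w = fn.local_weights(np.array([0.0, 1.0, 2.0]), 2.0)
        assert w[0] == pytest.approx(1.0)

    def test_stated_formula(self):
        """d={1,2,3}, h=1: scale=median=2, w=exp(-d/2)."""
        w = fn.local_weights(np.array([1.0, 2.0, 3.0]), 1.0)
        np.testing.assert_allclose(w, np.exp([-0.5, -1.0, -1.5]), atol=1e-12)

    def test_truncation(self):
        d = np.array([0.0, 100.0])
        w = fn.local_weights(d, 0.5)  # scale = median = 50 -> w1 = e^-4 kept
        assert w[1] > 0
        d = np.array([0.0, 0.001, 1000.0])
        w = fn.local_weights(d, 0.1)
        assert w[2] == 0.0

    def test_all_zero_distances(self):
        np.testing.assert_array_equal(fn.local_weights(np.zeros(4), 1.0), np.ones(4))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fn.local_weights(np.array([1.0, -0.1]), 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 500),
        h=st.floats(0.3, 8.0),
    )
    def test_monotone_nonincreasing_in_distance(self, seed, h):
        d = np.sort(np.random.default_rng(seed).uniform(0, 5, size=20))
        w = fn.local_weights(d, h)
        assert np.all(np.diff(w) <= 1e-15)


class TestReductions:
    """The documented nesting chain: AGG(min=max) == KNN-LWPLSR;
    KNN(k=n) == LWPLSR; LWPLSR(h=inf) == global PLS."""

    def test_full_chain(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        Xcal, ycal, Xnew = X[:90], y[:90], X[90:]
        nlv = 5
        g = fn.PLS(ycal, Xcal).fit(nlv).predict(Xnew)
        lw = fn.lwplsr_predict(Xcal, ycal, Xnew, math.inf, nlv)
        knn = fn.knn_lwplsr_predict(Xcal, ycal, Xnew, math.inf, 90, nlv)
        agg = fn.knn_lwplsr_agg_predict(Xcal, ycal, Xnew, math.inf, 90, nlv, nlv)
        np.testing.assert_allclose(lw, g, atol=1e-8)
        np.testing.assert_allclose(knn, lw, atol=1e-8)
        np.testing.assert_allclose(agg, knn, atol=1e-8)

    def test_chain_at_finite_h(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        Xcal, ycal, Xnew = X[:90], y[:90], X[90:100]
        knn = fn.knn_lwplsr_predict(Xcal, ycal, Xnew, 2.0, 90, 4)
        lw = fn.lwplsr_predict(Xcal, ycal, Xnew, 2.0, 4)
        np.testing.assert_allclose(knn, lw, atol=1e-8)

    def test_agg_is_mean_of_members(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        Xcal, ycal, Xnew = X[:90], y[:90], X[90:98]
        agg = fn.knn_lwplsr_agg_predict(Xcal, ycal, Xnew, 2.0, 60, 1, 6)
        members = np.column_stack(
            [fn.knn_lwplsr_predict(Xcal, ycal, Xnew, 2.0, 60, a) for a in range(1, 7)]
        )
        np.testing.assert_allclose(agg, members.mean(axis=1), atol=1e-10)


class TestLocalBehavior:
    def test_duplicate_target_predicts_neighborhood_value(self, two_cluster_xy):
        d = two_cluster_xy
        target = d["Xcal"][3][None, :]
        pred = fn.lwplsr_predict(d["Xcal"], d["ycal"], target, 0.5, 4)[0]
        assert abs(pred - d["ycal"][3]) < 3 * d["noise_sd"]

    def test_local_beats_global_on_heterogeneous_clusters(self, two_cluster_xy):
        """Two clusters with conflicting local slopes: sharp local weighting
        must reduce test error below the global model at the same nlv."""
        d = two_cluster_xy
        nlv = 4
        g = fn.PLS(d["ycal"], d["Xcal"]).fit(nlv).predict(d["Xtest"])
        lw = fn.lwplsr_predict(d["Xcal"], d["ycal"], d["Xtest"], 0.5, nlv)
        rmse_g = np.sqrt(np.mean((g - d["ytest"]) ** 2))
        rmse_lw = np.sqrt(np.mean((lw - d["ytest"]) ** 2))
        assert rmse_lw < rmse_g

    def test_knn_neighbor_sets_recover_clusters(self, two_cluster_xy):
        """With k = cluster size, each target's neighborhood should align
        with its true cluster for nearly all targets."""
        d = two_cluster_xy
        k = int(np.sum(d["cal_clusters"] == 0))
        # the first latent variable carries the cluster separation here
        prelim = fn.PLS(d["ycal"], d["Xcal"]).fit(1)
        T = prelim.training_scores
        sds = prelim.score_sds
        Tn = prelim.scores(d["Xtest"])
        hits = 0
        for i in range(len(d["ytest"])):
            dist = np.sqrt((((T - Tn[i]) / sds) ** 2).sum(axis=1))
            neigh = np.argsort(dist, kind="stable")[:k]
            own = d["cal_clusters"][neigh] == d["test_clusters"][i]
            hits += own.mean() > 0.9
        assert hits / len(d["ytest"]) >= 0.95

    def test_permutation_equivariance(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        Xcal, ycal, Xnew = X[:90], y[:90], X[90:96]
        perm = np.random.default_rng(0).permutation(90)
        a = fn.knn_lwplsr_predict(Xcal, ycal, Xnew, 2.0, 40, 4)
        b = fn.knn_lwplsr_predict(Xcal[perm], ycal[perm], Xnew, 2.0, 40, 4)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_too_sharp_weighting_rejected(self):
        rng = np.random.default_rng(1)
        X = np.vstack([np.zeros((1, 4)), rng.standard_normal((20, 4)) + 50])
        y = rng.random(21) * 0.1 + 0.5
        with pytest.raises(ValueError, match="nonzero weight"):
            # one coincident sample, all others extremely far with tiny h
            fn.lwplsr_predict(X, y, np.zeros((1, 4)), 0.01, 2)

    def test_k_bounds(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        with pytest.raises(ValueError, match="k"):
            fn.knn_lwplsr_predict(X[:50], y[:50], X[50:52], 1.0, 1, 2)
        with pytest.raises(ValueError, match="k"):
            fn.knn_lwplsr_predict(X[:50], y[:50], X[50:52], 1.0, 51, 2)


class TestModelClasses:
    def test_results_facade_matches_functions(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance, ref.omd
        Xcal, ycal, Xnew = X[:90], y[:90], X[90:95]
        res = fn.LWPLSR(ycal, Xcal, h=2.0, nlv=4).fit()
        np.testing.assert_allclose(
            res.predict(Xnew), fn.lwplsr_predict(Xcal, ycal, Xnew, 2.0, 4), atol=1e-12
        )
        agg = fn.KNNLWPLSRAgg(ycal, Xcal, h=2.0, k=60, nlv_min=1, nlv_max=4).fit()
        np.testing.assert_allclose(
            agg.predict(Xnew),
            fn.knn_lwplsr_agg_predict(Xcal, ycal, Xnew, 2.0, 60, 1, 4),
            atol=1e-12,
        )
        assert "LWPLSR" in res.summary()


class TestTuning:
    def test_full_grid_defaults(self):
        g = fn.TuningGrid.full()
        assert g.pls_nlv == list(range(1, 31))
        assert g.lw_h == [0.5, 1, 2, 3, 4, 5, 6]
        assert g.knn_h == [0.5, 1, 2, 3, 4, 5, 6, math.inf]
        assert g.knn_k == [50, 100, 150, 200, 250]
        assert g.agg_nlv_min == [1, 2, 3, 4, 5]
        assert g.agg_nlv_max == [15, 20, 25, 30]

    def test_infeasible_k_dropped(self):
        g = fn.TuningGrid.full()
        specs = g.specs("KNN-LWPLSR", n_cal=120)
        assert {s.k for s in specs} == {50, 100}

    def test_single_point_grid(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance[:60], ref.omd[:60]
        spec = LocalModelSpec("PLS", nlv=3)
        result = fn.cross_validate([spec], X, y)
        assert result.selected == spec

    def test_empty_grid_rejected(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        with pytest.raises(ValueError, match="empty"):
            fn.cross_validate([], pp.absorbance, ref.omd)

    def test_tie_break_prefers_fewer_nlv(self):
        a = LocalModelSpec("PLS", nlv=3)
        b = LocalModelSpec("PLS", nlv=7)
        assert a.sort_key(0.02) < b.sort_key(0.02 + 1e-13)

    def test_tie_break_order(self):
        base = LocalModelSpec("KNN-LWPLSR", h=2.0, k=100, nlv=5)
        assert base.sort_key(0.1) < LocalModelSpec("KNN-LWPLSR", h=2.0, k=200, nlv=5).sort_key(0.1)
        assert base.sort_key(0.1) < LocalModelSpec("KNN-LWPLSR", h=4.0, k=100, nlv=5).sort_key(0.1)

    def test_nlv_recovery_on_linear_data(self):
        """Three informative latent directions: cross-validation should pick
        a small component count, never the overfit end of the grid."""
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 120, 40
            T = rng.standard_normal((n, 3))
            load = rng.standard_normal((3, p))
            X = T @ load + 0.02 * rng.standard_normal((n, p))
            y = T @ np.array([1.0, 0.6, 0.3]) + 0.05 * rng.standard_normal(n)
            grid = [LocalModelSpec("PLS", nlv=a) for a in range(1, 11)]
            picks.append(fn.cross_validate(grid, X, y).selected.nlv)
        assert all(2 <= p <= 5 for p in picks)

    def test_rmsecv_is_pooled_out_of_fold(self, small_preprocessed):
        _, pp, ref = small_preprocessed
        X, y = pp.absorbance[:60], ref.omd[:60]
        result = fn.cross_validate([LocalModelSpec("PLS", nlv=2)], X, y, n_folds=5)
        folds = fn.interleaved_folds(60, 5)
        pooled = np.empty(60)
        for f in range(5):
            res = fn.PLS(y[folds != f], X[folds != f]).fit(2)
            pooled[folds == f] = res.predict(X[folds == f])
        expect = np.sqrt(np.mean((pooled - y) ** 2))
        assert result.selected_rmsecv == pytest.approx(expect, abs=1e-12)
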