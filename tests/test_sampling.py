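"""PCA scores, standardized Mahalanobis H, Kennard-Stone selection and
interleaved folds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fecalnirs as fn


class TestPCAScores:
    def test_two_dimensional_affine_subspace(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 7))
        X = 1.5 + rng.standard_normal((30, 2)) @ basis
        scores, evr = fn.pca_scores(X, variance_target=0.999)
        assert scores.shape[1] == 2
        assert np.sum(evr > 1e-12) == 2

    def test_explained_variance_properties(self):
        X = np.random.default_rng(1).standard_normal((25, 6))
        _, evr = fn.pca_scores(X)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-12

    def test_agreement_with_eigendecomposition(self):
        """Scores match the covariance eigendecomposition oracle up to sign."""
        X = np.random.default_rng(2).standard_normal((40, 5))
        scores, _ = fn.pca_scores(X, variance_target=1.0)
        Xc = X - X.mean(axis=0)
        vals, vecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(vals)[::-1]
        oracle = Xc @ vecs[:, order]
        for j in range(scores.shape[1]):
            sign = np.sign(oracle[0, j] * scores[0, j]) or 1.0
            np.testing.assert_allclose(scores[:, j], sign * oracle[:, j], atol=1e-8)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fn.pca_scores(np.ones((5, 3)))


class TestMahalanobisH:
    def test_centroid_is_zero(self):
        T = np.random.default_rng(3).standard_normal((50, 4))
        assert fn.mahalanobis_h(T.mean(axis=0), T) == pytest.approx(0.0, abs=1e-20)

    def test_identity_covariance_arithmetic(self):
        """Centered point (3,4) under unit covariance: D^2=25, H=12.5."""
        rng = np.random.default_rng(4)
        n = 200_000
        T = rng.standard_normal((n, 2))
        T = (T - T.mean(axis=0)) / T.std(axis=0, ddof=1)
        h = fn.mahalanobis_h(np.array([3.0, 4.0]), T)
        assert h == pytest.approx(12.5, rel=0.02)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_invariance_under_invertible_maps(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.standard_normal((30, 3))
        q = rng.standard_normal(3)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        h0 = fn.mahalanobis_h(q, T)
        h1 = fn.mahalanobis_h(q @ A, T @ A)
        assert h1 == pytest.approx(h0, rel=1e-6)

    def test_training_mean_h_near_one(self):
        T = np.random.default_rng(5).standard_normal((150, 4))
        h = fn.mahalanobis_h(T, T)
        assert 0.8 < h.mean() < 1.2

    def test_singular_covariance_rejected(self):
        T = np.zeros((10, 2))
        T[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="singular|fewer"):
            fn.mahalanobis_h(np.array([1.0, 1.0]), T)


@pytest.fixture(scope="module")
def cal_spectra():
    rng = np.random.default_rng(6)
    wl = np.linspace(400, 2500, 50)
    basis = rng.standard_normal((3, 50))
    X = rng.standard_normal((120, 3)) @ basis + 0.002 * rng.standard_normal((120, 50))
    return fn.SpectraSet([f"c{i}" for i in range(120)], wl, X)


class TestScreenOutliers:
    def test_self_screening_mean_h_near_one(self, cal_spectra):
        rep = fn.screen_outliers(cal_spectra, cal_spectra)
        assert 0.8 < rep.h_values.mean() < 1.2
        assert len(rep.excluded_ids) < 0.05 * 120

    def test_constructed_outlier_flagged(self, cal_spectra):
        """Centroid + 10 SD along PC1 in a 3-component space: H = 100/3."""
        scores, _ = fn.pca_scores(cal_spectra.absorbance, variance_target=0.999)
        assert scores.shape[1] == 3
        Xc = cal_spectra.absorbance - cal_spectra.absorbance.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        pc1_sd = scores[:, 0].std(ddof=1)
        outlier = cal_spectra.absorbance.mean(axis=0) + 10 * pc1_sd * Vt[0]
        query = fn.SpectraSet(["q"], cal_spectra.wavelengths_nm, outlier[None, :])
        rep = fn.screen_outliers(query, cal_spectra, variance_target=0.999)
        assert rep.h_values[0] == pytest.approx(100 / 3, rel=0.05)
        assert list(rep.excluded_ids) == ["q"]

    def test_infinite_threshold_excludes_none(self, cal_spectra):
        rep = fn.screen_outliers(cal_spectra, cal_spectra, threshold=np.inf)
        assert len(rep.excluded_ids) == 0


class TestKennardStone:
    def test_extreme_pair(self):
        X = np.arange(11.0)[:, None]
        split = fn.kennard_stone(X, 2)
        assert sorted(split.validation_ids) == [0, 10]

    def test_third_point_is_midpoint(self):
        X = np.arange(11.0)[:, None]
        split = fn.kennard_stone(X, 3)
        assert sorted(split.validation_ids) == [0, 5, 10]

    def test_select_all(self):
        X = np.random.default_rng(7).standard_normal((6, 2))
        split = fn.kennard_stone(X, 6)
        assert len(split.validation_ids) == 6
        assert len(split.calibration_ids) == 0

    def test_calibration_side_option(self):
        X = np.arange(5.0)[:, None]
        split = fn.kennard_stone(X, 2, select="calibration")
        assert sorted(split.calibration_ids) == [0, 4]

    @pytest.mark.parametrize("n,n_select,seed", [(8, 3, 0), (10, 4, 1), (12, 4, 2), (9, 2, 3)])
    def test_matches_bruteforce_maximin(self, n, n_select, seed):
        """Exhaustive oracle: over all candidate orderings, the greedy maximin
        choice at each step is unique up to the documented index tie-break."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)

        # brute-force greedy maximin with lowest-index tie-break
        best_pair = max(
            itertools.combinations(range(n), 2), key=lambda p: (D[p], -p[0], -p[1])
        )
        chosen = list(best_pair)
        while len(chosen) < n_select:
            cands = [i for i in range(n) if i not in chosen]
            nxt = max(cands, key=lambda i: (min(D[i, j] for j in chosen), -i))
            chosen.append(nxt)

        split = fn.kennard_stone(X, n_select)
        assert sorted(split.validation_ids) == sorted(chosen)

    def test_out_of_range_rejected(self):
        X = np.zeros((4, 1))
        with pytest.raises(ValueError):
            fn.kennard_stone(X, 1)
        with pytest.raises(ValueError):
            fn.kennard_stone(X, 5)


class TestInterleavedFolds:
    def test_ten_in_five(self):
        folds = fn.interleaved_folds(10, 5)
        assert [sorted(np.flatnonzero(folds == f)) for f in range(5)] == [
            [0, 5], [1, 6], [2, 7], [3, 8], [4, 9],
        ]

    def test_uneven_sizes(self):
        folds = fn.interleaved_folds(7, 5)
        sizes = [int(np.sum(folds == f)) for f in range(5)]
        assert sizes == [2, 2, 1, 1, 1]
        assert sorted(np.flatnonzero(folds == 0)) == [0, 5]

    @pytest.mark.parametrize("n,k", [(5, 5), (23, 5), (100, 7)])
    def test_partition(self, n, k):
        folds = fn.interleaved_folds(n, k)
        assert len(folds) == n
        assert set(folds) == set(range(k))
        assert max(np.bincount(folds)) - min(np.bincount(folds)) <= 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fn.interleaved_folds(3, 5)
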