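"""Scatter decomposition, MANOVA statistics against an independent
eigen-decomposition oracle, Mahalanobis distances, and phase contrasts."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

import stagedisc as sd
from stagedisc import mvstat, prep
from stagedisc.mvstat import (
    RegularizedCovariance,
    ScatterPair,
    StageDistanceMatrix,
    scatter_from_arrays,
)
from stagedisc.prep import StageLabelSeries, VoxelTimeSeries


def _ts(data):
    data = np.asarray(data, float)
    return VoxelTimeSeries(data=data, tr_seconds=2.0, voxel_ids=np.arange(data.shape[1]))


def _labels(y, K=None):
    y = np.asarray(y, int)
    return StageLabelSeries(labels=y, trial_ids=np.zeros_like(y), n_stages=K or y.max())


def brute_force_scatter(x, y):
    """Double-loop H/E summation, the oracle for scatter_matrices."""
    classes = np.unique(y)
    grand = x.mean(axis=0)
    p = x.shape[1]
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for c in classes:
        xc = x[y == c]
        mu = xc.mean(axis=0)
        H += len(xc) * np.outer(mu - grand, mu - grand)
        for row in xc:
            E += np.outer(row - mu, row - mu)
    return H, E


class TestScatterMatrices:
    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((30, 3))
        y = np.repeat([1, 2, 3], 10)
        sp = scatter_from_arrays(x, y)
        H, E = brute_force_scatter(x, y)
        assert np.allclose(sp.H, H, atol=1e-10)
        assert np.allclose(sp.E, E, atol=1e-10)

    def test_decomposition_identity(self, signal_dataset):
        shifted = prep.shift_labels(signal_dataset.labels, 2)
        sp = mvstat.scatter_matrices(signal_dataset.rois["sig"], shifted)
        x = signal_dataset.rois["sig"].data[shifted.labeled_mask]
        total = (x - x.mean(0)).T @ (x - x.mean(0))
        assert np.allclose(sp.H + sp.E, total, rtol=1e-8, atol=1e-8)

    def test_identical_class_means_zero_between_scatter(self):
        base = np.array([[1.0, 2.0], [3.0, -1.0], [-4.0, 0.5], [0.0, 1.5]])
        x = np.vstack([base, base, base])  # three classes with equal means
        y = np.repeat([1, 2, 3], 4)
        sp = scatter_from_arrays(x, y)
        assert np.linalg.norm(sp.H) < 1e-8

    def test_single_scan_class_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError, match="2"):
            scatter_from_arrays(x, np.array([1, 1, 1, 1, 2]))


class TestManovaStats:
    def test_zero_between_scatter_gives_null_triple(self):
        E = np.eye(3) * 2
        sp = ScatterPair(
            H=np.zeros((3, 3)), E=E, class_counts=np.array([5, 5]),
            class_ids=np.array([1, 2]), grand_mean=np.zeros(3),
            class_means=np.zeros((2, 3)),
        )
        t = mvstat.manova_stats(sp)
        assert t.wilks_lambda == pytest.approx(1.0)
        assert t.lawley_hotelling == pytest.approx(0.0)
        assert t.roy_gcr == pytest.approx(0.0)

    def test_scalar_case(self):
        sp = ScatterPair(
            H=np.array([[2.0]]), E=np.array([[2.0]]),
            class_counts=np.array([5, 5]), class_ids=np.array([1, 2]),
            grand_mean=np.zeros(1), class_means=np.zeros((2, 1)),
        )
        t = mvstat.manova_stats(sp)
        assert t.wilks_lambda == pytest.approx(0.5, abs=1e-12)
        assert t.lawley_hotelling == pytest.approx(1.0, abs=1e-12)
        assert t.roy_gcr == pytest.approx(1.0, abs=1e-12)

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        """Random PD scatter pairs: the triple must match the closed forms on
        the eigenvalues of H E^-1 to 1e-10."""
        for _ in range(10):
            a = rng.standard_normal((6, 4))
            b = rng.standard_normal((8, 4))
            H = a.T @ a
            E = b.T @ b + 4 * np.eye(4)
            sp = ScatterPair(
                H=H, E=E, class_counts=np.array([10, 10]),
                class_ids=np.array([1, 2]), grand_mean=np.zeros(4),
                class_means=np.zeros((2, 4)),
            )
            lam = np.real(scipy.linalg.eigvals(H @ np.linalg.inv(E)))
            lam = np.clip(np.sort(lam), 0, None)
            t = mvstat.manova_stats(sp)
            assert t.wilks_lambda == pytest.approx(np.prod(1 / (1 + lam)), abs=1e-10)
            assert t.lawley_hotelling == pytest.approx(lam.sum(), abs=1e-10)
            assert t.roy_gcr == pytest.approx(lam.max(), abs=1e-10)

    def test_univariate_reduction_is_monotone_transform_of_f(self, rng):
        """For p = 1 all three statistics are deterministic transforms of the
        independently computed one-way F statistic."""
        y = np.repeat([1, 2, 3], 20)
        n, K = len(y), 3
        for _ in range(5):
            x = rng.standard_normal((n, 1)) + 0.5 * (y == 2)[:, None]
            sp = scatter_from_arrays(x, y)
            t = mvstat.manova_stats(sp)
            f_oracle = scipy.stats.f_oneway(*(x[y == c, 0] for c in (1, 2, 3))).statistic
            lam_from_f = f_oracle * (K - 1) / (n - K)
            assert t.lawley_hotelling == pytest.approx(lam_from_f, rel=1e-10)
            assert t.roy_gcr == pytest.approx(lam_from_f, rel=1e-10)
            assert t.wilks_lambda == pytest.approx(1 / (1 + lam_from_f), rel=1e-10)

    def test_singular_within_scatter_needs_shrinkage(self):
        E = np.zeros((2, 2))
        sp = ScatterPair(
            H=np.eye(2), E=E, class_counts=np.array([3, 3]),
            class_ids=np.array([1, 2]), grand_mean=np.zeros(2),
            class_means=np.zeros((2, 2)),
        )
        with pytest.raises(ValueError, match="shrink"):
            mvstat.manova_stats(sp, 0.0)


class TestRegularizedCov:
    def _fixture(self, rng):
        x = rng.standard_normal((40, 4)) @ rng.standard_normal((4, 4))
        y = np.repeat([1, 2], 20)
        return _ts(x), _labels(y)

    def test_lambda_zero_is_pooled(self, rng):
        ts, labels = self._fixture(rng)
        sp = mvstat.scatter_matrices(ts, labels)
        cov = mvstat.regularized_cov(ts, labels, 0.0)
        assert np.allclose(cov.sigma_hat, sp.E / (40 - 2), atol=1e-12)

    def test_lambda_one_is_diagonal(self, rng):
        ts, labels = self._fixture(rng)
        cov = mvstat.regularized_cov(ts, labels, 1.0)
        off = cov.sigma_hat - np.diag(np.diag(cov.sigma_hat))
        assert np.allclose(off, 0, atol=1e-14)

    def test_half_lambda_halves_off_diagonals(self, rng):
        ts, labels = self._fixture(rng)
        c0 = mvstat.regularized_cov(ts, labels, 0.0).sigma_hat
        c5 = mvstat.regularized_cov(ts, labels, 0.5).sigma_hat
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(c5[off], 0.5 * c0[off], atol=1e-12)
        assert np.allclose(np.diag(c5), np.diag(c0), atol=1e-12)

    def test_invalid_lambda_rejected(self, rng):
        ts, labels = self._fixture(rng)
        with pytest.raises(ValueError):
            mvstat.regularized_cov(ts, labels, 1.5)


class TestMahalanobis:
    def test_zero_distance_to_self(self):
        cov = RegularizedCovariance(np.eye(3), 0.0)
        assert mvstat.mahalanobis_sq(np.ones(3), np.ones(3), cov) == 0.0

    def test_identity_covariance_unit_basis(self):
        cov = RegularizedCovariance(np.eye(4), 0.0)
        e2 = np.eye(4)[2]
        assert mvstat.mahalanobis_sq(e2, np.zeros(4), cov) == pytest.approx(1.0)

    def test_matches_explicit_inverse_oracle(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal(5), rng.standard_normal(5)
            m = rng.standard_normal((8, 5))
            sigma = m.T @ m + np.eye(5)
            cov = RegularizedCovariance(sigma, 0.0)
            oracle = (a - b) @ np.linalg.inv(sigma) @ (a - b)
            assert mvstat.mahalanobis_sq(a, b, cov) == pytest.approx(oracle, abs=1e-10)

    def test_affine_invariance_at_lambda_zero(self, rng):
        """Mahalanobis stage distances are invariant (tol 1e-6) under any
        invertible linear transform of the data when no shrinkage is used."""
        x = rng.standard_normal((60, 4))
        y = np.repeat([1, 2, 3], 20)
        ts, labels = _ts(x), _labels(y)
        d0 = mvstat.stage_distance_matrix(ts, labels, 0.0).d2
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        d1 = mvstat.stage_distance_matrix(_ts(x @ A), labels, 0.0).d2
        assert np.allclose(d0, d1, atol=1e-6)

    def test_non_pd_covariance_rejected(self):
        cov = RegularizedCovariance(np.diag([1.0, -1.0]), 0.0)
        with pytest.raises(ValueError):
            mvstat.mahalanobis_sq(np.ones(2), np.zeros(2), cov)


class TestStageDistanceMatrix:
    def test_symmetry_and_zero_diagonal(self, signal_dataset):
        shifted = prep.shift_labels(signal_dataset.labels, 2)
        dm = mvstat.stage_distance_matrix(signal_dataset.rois["sig"], shifted)
        assert np.allclose(dm.d2, dm.d2.T)
        assert np.allclose(np.diag(dm.d2), 0)
        assert np.all(dm.d2 >= 0)

    def test_two_class_consistency_with_direct_distance(self, rng):
        x = rng.standard_normal((40, 3))
        y = np.repeat([1, 2], 20)
        ts, labels = _ts(x), _labels(y)
        dm = mvstat.stage_distance_matrix(ts, labels, 0.1)
        cov = mvstat.regularized_cov(ts, labels, 0.1)
        mu1, mu2 = x[y == 1].mean(0), x[y == 2].mean(0)
        assert dm.d2[0, 1] == pytest.approx(mvstat.mahalanobis_sq(mu1, mu2, cov))

    def test_stage4_pattern_dominates_distances(self):
        """An ROI informative only about the decision stage must show its
        largest pairwise distances in the stage-4 row/column."""
        roi = sd.RoiSpec(
            name="a", n_voxels=16, n_informative=5, effect_amplitude=1.2,
            stage_pattern_mode=(4,), pattern_strength="unit",
        )
        wins = 0
        for r in range(20):
            ds = sd.simulate_dataset(sd.default_design(), [roi], seed=70 + r)
            shifted = prep.shift_labels(ds.labels, ds.ground_truth.lag_trs)
            d2 = mvstat.stage_distance_matrix(ds.rois["a"], shifted, 0.1).d2
            off = d2.copy()
            np.fill_diagonal(off, -np.inf)
            i, j = np.unravel_index(np.argmax(off), off.shape)
            wins += 3 in (i, j)
        assert wins >= 18


class TestPhaseContrast:
    def test_constant_matrix_gives_constant_contrasts(self):
        d2 = np.full((6, 6), 3.0)
        np.fill_diagonal(d2, 0)
        making, evaluation = mvstat.phase_contrast(StageDistanceMatrix(d2, 6))
        assert making == pytest.approx(3.0)
        assert evaluation == pytest.approx(3.0)

    def test_hand_filled_matrix(self):
        d2 = np.ones((6, 6))
        np.fill_diagonal(d2, 0)
        d2[0, 3] = d2[3, 0] = 2.0
        d2[1, 3] = d2[3, 1] = 4.0
        d2[2, 3] = d2[3, 2] = 6.0
        making, evaluation = mvstat.phase_contrast(StageDistanceMatrix(d2, 6))
        assert making == pytest.approx(4.0)
        assert evaluation == pytest.approx(1.0)

    def test_wrong_stage_count_rejected(self):
        with pytest.raises(ValueError):
            mvstat.phase_contrast(StageDistanceMatrix(np.zeros((5, 5)), 5))
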