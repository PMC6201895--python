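"""Cluster statistics: closed-form values, matrix identities, hull oracle."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.stats import wishart

from attnquality import (
    centroid,
    cluster_dispersion,
    compute_cluster_stats,
    correlation,
    covariance,
    eigen_features,
    euclidean_distances,
    graham_scan,
    itm,
    kmeans,
    tld_distance,
    tld_divergence,
)

I2 = np.eye(2)


def _random_spd(rng, n=2):
    a = rng.standard_normal((n, n))
    return a @ a.T + 0.1 * np.eye(n)


class TestFirstOrder:
    def test_centroid_examples(self):
        np.testing.assert_allclose(centroid([[0.3, 0.7]]), [0.3, 0.7])
        np.testing.assert_allclose(centroid([[0, 0], [1, 1]]), [0.5, 0.5])

    def test_centroid_distance_from_printed_group_centres(self):
        d = euclidean_distances([[0.1771, 0.6390], [0.7244, 0.6335]])
        assert d[0, 1] == pytest.approx(0.54733, abs=1e-4)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        C = np.random.default_rng(0).random((5, 3))
        d = euclidean_distances(C)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestDispersion:
    def test_identical_pair_zero(self):
        sigma, _ = cluster_dispersion([[0.4, 0.4], [0.4, 0.4]])
        assert sigma == 0.0

    def test_unbiased_two_point_value(self):
        sigma, per_dim = cluster_dispersion([[0.0], [1.0]])
        assert sigma == pytest.approx(math.sqrt(0.5))
        assert per_dim == pytest.approx(math.sqrt(0.5))

    def test_sigma_squared_equals_covariance_trace(self):
        X = np.random.default_rng(1).random((25, 3))
        sigma, _ = cluster_dispersion(X)
        assert sigma ** 2 == pytest.approx(np.trace(covariance(X)), abs=1e-10)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            cluster_dispersion([[1.0, 2.0]])


class TestCovarianceCorrelation:
    def test_two_point_hand_value(self):
        np.testing.assert_allclose(covariance([[0, 0], [1, 1]]),
                                   [[0.5, 0.5], [0.5, 0.5]])

    def test_identical_points_zero_matrix(self):
        np.testing.assert_allclose(covariance([[0.2, 0.3]] * 4), 0.0)

    def test_symmetric_psd(self):
        X = np.random.default_rng(2).random((30, 3))
        S = covariance(X)
        np.testing.assert_allclose(S, S.T, atol=1e-14)
        assert np.linalg.eigvalsh(S).min() >= -1e-12

    def test_correlation_normalization(self):
        np.testing.assert_allclose(correlation([[0.5, 0.5], [0.5, 0.5]]),
                                   [[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(correlation(I2), I2)
        C = correlation(covariance(np.random.default_rng(3).random((20, 3))))
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(np.abs(C) <= 1 + 1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlation([[0.0, 0.0], [0.0, 1.0]])


class TestTLD:
    def test_self_divergence_zero(self):
        S = _random_spd(np.random.default_rng(0))
        assert tld_divergence(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_and_asymmetry(self):
        assert tld_divergence(2 * I2, I2) == pytest.approx(1 - math.log(2), abs=1e-12)
        assert tld_divergence(I2, 2 * I2) == pytest.approx((math.log(4) - 1) / 2,
                                                           abs=1e-12)

    def test_distance_closed_form_quarter(self):
        assert tld_distance(2 * I2, I2) == pytest.approx(0.25, abs=1e-14)

    def test_metric_axioms_on_random_spd_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            A, B = _random_spd(rng), _random_spd(rng)
            dab, dba = tld_distance(A, B), tld_distance(B, A)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)
        assert tld_distance(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_inequality_checked_empirically(self):
        """The symmetrized log-det divergence is not guaranteed to satisfy
        the triangle inequality; count violations on 1000 random SPD triples
        instead of assuming it."""
        rng = np.random.default_rng(5)
        violations = 0
        for _ in range(1000):
            A, B, C = (wishart.rvs(4, 0.25 * I2, random_state=rng)
                       for _ in range(3))
            if tld_distance(A, B) + tld_distance(B, C) < tld_distance(A, C) - 1e-12:
                violations += 1
        # report the measured rate; the property is empirical, not axiomatic
        assert 0 <= violations <= 1000

    def test_singular_matrix_rejected_not_regularized(self):
        singular = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            tld_divergence(I2, singular)
        with pytest.raises(ValueError):
            itm(singular)


class TestITM:
    def test_identity_is_zero_in_both_conventions(self):
        assert itm(I2, "unnormalized") == 0.0
        assert itm(I2, "per_dimension") == 0.0

    def test_scaled_identity_closed_form(self):
        assert itm(2 * I2, "per_dimension") == pytest.approx(1 - math.log(2))
        assert itm(2 * I2, "unnormalized") == pytest.approx(2 - 2 * math.log(2))

    def test_conventions_differ_by_dimension_factor(self):
        S = _random_spd(np.random.default_rng(6), n=3)
        assert itm(S, "per_dimension") == pytest.approx(itm(S, "unnormalized") / 3,
                                                        abs=1e-12)

    def test_equals_tld_divergence_from_identity(self):
        S = _random_spd(np.random.default_rng(7), n=3)
        assert itm(S, "per_dimension") == pytest.approx(
            tld_divergence(S, np.eye(3)), abs=1e-12)


class TestEigenFeatures:
    def test_diagonal_matrix(self):
        vals, vecs = eigen_features(np.diag([3.0, 1.0, 2.0]))
        np.testing.assert_allclose(vals, [3.0, 2.0, 1.0])
        np.testing.assert_allclose(np.abs(vecs),
                                   np.eye(3)[:, [0, 2, 1]], atol=1e-12)

    def test_two_by_two_closed_form(self):
        S = np.array([[0.0076, 0.0005], [0.0005, 0.0047]])
        vals, _ = eigen_features(S)
        tr, det = S.trace(), np.linalg.det(S)
        lam1 = (tr + math.sqrt(tr ** 2 - 4 * det)) / 2
        np.testing.assert_allclose(vals, [lam1, tr - lam1], atol=1e-12)

    def test_reconstruction_and_orthonormality(self):
        S = _random_spd(np.random.default_rng(8), n=3)
        vals, vecs = eigen_features(S)
        recon = (vecs * vals) @ vecs.T
        assert np.max(np.abs(recon - S)) < 1e-10
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(3), atol=1e-10)
        assert np.all(np.diff(vals) <= 0)

    def test_sign_convention_reproducible(self):
        S = _random_spd(np.random.default_rng(9), n=3)
        _, vecs = eigen_features(S)
        for j in range(3):
            assert vecs[np.argmax(np.abs(vecs[:, j])), j] > 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigen_features([[1.0, 2.0], [0.0, 1.0]])


class TestGrahamScan:
    def test_triangle_returned_whole(self):
        pts = [[0, 0], [1, 0], [0.5, 1]]
        hull = graham_scan(pts)
        assert len(hull) == 3

    def test_interior_and_collinear_points_excluded(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5], [0.5, 0.0]]
        hull = graham_scan(pts)
        assert len(hull) == 4
        assert {tuple(v) for v in hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_starts_at_lowest_point_counter_clockwise(self):
        hull = graham_scan([[0, 0], [1, 0], [1, 1], [0, 1]])
        np.testing.assert_allclose(hull[0], [0, 0])
        area2 = sum(hull[i - 1][0] * hull[i][1] - hull[i][0] * hull[i - 1][1]
                    for i in range(len(hull)))
        assert area2 > 0  # counter-clockwise orientation

    def test_matches_qhull_on_random_sets(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pts = rng.random((30, 2))
            ours = {tuple(np.round(v, 12)) for v in graham_scan(pts)}
            ref = {tuple(np.round(pts[i], 12)) for i in ConvexHull(pts).vertices}
            assert ours == ref

    def test_degenerate_inputs_return_extremes(self):
        with pytest.warns(UserWarning, match="degenerate"):
            hull = graham_scan([[0, 0], [1, 1]])
        assert len(hull) == 2
        with pytest.warns(UserWarning, match="degenerate"):
            hull = graham_scan([[0, 0], [1, 1], [2, 2], [3, 3]])
        assert {tuple(v) for v in hull} <= {(0, 0), (1, 1), (2, 2), (3, 3)}
        assert (0, 0) in {tuple(v) for v in hull}
        assert (3, 3) in {tuple(v) for v in hull}


class TestComputeClusterStats:
    def test_integration_with_partition(self, feature_table):
        part = kmeans(feature_table, k=4, seed=0)
        stats, metrics = compute_cluster_stats(feature_table,
                                               part.assignments, K=4)
        assert len(stats) == 4
        assert sum(s.size for s in stats) == len(feature_table)
        total = sum(s.sse for s in stats)
        assert total == pytest.approx(part.sse_total, abs=1e-9)
        for s in stats:
            assert s.sigma ** 2 == pytest.approx(np.trace(s.covariance),
                                                 abs=1e-10)
            assert s.itm_per_dimension == pytest.approx(
                s.itm_unnormalized / feature_table.shape[1], abs=1e-12)
        np.testing.assert_allclose(metrics.tld_distance,
                                   metrics.tld_distance.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(metrics.tld_divergence), 0.0)

    def test_undersized_cluster_yields_nan_not_crash(self):
        X = np.array([[0.0, 0.0], [0.0, 0.1], [0.1, 0.0], [5.0, 5.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats, _ = compute_cluster_stats(X, np.array([0, 0, 0, 1]), K=2)
        assert math.isnan(stats[1].sigma)
        assert stats[1].size == 1
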