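"""Geometry of covariance descriptors: estimation, metric, mean, tangent map.

Oracles are independent of the implementation paths: covariance against a
brute-force double loop over channel pairs, the distance against
``scipy.linalg.logm``/``sqrtm`` (dense matrix functions, not the generalized
symmetric eigenproblem the implementation uses), and closed forms for
commuting/diagonal matrices.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from posturekit.datamodel_io import JointSubset
from posturekit.spd_geometry import (
    NotSPDError,
    NotSPDWarning,
    TangentFeatureModel,
    estimate_covariance,
    fit_feature_model,
    logeuclidean_mean,
    riemannian_distance,
    tangent_project,
    unvectorize,
    upper_vectorize,
)
from tests.conftest import random_spd


def brute_force_covariance(x: np.ndarray) -> np.ndarray:
    """Elementwise oracle for the 1/Nt covariance with mean removal."""
    n, nt = x.shape
    means = [sum(x[i]) / nt for i in range(n)]
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = sum(
                (x[i, t] - means[i]) * (x[j, t] - means[j]) for t in range(nt)
            ) / nt
    return c


def oracle_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    """Distance via dense logm of the whitened matrix (independent route)."""
    isqrt = np.real(scipy.linalg.inv(scipy.linalg.sqrtm(c1)))
    return float(np.linalg.norm(scipy.linalg.logm(isqrt @ c2 @ isqrt), "fro"))


class TestEstimateCovariance:
    def test_hand_example(self):
        x = np.array([[1, -1, 1, -1], [-1, 1, -1, 1]], dtype=float)
        with pytest.warns(NotSPDWarning):
            c = estimate_covariance(x, shrinkage=0.0)
        np.testing.assert_allclose(c, [[1, -1], [-1, 1]], atol=1e-14)

    def test_constant_signals_flagged(self):
        x = np.array([[1, 1, 1], [2, 2, 2]], dtype=float)
        with pytest.warns(NotSPDWarning):
            c = estimate_covariance(x, shrinkage=0.0)
        np.testing.assert_allclose(c, np.zeros((2, 2)), atol=1e-14)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((4, 50))
        c = estimate_covariance(x, shrinkage=0.0)
        np.testing.assert_allclose(c, brute_force_covariance(x), rtol=1e-12)

    def test_shrinkage_adds_scaled_identity(self, rng):
        x = rng.standard_normal((3, 40))
        c0 = estimate_covariance(x, shrinkage=0.0)
        c1 = estimate_covariance(x, shrinkage=0.1)
        np.testing.assert_allclose(
            c1 - c0, 0.1 * (np.trace(c0) / 3) * np.eye(3), rtol=1e-10
        )

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="frames"):
            estimate_covariance(np.ones((3, 1)))


class TestRiemannianDistance:
    def test_identity_of_indiscernibles(self):
        assert riemannian_distance(np.eye(3), np.eye(3)) == 0.0

    def test_commuting_closed_form(self):
        # eigenvalues of C1^{-1} C2 are (4, 4): sqrt(2) * ln 4
        d = riemannian_distance(np.diag([1.0, 1.0]), np.diag([4.0, 4.0]))
        assert d == pytest.approx(np.sqrt(2) * np.log(4), rel=1e-12)

    def test_matches_dense_logm_oracle(self, rng):
        for _ in range(20):
            c1 = random_spd(rng, 5)
            c2 = random_spd(rng, 5)
            assert riemannian_distance(c1, c2) == pytest.approx(
                oracle_distance(c1, c2), rel=1e-8
            )

    def test_metric_axioms(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            a, b, c = (random_spd(rng, n) for _ in range(3))
            dab = riemannian_distance(a, b)
            assert dab >= 0
            assert abs(dab - riemannian_distance(b, a)) <= 1e-10 * max(dab, 1)
            assert dab <= (
                riemannian_distance(a, c) + riemannian_distance(c, b) + 1e-8
            )

    def test_affine_invariance(self, rng):
        for _ in range(50):
            c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
            v = rng.standard_normal((4, 4))
            v += 4 * np.eye(4)  # keep well away from singular
            d = riemannian_distance(c1, c2)
            dt = riemannian_distance(v @ c1 @ v.T, v @ c2 @ v.T)
            assert dt == pytest.approx(d, rel=1e-8)

    def test_inversion_invariance(self, rng):
        for _ in range(50):
            c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
            d = riemannian_distance(c1, c2)
            di = riemannian_distance(
                np.linalg.inv(c1), np.linalg.inv(c2)
            )
            assert di == pytest.approx(d, rel=1e-8)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            riemannian_distance(np.eye(2), np.eye(3))

    def test_non_spd_argument(self):
        with pytest.raises(NotSPDError):
            riemannian_distance(np.diag([1.0, -1.0]), np.eye(2))


class TestLogEuclideanMean:
    def test_idempotence(self, rng):
        c = random_spd(rng, 4)
        np.testing.assert_allclose(logeuclidean_mean([c, c]), c, atol=1e-10)

    def test_single_matrix(self, rng):
        c = random_spd(rng, 3)
        np.testing.assert_allclose(logeuclidean_mean([c]), c, atol=1e-10)

    def test_commuting_geometric_mean(self):
        m = logeuclidean_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        np.testing.assert_allclose(m, np.diag([2.0, 2.0]), rtol=1e-12)

    def test_commutes_with_rotation(self, rng):
        mats = [random_spd(rng, 5) for _ in range(4)]
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        rotated = logeuclidean_mean([q @ c @ q.T for c in mats])
        np.testing.assert_allclose(
            rotated, q @ logeuclidean_mean(mats) @ q.T, atol=1e-8
        )

    def test_empty_list(self):
        with pytest.raises(ValueError, match="empty"):
            logeuclidean_mean([])


class TestTangentProjection:
    def test_reference_maps_to_zero(self, rng):
        c = random_spd(rng, 4)
        model = TangentFeatureModel.from_reference(c)
        np.testing.assert_allclose(
            tangent_project(c, model), np.zeros(10), atol=1e-10
        )

    def test_scalar_log_example(self):
        model = TangentFeatureModel.from_reference(np.eye(2))
        v = tangent_project(np.diag([np.e**2, np.e**2]), model)
        np.testing.assert_allclose(v, [2.0, 0.0, 2.0], atol=1e-12)

    def test_norm_equivalence(self, rng):
        for _ in range(50):
            ref = random_spd(rng, 5)
            c = random_spd(rng, 5)
            model = TangentFeatureModel.from_reference(ref)
            assert np.linalg.norm(tangent_project(c, model)) == pytest.approx(
                riemannian_distance(c, ref), rel=1e-8
            )

    def test_vectorize_round_trip(self, rng):
        s = rng.standard_normal((6, 6))
        s = s + s.T
        np.testing.assert_allclose(
            unvectorize(upper_vectorize(s)), s, atol=1e-12
        )

    def test_dimension_mismatch(self, rng):
        model = TangentFeatureModel.from_reference(np.eye(3))
        with pytest.raises(ValueError, match="mismatch"):
            tangent_project(random_spd(rng, 4), model)


class TestGeometryProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 6))
    def test_distance_norm_equivalence_any_pair(self, seed, n):
        """The tangent vector's 2-norm equals the manifold distance."""
        rng = np.random.default_rng(seed)
        ref, c = random_spd(rng, n), random_spd(rng, n)
        model = TangentFeatureModel.from_reference(ref)
        assert np.linalg.norm(tangent_project(c, model)) == pytest.approx(
            riemannian_distance(c, ref), rel=1e-8, abs=1e-10
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 6))
    def test_log_mean_lies_between_in_distance(self, seed, n):
        """The mean of two points is no farther from either than they are
        from each other."""
        rng = np.random.default_rng(seed)
        c1, c2 = random_spd(rng, n), random_spd(rng, n)
        m = logeuclidean_mean([c1, c2])
        d12 = riemannian_distance(c1, c2)
        assert riemannian_distance(c1, m) <= d12 + 1e-8
        assert riemannian_distance(c2, m) <= d12 + 1e-8


class TestFitFeatureModel:
    @pytest.mark.parametrize(
        "subset,expected_dim",
        [(JointSubset.UPPER_16, 48 * 49 // 2), (JointSubset.SPINE_4, 78)],
    )
    def test_feature_dimensions(self, small_dataset, subset, expected_dim):
        trials = [t for t in small_dataset
                  if t.device.value == "MK2" and t.subject_id == "S01"][:10]
        model, feats = fit_feature_model(trials, subset)
        assert feats.shape == (10, expected_dim)
        assert model.n_features == expected_dim

    def test_singleton_projects_to_zero(self, mk2_trial):
        model, feats = fit_feature_model([mk2_trial], JointSubset.UPPER_16)
        np.testing.assert_allclose(feats, 0.0, atol=1e-8)

    def test_empty_input(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_feature_model([])
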