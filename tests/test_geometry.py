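"""Bures-Wasserstein geometry: distance, metric, curvature and bounds."""

import numpy as np
import pytest

from wscec.geometry import (
    curvature_tensor,
    curvature_upper_bound,
    metric_gw,
    scalar_curvature,
    scalar_curvature_oracle,
    spd_sqrt,
    sylvester_gamma,
    wasserstein_gaussian,
)

from conftest import random_spd, random_symmetric


class TestSpdSqrt:
    def test_identity_and_diagonal(self):
        assert np.allclose(spd_sqrt(np.eye(3)), np.eye(3))
        assert np.allclose(spd_sqrt(np.diag([4.0, 9.0])), np.diag([2.0, 3.0]))

    def test_reconstruction(self, rng):
        for _ in range(10):
            S = random_spd(rng, 3)
            R = spd_sqrt(S)
            assert np.allclose(R @ R, S, atol=1e-10 * np.linalg.norm(S))

    def test_rejects_non_spd(self):
        with pytest.raises(ValueError):
            spd_sqrt(np.diag([1.0, -1.0]))


class TestWassersteinGaussian:
    def test_identical_gaussians_zero(self, rng):
        S = random_spd(rng, 3)
        mu = rng.normal(size=3)
        assert wasserstein_gaussian(mu, S, mu, S) == pytest.approx(0.0, abs=1e-8)

    def test_univariate_closed_form(self):
        # 1-D: W = sqrt((mu1-mu2)^2 + (sd1-sd2)^2)
        w = wasserstein_gaussian([0.0], [[4.0]], [3.0], [[1.0]])
        assert w == pytest.approx(np.sqrt(10.0), rel=1e-12)

    def test_commuting_diagonal_closed_form(self):
        w = wasserstein_gaussian(
            np.zeros(2), np.diag([4.0, 1.0]), np.zeros(2), np.diag([1.0, 4.0])
        )
        assert w == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_distance_axioms(self, rng):
        """Symmetry, identity of indiscernibles and triangle inequality."""
        for _ in range(50):
            gs = [(rng.normal(size=2), random_spd(rng, 2, (-1, 1)))
                  for _ in range(3)]
            d01 = wasserstein_gaussian(*gs[0], *gs[1])
            d10 = wasserstein_gaussian(*gs[1], *gs[0])
            d12 = wasserstein_gaussian(*gs[1], *gs[2])
            d02 = wasserstein_gaussian(*gs[0], *gs[2])
            assert d01 == pytest.approx(d10, rel=1e-10)
            assert d02 <= d01 + d12 + 1e-10
            assert wasserstein_gaussian(*gs[0], *gs[0]) < 1e-8


class TestSylvester:
    def test_identity_base(self, rng):
        Y = random_symmetric(rng, 3)
        assert np.allclose(sylvester_gamma(np.eye(3), Y), Y / 2)

    def test_diagonal_example(self):
        S = np.diag([1.0, 3.0])
        Y = np.array([[2.0, 4.0], [4.0, 6.0]])
        assert np.allclose(sylvester_gamma(S, Y), np.ones((2, 2)))

    def test_defining_equation(self, rng):
        for _ in range(10):
            S = random_spd(rng, 4)
            Y = random_symmetric(rng, 4)
            G = sylvester_gamma(S, Y)
            assert np.allclose(S @ G + G @ S, Y, atol=1e-10 * np.linalg.norm(Y))
            assert np.allclose(G, G.T, atol=1e-10)

    def test_antisymmetric_rhs_supported(self, rng):
        # the curvature tensor feeds a commutator (antisymmetric) through
        S = random_spd(rng, 3)
        A = rng.normal(size=(3, 3))
        M = A - A.T
        G = sylvester_gamma(S, M)
        assert np.allclose(S @ G + G @ S, M, atol=1e-10 * np.linalg.norm(M))


class TestMetric:
    def test_identity_base_quarter_trace(self, rng):
        X, Y = random_symmetric(rng, 3), random_symmetric(rng, 3)
        assert metric_gw(np.eye(3), X, Y) == pytest.approx(
            0.25 * np.trace(X @ Y), rel=1e-12
        )

    def test_symmetry_and_positivity(self, rng):
        for _ in range(10):
            S = random_spd(rng, 3)
            X, Y = random_symmetric(rng, 3), random_symmetric(rng, 3)
            assert metric_gw(S, X, Y) == pytest.approx(metric_gw(S, Y, X), rel=1e-10)
            assert metric_gw(S, X, X) > 0

    def test_distance_expansion_matches_metric(self, rng):
        """Squared distance of a small perturbation expands as g_W(X, X)."""
        mu = np.zeros(3)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + 0.5 * np.eye(3)
            X = random_symmetric(rng, 3)
            g = metric_gw(S, X, X)

            def d2(t):
                return wasserstein_gaussian(mu, S, mu, S + t * X) ** 2 / t**2

            t = 4e-4
            richardson = (4.0 * d2(t / 2) - d2(t)) / 3.0
            assert richardson == pytest.approx(g, rel=1e-3)


class TestCurvatureTensor:
    def test_parallel_arguments_vanish(self, rng):
        S = random_spd(rng, 3)
        X = random_symmetric(rng, 3)
        assert curvature_tensor(S, X, X) == pytest.approx(0.0, abs=1e-10)
        assert curvature_tensor(S, X, 2.5 * X) == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_pair_positive_and_bounded(self, rng):
        for _ in range(20):
            S = random_spd(rng, 3, (-1, 1))
            X = random_symmetric(rng, 3)
            Y = random_symmetric(rng, 3)
            # g-orthonormalise the pair so the sectional curvature is R itself
            X = X / np.sqrt(metric_gw(S, X, X))
            Y = Y - metric_gw(S, Y, X) * X
            Y = Y / np.sqrt(metric_gw(S, Y, Y))
            R = curvature_tensor(S, X, Y)
            lam = np.sort(np.linalg.eigvalsh(S))
            assert 0 < R < 3.0 / lam[1]

    def test_orthogonal_conjugation_invariance(self, rng):
        S = random_spd(rng, 3)
        X, Y = random_symmetric(rng, 3), random_symmetric(rng, 3)
        O, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        r1 = curvature_tensor(S, X, Y)
        r2 = curvature_tensor(O @ S @ O.T, O @ X @ O.T, O @ Y @ O.T)
        assert r1 == pytest.approx(r2, rel=1e-8)


class TestScalarCurvature:
    def test_orthogonal_invariance(self, rng):
        S = random_spd(rng, 3)
        O, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert scalar_curvature(O @ S @ O.T) == pytest.approx(
            scalar_curvature(S), rel=1e-10
        )

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_inverse_scale_law(self, rng, c):
        S = random_spd(rng, 3)
        assert scalar_curvature(c * S) == pytest.approx(
            scalar_curvature(S) / c, rel=1e-10
        )

    def test_identity_matches_oracle(self):
        # closed form and basis double-sum agree at the identity
        assert scalar_curvature(np.eye(2)) == pytest.approx(
            scalar_curvature_oracle(np.eye(2)), abs=1e-8
        )

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_oracle_on_random_matrices(self, rng, n):
        for _ in range(25):
            S = random_spd(rng, n)
            rho = scalar_curvature(S)
            assert rho == pytest.approx(scalar_curvature_oracle(S), rel=1e-6)

    def test_diagonal_example_matches_oracle(self):
        S = np.diag([1.0, 2.0, 5.0])
        assert scalar_curvature(S) == pytest.approx(
            scalar_curvature_oracle(S), rel=1e-6
        )

    def test_oracle_basis_independent(self, rng):
        """Gram-Schmidt start basis does not affect the double sum."""
        from wscec.geometry import _symmetric_basis

        S = random_spd(rng, 2)
        ref = scalar_curvature_oracle(S)
        basis = _symmetric_basis(2)
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible remix
        mixed = [sum(M[i, j] * basis[j] for j in range(3)) for i in range(3)]
        assert scalar_curvature_oracle(S, basis=mixed) == pytest.approx(ref, abs=1e-8 * abs(ref))


class TestCurvatureBound:
    def test_identity_n3(self):
        assert curvature_upper_bound(np.eye(3)) == pytest.approx(18.0)

    def test_printed_operating_point(self):
        # lam_min2 = 0.09 gives the ceiling 3*3*2/0.09 = 200
        assert curvature_upper_bound(np.diag([0.09, 0.09, 1.0])) == pytest.approx(200.0)

    def test_positivity_and_bound_random_sweep(self, rng):
        for _ in range(200):
            S = random_spd(rng, 3, (-3, 2), max_cond=1e6)
            rho = scalar_curvature(S)
            bound = curvature_upper_bound(S)
            assert 0.0 < rho < bound
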