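"""SPC network dynamics: iteration, equilibria, Jacobian stability, curves."""

import numpy as np
import pytest

from spcdn.homeostasis import HomeostasisSpec, homeostasis_from_dn
from spcdn.network import (
    IterationConfig,
    SPCNetwork,
    analytic_response_curve,
    iterate_responses,
    jacobian,
    prediction_error,
    solve_equilibrium,
    sparse_coding_cost,
    stability_eigenvalues,
)
from spcdn.normalization import DNParams, naka_rushton

ZERO = HomeostasisSpec("zero")
DN322 = DNParams(3.0, 2.0, 2.0)


def random_net(rng, L=8, M=4, hspec=None, nonnegative=True):
    A = rng.standard_normal((L, M))
    A /= np.linalg.norm(A, axis=0)
    return SPCNetwork(A=A, hspec=hspec or ZERO, nonnegative=nonnegative)


class TestPredictionError:
    def test_zero_response_returns_input(self):
        net = random_net(np.random.default_rng(0))
        x = np.arange(8.0)
        np.testing.assert_array_equal(prediction_error(net, x, np.zeros(4)), x)

    def test_exact_reconstruction_gives_zero_error(self):
        net = random_net(np.random.default_rng(1))
        s = np.array([1.0, -2.0, 0.5, 3.0])
        x = net.A @ s
        np.testing.assert_allclose(prediction_error(net, x, s), 0.0, atol=1e-14)

    def test_hand_arithmetic(self):
        net = SPCNetwork(A=np.array([[1.0], [0.0]]), hspec=ZERO)
        e = prediction_error(net, np.array([3.0, 1.0]), np.array([2.0]))
        np.testing.assert_array_equal(e, [1.0, 1.0])

    def test_dimension_mismatch(self):
        net = random_net(np.random.default_rng(2))
        with pytest.raises(ValueError, match="mismatch"):
            prediction_error(net, np.zeros(7), np.zeros(4))


class TestIterateResponses:
    def test_single_neuron_dn_equivalence_at_x10(self):
        """Converged SPC response reproduces the DN closed form (x=10)."""
        net = SPCNetwork(A=np.array([[1.0]]), hspec=homeostasis_from_dn(DN322))
        res = iterate_responses(
            net,
            np.array([10.0]),
            IterationConfig(eta_s=0.002, max_iter=5000, tol=1e-12, s_init=1.0),
        )
        assert res.converged
        assert res.s_final[0] == pytest.approx(naka_rushton(10.0, DN322), abs=1e-6)

    def test_zero_input_fixed_point_at_origin(self, reference_cc_spec):
        net = SPCNetwork(A=np.array([[1.0]]), hspec=reference_cc_spec)
        res = iterate_responses(
            net, np.array([0.0]), IterationConfig(eta_s=0.01, max_iter=100, tol=1e-12)
        )
        assert res.converged and res.s_final[0] == 0.0

    def test_orthonormal_columns_recover_projection(self):
        """With H=0 and orthonormal A the dynamics solve least squares."""
        rng = np.random.default_rng(4)
        A, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        net = SPCNetwork(A=A, hspec=ZERO, nonnegative=False)
        x = rng.standard_normal(8)
        res = iterate_responses(
            net, x, IterationConfig(eta_s=0.1, max_iter=2000, tol=1e-10)
        )
        np.testing.assert_allclose(res.s_final, A.T @ x, atol=1e-6)

    def test_oscillation_flagged_at_large_rate(self):
        """Too large an update rate produces the oscillatory regime."""
        net = SPCNetwork(A=np.array([[1.0]]), hspec=homeostasis_from_dn(DN322))
        res = iterate_responses(
            net,
            np.array([10.0]),
            IterationConfig(eta_s=1.9, max_iter=300, tol=0.0, s_init=1.0),
        )
        assert res.oscillating

    def test_trajectory_recording(self):
        net = SPCNetwork(A=np.array([[1.0]]), hspec=ZERO)
        res = iterate_responses(
            net,
            np.array([1.0]),
            IterationConfig(eta_s=0.1, max_iter=50, tol=0.0, record_trajectory=True),
        )
        assert res.trajectory is not None
        assert res.trajectory.shape == (res.iterations_used + 1, 1)

    def test_nonnegativity_enforced(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, hspec=ZERO, nonnegative=True)
        res = iterate_responses(
            net, -rng.random(8), IterationConfig(eta_s=0.05, max_iter=500, tol=1e-10)
        )
        assert np.all(res.s_final >= 0.0)


class TestEquilibrium:
    def test_single_neuron_no_homeostasis(self):
        net = SPCNetwork(A=np.array([[1.0]]), hspec=ZERO, nonnegative=False)
        eq = solve_equilibrium(net, np.array([4.2]), tol=1e-12)
        assert eq.s_eq[0] == pytest.approx(4.2)

    def test_single_neuron_dn_closed_form(self):
        net = SPCNetwork(A=np.array([[1.0]]), hspec=homeostasis_from_dn(DN322))
        eq = solve_equilibrium(net, np.array([10.0]), tol=1e-12)
        assert eq.s_eq[0] == pytest.approx(naka_rushton(10.0, DN322), abs=1e-10)
        assert eq.stable

    def test_agrees_with_long_iteration_on_random_stable_instances(self):
        rng = np.random.default_rng(11)
        hspec = HomeostasisSpec("power_prior", {"lam": 0.3, "alpha": 1.5})
        for _ in range(5):
            net = random_net(rng, hspec=hspec)
            x = rng.standard_normal(8)
            eq = solve_equilibrium(net, x, tol=1e-10)
            res = iterate_responses(
                net, x, IterationConfig(eta_s=0.05, max_iter=100_000, tol=1e-10)
            )
            np.testing.assert_allclose(eq.s_eq, res.s_final, atol=1e-5)

    def test_least_squares_limit(self):
        """H=0 and full column rank: equilibrium is the least-squares solution."""
        rng = np.random.default_rng(12)
        A = rng.standard_normal((8, 4))
        net = SPCNetwork(A=A, hspec=ZERO, nonnegative=False)
        x = rng.standard_normal(8)
        eq = solve_equilibrium(net, x, tol=1e-12)
        np.testing.assert_allclose(
            eq.s_eq, np.linalg.lstsq(A, x, rcond=None)[0], atol=1e-8
        )


class TestStability:
    def test_jacobian_structure(self):
        rng = np.random.default_rng(13)
        net = random_net(rng, hspec=ZERO)
        J = jacobian(net, np.zeros(4))
        np.testing.assert_allclose(J, -(net.A.T @ net.A), atol=1e-14)
        assert np.allclose(J, J.T)

    def test_scalar_constant_derivative(self):
        # 1 neuron, a'a = 1, H'(s) = c -> J = -(1+c)
        spec = HomeostasisSpec("power_prior", {"lam": 0.3, "alpha": 1.0})
        net = SPCNetwork(A=np.array([[1.0]]), hspec=spec)
        J = jacobian(net, np.array([0.5]))
        assert J[0, 0] == pytest.approx(-1.0)  # alpha=1 has H' = 0

    def test_negative_slope_destabilizes(self):
        """A homeostasis decreasing faster than the leak flips the eigenvalue sign."""
        spec = HomeostasisSpec("gaussian_prior", {"lam": 10.0, "sigma": 1.0})
        net = SPCNetwork(A=np.array([[1.0]]), hspec=spec)
        # H'(s) = lam*exp(-u^2)(1-2u^2): at s=sigma, H' = -lam*e^-1 ~ -3.68 < -1
        eigs, stable = stability_eigenvalues(net, np.array([1.0]))
        assert eigs[0] > 0 and not stable

    def test_orthonormal_no_homeostasis_eigenvalues_minus_one(self):
        rng = np.random.default_rng(14)
        A, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        net = SPCNetwork(A=A, hspec=ZERO)
        eigs, stable = stability_eigenvalues(net, np.zeros(4))
        np.testing.assert_allclose(eigs, -1.0, atol=1e-12)
        assert stable

    def test_monotone_homeostasis_gives_stable_equilibria(self):
        rng = np.random.default_rng(15)
        hspec = HomeostasisSpec("power_prior", {"lam": 0.2, "alpha": 1.5})
        for _ in range(10):
            net = random_net(rng, hspec=hspec)
            eq = solve_equilibrium(net, rng.standard_normal(8), tol=1e-9)
            assert eq.stable


class TestAnalyticCurve:
    def test_zero_homeostasis_identity(self):
        xs = np.linspace(0, 5, 11)
        curve = analytic_response_curve(ZERO, xs)
        np.testing.assert_allclose(curve[:, 1], xs, atol=1e-10)

    def test_dn_equivalent_matches_naka_rushton(self):
        xs = np.linspace(0, 20, 41)
        curve = analytic_response_curve(homeostasis_from_dn(DN322), xs)
        np.testing.assert_allclose(curve[:, 1], naka_rushton(xs, DN322), atol=1e-8)

    def test_concave_convex_monotone_bounded(self, reference_cc_spec):
        curve = analytic_response_curve(reference_cc_spec, np.linspace(0, 20, 81))
        s = curve[:, 1]
        assert np.all(np.diff(s) >= -1e-12)
        assert s[-1] < 2.0  # saturates well below the input range


class TestEnergyDescent:
    def test_sparse_coding_cost_nonincreasing(self):
        """For a power-law prior the iteration descends the sparse-coding energy."""
        rng = np.random.default_rng(16)
        hspec = HomeostasisSpec("power_prior", {"lam": 0.3, "alpha": 1.5})
        net = random_net(rng, hspec=hspec)
        x = rng.standard_normal(8)
        res = iterate_responses(
            net,
            x,
            IterationConfig(eta_s=0.01, max_iter=2000, tol=0.0, record_trajectory=True),
        )
        costs = [sparse_coding_cost(net, x, s) for s in res.trajectory]
        assert np.all(np.diff(costs) <= 1e-10)

    def test_cost_requires_power_prior(self):
        net = SPCNetwork(A=np.array([[1.0]]), hspec=ZERO)
        with pytest.raises(ValueError):
            sparse_coding_cost(net, np.array([1.0]), np.array([0.5]))
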