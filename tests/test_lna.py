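import numpy as np
import pytest
import sympy as sp

from rxnscale import parse_model
from rxnscale.master_equation import derive_master_equation
from rxnscale.meanfield import derive_odes, find_fixed_points
from rxnscale.lna import (
    moment_equations,
    noise_correlation,
    stationary_covariance,
    van_kampen_expand,
)

k, h, d = sp.symbols("k h d")
Phi_A, Phi_X = sp.symbols("Phi_A Phi_X")


@pytest.fixture(scope="module")
def toy_lnr(toy_model):
    return van_kampen_expand(derive_master_equation(toy_model))


@pytest.fixture(scope="module")
def bee_lnr(honeybee_reduced):
    return van_kampen_expand(derive_master_equation(honeybee_reduced))


class TestExpansion:
    def test_toy_fpe_matches_worked_example(self, toy_lnr):
        """The order-V^0 collection equals the textbook linear FPE:
        (Phi_A k/2 + 2 Phi_X^2 h) d2P/deta2 + 4 Phi_X eta h dP/deta + 4 Phi_X h P."""
        eta = sp.Symbol("eta_X")
        P = toy_lnr.distribution
        expected = (
            Phi_A * k / 2 * sp.Derivative(P, (eta, 2))
            + 2 * Phi_X**2 * h * sp.Derivative(P, (eta, 2))
            + 4 * Phi_X * eta * h * sp.Derivative(P, eta)
            + 4 * Phi_X * h * P
        )
        assert sp.simplify(toy_lnr.fpe - expected) == 0

    def test_toy_drift_and_diffusion_matrices(self, toy_lnr):
        assert sp.simplify(toy_lnr.drift_matrix[0, 0] + 4 * h * Phi_X) == 0
        assert sp.simplify(toy_lnr.diffusion_matrix[0, 0] - (k * Phi_A + 4 * h * Phi_X**2)) == 0

    def test_pure_decay_by_hand(self):
        lnr = van_kampen_expand(derive_master_equation(parse_model("X -> EMPTY : d")))
        Phi = sp.Symbol("Phi_X")
        assert sp.simplify(lnr.macroscopic_odes.drift[0] + d * Phi) == 0
        assert sp.simplify(lnr.drift_matrix[0, 0] + d) == 0
        assert sp.simplify(lnr.diffusion_matrix[0, 0] - d * Phi) == 0

    @pytest.mark.parametrize("fixture_name", ["toy_lnr", "bee_lnr"])
    def test_drift_matrix_is_macroscopic_jacobian(self, fixture_name, request):
        lnr = request.getfixturevalue(fixture_name)
        jac = lnr.macroscopic_odes.jacobian
        for i in range(lnr.dim):
            for j in range(lnr.dim):
                assert sp.simplify(lnr.drift_matrix[i, j] - jac[i, j]) == 0

    def test_macroscopic_equals_mass_action(self, honeybee_reduced, bee_lnr):
        """The order-sqrt(V) collection reproduces the mass-action
        concentration ODEs (with the conserved total at its closed-population
        value N = 1)."""
        odes = derive_odes(honeybee_reduced, "concentrations")
        N = sp.Symbol("N")
        for expanded, direct in zip(bee_lnr.macroscopic_odes.drift, odes.drift):
            assert sp.simplify(expanded - direct.subs(N, 1)) == 0

    def test_diffusion_symmetric_psd_at_positive_state(self, bee_lnr):
        subs = {sp.Symbol("mu"): 3.0, sp.Symbol("Delta"): 0.1, sp.Symbol("s"): 4.0,
                sp.Symbol("Phi_A"): 0.3, sp.Symbol("Phi_B"): 0.25}
        B = np.array(bee_lnr.diffusion_matrix.subs(subs).evalf(), dtype=float)
        assert np.allclose(B, B.T)
        assert np.all(np.linalg.eigvalsh(B) >= -1e-12)


class TestMoments:
    def test_toy_moment_odes(self, toy_lnr):
        """d<eta>/dt = -4 h Phi <eta>; d<eta^2>/dt = -8 h Phi <eta^2> + B."""
        ms = moment_equations(toy_lnr)
        m1 = ms.first_symbols[0]
        m2 = ms.second_symbols[(0, 0)]
        assert sp.simplify(ms.first_rhs[0] + 4 * h * Phi_X * m1) == 0
        assert sp.simplify(
            ms.second_rhs[(0, 0)] - (-8 * h * Phi_X * m2 + k * Phi_A + 4 * h * Phi_X**2)
        ) == 0

    def test_moment_odes_have_lyapunov_form(self, bee_lnr):
        """d<eta>/dt = A <eta>; d<eta eta^T>/dt = A M + M A^T + B, checked
        symbolically against the matrices extracted from the FPE."""
        ms = moment_equations(bee_lnr)
        n = bee_lnr.dim
        m1 = sp.Matrix(ms.first_symbols)
        assert sp.simplify(sp.Matrix(ms.first_rhs) - bee_lnr.drift_matrix * m1) == sp.zeros(n, 1)
        M = sp.Matrix(n, n, lambda i, j: ms.second_symbols[(min(i, j), max(i, j))])
        expected = bee_lnr.drift_matrix * M + M * bee_lnr.drift_matrix.T + bee_lnr.diffusion_matrix
        for i in range(n):
            for j in range(i, n):
                assert sp.simplify(ms.second_rhs[(i, j)] - expected[i, j]) == 0

    def test_honeybee_moment_count(self, bee_lnr):
        ms = moment_equations(bee_lnr)
        assert len(ms.first_rhs) == 2
        assert len(ms.second_rhs) == 3  # (AA), (AB)=(BA), (BB)

    def test_no_reactions_all_zero(self):
        lnr = van_kampen_expand(derive_master_equation(parse_model("X -> X : r")))
        ms = moment_equations(lnr)
        assert all(rhs == 0 for rhs in ms.first_rhs)
        assert all(rhs == 0 for rhs in ms.second_rhs.values())


class TestStationaryNoise:
    def test_toy_scalar_lyapunov(self, toy_lnr):
        """C = B/(2|A|) = 3/(8 Phi*) = 0.53033 at k = h = Phi_A = 1."""
        params = {"k": 1.0, "h": 1.0, "Phi_A": 1.0}
        fp = find_fixed_points(toy_lnr.macroscopic_odes, params, [(0.0, 2.0)])[0]
        assert fp.location[0] == pytest.approx(0.70711, abs=1e-5)
        cov = stationary_covariance(toy_lnr, fp, params)
        assert cov.covariance[0, 0] == pytest.approx(0.53033, abs=1e-5)
        assert cov.lyapunov_residual <= 1e-8

    def test_birth_death_poisson(self, birth_death):
        """Immigration-death: A = -d, B = 2b at Phi* = b/d, so C = b/d
        (Poisson: variance equals mean)."""
        lnr = van_kampen_expand(derive_master_equation(birth_death))
        params = {"b": 1.4, "d": 0.7}
        fp = find_fixed_points(lnr.macroscopic_odes, params, [(0.0, 5.0)])[0]
        cov = stationary_covariance(lnr, fp, params)
        assert cov.covariance[0, 0] == pytest.approx(2.0, abs=1e-10)

    def test_unstable_fixed_point_rejected(self, toy_lnr):
        from rxnscale.meanfield import FixedPoint

        fake = FixedPoint(location=(0.5,), eigenvalues=(1.0,), classification="unstable")
        with pytest.raises(ValueError, match="stable"):
            stationary_covariance(toy_lnr, fake, {"k": 1.0, "h": 1.0, "Phi_A": 1.0})

    def test_honeybee_lyapunov_residual_and_ellipse(self, bee_lnr):
        params = {"mu": 3.0, "Delta": 0.0, "s": 10.0}
        fps = find_fixed_points(
            bee_lnr.macroscopic_odes, params, [(0.0, 1.0), (0.0, 1.0)],
            constraint=lambda z: z.sum() <= 1 + 1e-9,
        )
        stable = [f for f in fps if f.is_stable]
        assert len(stable) == 2
        cov = stationary_covariance(bee_lnr, stable[0], params)
        assert cov.lyapunov_residual <= 1e-8
        # principal axes orthonormal
        Q = cov.ellipse_axes
        assert np.allclose(Q.T @ Q, np.eye(2), atol=1e-12)
        # anisotropic, non-axis-parallel noise at the committed attractor
        assert cov.ellipse_lengths[0] / cov.ellipse_lengths[1] > 1.2
        assert np.min(np.abs(Q)) > 1e-3


class TestCorrelation:
    def test_zero_lag_returns_covariance(self, toy_lnr):
        params = {"k": 1.0, "h": 1.0, "Phi_A": 1.0}
        fp = find_fixed_points(toy_lnr.macroscopic_odes, params, [(0.0, 2.0)])[0]
        cov = stationary_covariance(toy_lnr, fp, params)
        out = noise_correlation(toy_lnr, fp, cov, [0.0], params)
        assert np.allclose(out[0], cov.covariance)

    def test_scalar_ou_closed_form(self, toy_lnr):
        """<eta(t+tau) eta(t)> = C exp(A tau) with A = -4 h Phi* = -2 sqrt(2):
        at tau = 0.5 this is 0.53033 * exp(-1.41421) = 0.12893."""
        params = {"k": 1.0, "h": 1.0, "Phi_A": 1.0}
        fp = find_fixed_points(toy_lnr.macroscopic_odes, params, [(0.0, 2.0)])[0]
        cov = stationary_covariance(toy_lnr, fp, params)
        out = noise_correlation(toy_lnr, fp, cov, [0.5], params)
        assert out[0][0, 0] == pytest.approx(0.53033 * np.exp(-np.sqrt(2)), abs=1e-4)
        assert out[0][0, 0] == pytest.approx(0.12893, abs=1e-4)

    def test_scalar_correlation_decreases_with_lag(self, toy_lnr):
        params = {"k": 1.0, "h": 2.0, "Phi_A": 1.5}
        fp = find_fixed_points(toy_lnr.macroscopic_odes, params, [(0.0, 2.0)])[0]
        cov = stationary_covariance(toy_lnr, fp, params)
        lags = [0.0, 0.2, 0.5, 1.0, 2.0]
        vals = [m[0, 0] for m in noise_correlation(toy_lnr, fp, cov, lags, params)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_lag_rejected(self, toy_lnr):
        params = {"k": 1.0, "h": 1.0, "Phi_A": 1.0}
        fp = find_fixed_points(toy_lnr.macroscopic_odes, params, [(0.0, 2.0)])[0]
        cov = stationary_covariance(toy_lnr, fp, params)
        with pytest.raises(ValueError, match="non-negative"):
            noise_correlation(toy_lnr, fp, cov, [-0.1], params)
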