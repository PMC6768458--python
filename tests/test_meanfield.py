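import numpy as np
import pytest
import sympy as sp

from rxnscale import load_fixture, parse_model
from rxnscale.meanfield import (
    ODESystem,
    derive_odes,
    find_fixed_points,
    integrate_odes,
    sample_field,
    stream_field,
)

x, mu = sp.symbols("x mu")


class TestDeriveODEs:
    def test_toy_concentration_form(self, toy_model):
        odes = derive_odes(toy_model, "concentrations")
        k, h, PhiA, PhiX = sp.symbols("k h Phi_A Phi_X")
        assert sp.simplify(odes.drift[0] - (k * PhiA - 2 * h * PhiX**2)) == 0

    def test_no_reactions_gives_zero_drift(self):
        m = parse_model("X -> X : r")
        odes = derive_odes(m, "counts")
        assert odes.drift == (sp.Integer(0),)

    def test_jacobian_is_symbolic_derivative(self, honeybee_reduced):
        odes = derive_odes(honeybee_reduced, "counts")
        jac = odes.jacobian
        for i, f in enumerate(odes.drift):
            for j, v in enumerate(odes.variables):
                assert sp.simplify(jac[i, j] - sp.diff(f, v)) == 0

    def test_jacobian_matches_finite_differences(self, honeybee_reduced):
        odes = derive_odes(honeybee_reduced, "concentrations")
        params = {"mu": 3.0, "Delta": 0.2, "s": 5.0, "N": 1.0}
        rhs = odes.rhs_function(params)
        jac = odes.jacobian_function(params)
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(0.05, 0.45, size=2)
            J = jac(y)
            eps = 1e-7
            for j in range(2):
                dy = np.zeros(2)
                dy[j] = eps
                col = (rhs(0, y + dy) - rhs(0, y - dy)) / (2 * eps)
                assert np.allclose(col, J[:, j], rtol=1e-5, atol=1e-8)


class TestIntegration:
    def test_exponential_decay_closed_form(self):
        odes = ODESystem((x,), (-x,), "counts")
        traj = integrate_odes(odes, [1.0], {}, 1.0, 101)
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_unbound_parameter_errors(self):
        odes = ODESystem((x,), (-mu * x,), "counts")
        with pytest.raises(ValueError, match="unbound"):
            integrate_odes(odes, [1.0], {}, 1.0)

    def test_brusselator_stable_regime_converges(self, brusselator):
        model, params = brusselator
        odes = derive_odes(model, "concentrations")
        traj = integrate_odes(odes, [1.0, 1.0], params["fig3_left"], 50.0, 500)
        tail = traj.states[int(0.9 * len(traj.times)):]
        assert np.max(np.abs(tail - tail[-1])) < 1e-3

    def test_brusselator_oscillatory_regime_sustains(self, brusselator):
        model, params = brusselator
        odes = derive_odes(model, "concentrations")
        traj = integrate_odes(odes, [1.0, 1.0], params["fig3_right"], 60.0, 3000)
        half = traj.states[len(traj.times) // 2:, 0]
        peaks = [
            half[i]
            for i in range(1, len(half) - 1)
            if half[i] > half[i - 1] and half[i] > half[i + 1] and half[i] > half.mean()
        ]
        assert len(peaks) >= 3
        assert np.std(peaks) / np.mean(peaks) < 0.05  # comparable amplitudes

    def test_closed_population_is_conserved(self, honeybee):
        odes = derive_odes(honeybee, "concentrations")
        traj = integrate_odes(
            odes, [0.6, 0.3, 0.1], {"mu": 3.0, "Delta": 0.1, "s": 4.0}, 20.0
        )
        totals = traj.states.sum(axis=1)
        assert np.max(np.abs(totals - 1.0)) < 1e-6

    def test_proportions_output(self, honeybee):
        odes = derive_odes(honeybee, "counts")
        traj = integrate_odes(
            odes, [40.0, 5.0, 5.0], {"mu": 3.0, "Delta": 0.0, "s": 4.0}, 1.0,
            proportions=True,
        )
        assert traj.units == "proportions"
        assert traj.states[0].sum() == pytest.approx(1.0)


class TestFixedPoints:
    def test_logistic_roots_and_stability(self):
        odes = ODESystem((x,), (x * (1 - x),), "counts")
        fps = find_fixed_points(odes, {}, [(-0.5, 1.5)])
        locs = {round(f.location[0], 6): f.classification for f in fps}
        assert locs == {0.0: "unstable", 1.0: "stable"}

    def test_polynomial_roots_match_companion_oracle(self):
        # independent oracle: roots of the polynomial via numpy's companion matrix
        roots = [-1.1, 0.2, 0.7]
        poly = sp.expand(sp.prod([x - r for r in roots]))
        odes = ODESystem((x,), (poly,), "counts")
        fps = find_fixed_points(odes, {}, [(-2.0, 2.0)])
        oracle = np.sort(np.roots(np.array([1.0, *np.poly(roots)[1:]])))
        found = np.sort([f.location[0] for f in fps])
        assert np.allclose(found, oracle, atol=1e-6)

    def test_numeric_fallback_agrees_with_symbolic(self):
        odes = ODESystem((x,), (x * (1 - x) * (x - 0.4),), "counts")
        sym = find_fixed_points(odes, {}, [(-0.5, 1.5)], symbolic=True)
        num = find_fixed_points(odes, {}, [(-0.5, 1.5)], symbolic=False)
        assert np.allclose(
            sorted(f.location[0] for f in sym), sorted(f.location[0] for f in num), atol=1e-8
        )

    def test_brusselator_single_stable_attractor(self, brusselator):
        model, params = brusselator
        odes = derive_odes(model, "concentrations")
        fps = find_fixed_points(odes, params["fig3_left"], [(0.0, 8.0), (0.0, 8.0)])
        assert len(fps) == 1
        assert fps[0].classification == "stable"
        assert fps[0].location == pytest.approx((2.0, 1.0), abs=1e-8)

    def test_honeybee_bistability_with_saddle(self, honeybee_reduced):
        odes = derive_odes(honeybee_reduced, "counts")
        params = {"Delta": 0.0, "mu": 3.0, "s": 10.0, "N": 20.0}
        fps = find_fixed_points(
            odes, params, [(0.0, 20.0), (0.0, 20.0)],
            constraint=lambda z: z.sum() <= 20.0 + 1e-9,
        )
        kinds = sorted(f.classification for f in fps)
        assert kinds == ["saddle", "stable", "stable"]


class TestFields:
    def test_lotka_volterra_drift_at_unit_state(self):
        model, params = load_fixture("lotka_volterra")
        odes = derive_odes(model, "concentrations")
        fs = sample_field(odes, params["fig4_upper_left"], [(1.0, 1.0), (1.0, 1.0)], n=1)
        assert np.allclose(fs.vectors[0], [2.0, 0.0])

    def test_grid_shape_and_finiteness(self, honeybee_reduced):
        odes = derive_odes(honeybee_reduced, "concentrations")
        fs = sample_field(
            odes, {"mu": 3.0, "Delta": 0.0, "s": 4.0, "N": 1.0},
            [(0.0, 1.0), (0.0, 1.0)], n=10,
        )
        assert fs.points.shape == (100, 2)
        assert np.all(np.isfinite(fs.vectors)) and np.all(np.isfinite(fs.speed))

    def test_stream_field_drift_vanishes_at_fixed_points(self, honeybee_reduced):
        odes = derive_odes(honeybee_reduced, "concentrations")
        params = {"mu": 3.0, "Delta": 0.0, "s": 6.0, "N": 1.0}
        fs = stream_field(odes, params, [(0.0, 1.0), (0.0, 1.0)], n=5)
        rhs = odes.rhs_function(params)
        assert fs.fixed_points
        for fp in fs.fixed_points:
            assert np.max(np.abs(rhs(0.0, np.array(fp.location)))) <= 1e-9

    def test_high_dimension_advises_reduction(self, honeybee):
        odes = derive_odes(honeybee, "concentrations")
        with pytest.raises(ValueError, match="substitute"):
            sample_field(odes, {}, [(0, 1)] * 3)
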