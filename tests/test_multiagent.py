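import numpy as np
import pytest

from rxnscale import parse_model
from rxnscale.multiagent import (
    build_topology,
    choose_timestep,
    compile_state_machine,
    multiagent_ensemble,
    multiagent_trajectory,
)


class TestTopologies:
    def test_complete_graph_all_pairs(self):
        topo = build_topology("complete", 5, seed=0)
        assert topo.kind == "complete" and topo.n == 5

    def test_geometric_large_radius_is_complete(self):
        # max distance in the unit square is sqrt(2) < 1.5
        topo = build_topology("geometric_static", 12, {"radius": 1.5}, seed=1)
        assert all(len(nbrs) == 11 for nbrs in topo.neighbors)

    def test_erdos_renyi_degenerate_probabilities(self):
        empty = build_topology("erdos_renyi", 8, {"p": 0.0}, seed=2)
        assert all(len(nbrs) == 0 for nbrs in empty.neighbors)
        full = build_topology("erdos_renyi", 8, {"p": 1.0}, seed=2)
        assert all(len(nbrs) == 7 for nbrs in full.neighbors)

    def test_barabasi_albert_connected(self):
        topo = build_topology("barabasi_albert", 30, {"m": 2}, seed=3)
        assert all(len(nbrs) >= 2 for nbrs in topo.neighbors)

    @pytest.mark.parametrize(
        "kind,params",
        [("erdos_renyi", {"p": 1.5}), ("geometric_static", {"radius": 0.0}),
         ("barabasi_albert", {"m": 0})],
    )
    def test_invalid_parameters(self, kind, params):
        with pytest.raises(ValueError):
            build_topology(kind, 10, params, seed=0)

    def test_same_seed_same_graph(self):
        a = build_topology("erdos_renyi", 20, {"p": 0.3}, seed=9)
        b = build_topology("erdos_renyi", 20, {"p": 0.3}, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.neighbors, b.neighbors))
        assert np.array_equal(
            build_topology("geometric_static", 10, {"radius": 0.2}, seed=4).positions,
            build_topology("geometric_static", 10, {"radius": 0.2}, seed=4).positions,
        )


class TestCompilation:
    def test_honeybee_four_plus_four(self, honeybee):
        machine = compile_state_machine(honeybee)
        assert machine.states == ("U", "A", "B")
        assert len(machine.spontaneous) == 4
        assert len(machine.interactive) == 4

    def test_inert_rule_compiles_to_inert_transition(self):
        machine = compile_state_machine(parse_model("X -> X : r"))
        assert machine.spontaneous == (("X", "X", machine.spontaneous[0][2]),)

    def test_agent_count_changing_model_rejected(self, toy_model):
        with pytest.raises(ValueError):
            compile_state_machine(toy_model)

    def test_three_body_rule_rejected(self):
        m = parse_model("X + X + Y -> X + X + X : c")
        with pytest.raises(ValueError, match="more than two"):
            compile_state_machine(m)


class TestTimestep:
    def test_single_rule_example(self):
        machine = compile_state_machine(parse_model("X -> Y : r"))
        assert choose_timestep(machine, {"r": 2.0}, safety=1.0) == pytest.approx(0.5)

    def test_doubling_rates_halves_dt(self, honeybee):
        machine = compile_state_machine(honeybee)
        p1 = {"mu": 3.0, "Delta": 0.0, "s": 3.0}
        p2 = {"mu": 6.0, "Delta": 0.0, "s": 6.0}
        assert choose_timestep(machine, p1) == pytest.approx(2 * choose_timestep(machine, p2))

    def test_zero_rates_error(self):
        machine = compile_state_machine(parse_model("X -> Y : r"))
        with pytest.raises(ValueError, match="zero"):
            choose_timestep(machine, {"r": 0.0})


class TestSimulation:
    def test_counts_conserved_every_step(self, honeybee):
        machine = compile_state_machine(honeybee)
        topo = build_topology("erdos_renyi", 40, {"p": 0.2}, seed=5)
        traj = multiagent_trajectory(
            machine, topo, ["U"] * 40, {"mu": 3.0, "Delta": 0.5, "s": 2.0}, 5.0, seed=6
        )
        assert np.all(traj.counts.sum(axis=1) == 40)

    def test_no_matching_transitions_keeps_counts(self):
        machine = compile_state_machine(parse_model("X -> X : r"))
        topo = build_topology("complete", 10, seed=0)
        traj = multiagent_trajectory(machine, topo, ["X"] * 10, {"r": 1.0}, 2.0, seed=1)
        assert np.all(traj.counts[:, 0] == 10)

    def test_same_seed_same_trajectory(self, honeybee):
        machine = compile_state_machine(honeybee)
        topo = build_topology("geometric_static", 30, {"radius": 0.3}, seed=12)
        p = {"mu": 3.0, "Delta": 0.0, "s": 3.0}
        a = multiagent_trajectory(machine, topo, ["U"] * 30, p, 3.0, seed=13)
        b = multiagent_trajectory(machine, topo, ["U"] * 30, p, 3.0, seed=13)
        assert np.array_equal(a.counts, b.counts)

    def test_geometric_dynamic_positions_move_and_wrap(self, honeybee):
        machine = compile_state_machine(honeybee)
        topo = build_topology(
            "geometric_dynamic", 20, {"radius": 0.2, "speed": 0.05}, seed=20
        )
        traj = multiagent_trajectory(
            machine, topo, ["U"] * 20, {"mu": 3.0, "Delta": 0.0, "s": 3.0}, 2.0,
            seed=21, record_agents=True,
        )
        assert traj.positions is not None
        assert np.all(traj.positions >= 0.0) and np.all(traj.positions <= 1.0)
        assert not np.allclose(traj.positions[0], traj.positions[-1])

    def test_two_state_relaxation_matches_mean_field(self):
        """X <-> Y on a complete graph relaxes to the n_Y/n = r1/(r1+r2)
        mean-field equilibrium."""
        machine = compile_state_machine(parse_model("X -> Y : r_1\nY -> X : r_2"))
        finals, mean_counts, times = multiagent_ensemble(
            machine, build_topology("complete", 200), ["X"] * 200,
            {"r_1": 1.0, "r_2": 2.0}, 10.0, runs=20, seed=30,
        )
        frac_Y = finals[:, 1].mean() / 200
        assert frac_Y == pytest.approx(1.0 / 3.0, abs=0.03)

    def test_complete_graph_matches_ssa_final_mean(self, honeybee):
        """Agent simulation on the complete graph and the exact SSA agree in
        final-state mean (matched time scale, V = n = 50)."""
        from rxnscale.ssa import ssa_ensemble

        machine = compile_state_machine(honeybee)
        p = {"mu": 3.0, "Delta": 0.0, "s": 3.0}
        runs = 100
        finals, _, _ = multiagent_ensemble(
            machine, build_topology("complete", 50), ["U"] * 50, p, 10.0, runs=runs, seed=31
        )
        res = ssa_ensemble(honeybee, [50, 0, 0], p, 50.0, t_max=10.0, runs=runs, seed=32)
        se = np.sqrt(
            finals.var(axis=0, ddof=1) / runs + res.final_states.var(axis=0, ddof=1) / runs
        )
        diff = np.abs(finals.mean(axis=0) - res.mean)
        assert np.all(diff <= 3 * se + 1e-9)
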