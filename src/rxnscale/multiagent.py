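"""Network-embedded finite-population simulation.

Reaction rules are compiled into a per-agent probabilistic finite state
machine: unimolecular rules become spontaneous state transitions and
bimolecular rules become pairwise interactive transitions between an
initiating agent and one uniformly chosen neighbour on the interaction
topology.  Agents update at synchronous discrete timesteps, realised as a
randomised sequential sweep so that no agent takes part in two events in
one step.

The timestep is sized automatically to match the population-level clock:
``dt = safety / R_max`` where ``R_max`` is the largest total outgoing rate
of any state assuming worst-case partner availability, so every per-step
transition probability ``rate * dt`` is at most ``safety``.  With this
calibration agent counts are directly comparable to SSA trajectories and to
the concentration-form ODEs (scaled by the agent count) at the same times.

Pair sampling matches the master-equation propensities on a complete graph:
a rule between two *distinct* states can be initiated from either side, so
each directed form fires with probability ``rate*dt/2``; a same-state rule
has a single form firing with ``rate*dt`` (either member of a pair may
initiate, and the falling-factorial propensity ``rate*n*(n-1)/V`` counts
ordered pairs).

Topologies: complete graph, Erdős–Rényi, Barabási–Albert, and random
geometric graphs on the unit square — static, or dynamic with agents
performing a correlated random walk (wrapped-normal heading noise, fixed
speed, periodic boundary) and the graph rebuilt from pair distances every
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp

from .meanfield import _param_subs
from .model_dsl import ReactionModel

__all__ = [
    "InteractionTopology",
    "AgentStateMachine",
    "AgentTrajectory",
    "build_topology",
    "compile_state_machine",
    "choose_timestep",
    "multiagent_trajectory",
    "multiagent_ensemble",
]

TOPOLOGY_KINDS = ("complete", "erdos_renyi", "barabasi_albert", "geometric_static", "geometric_dynamic")


@dataclass(frozen=True)
class InteractionTopology:
    kind: str
    n: int
    kind_params: dict = field(default_factory=dict)
    positions: np.ndarray | None = None  # (n, 2) in the unit square
    neighbors: tuple | None = None  # tuple of index arrays; None for complete
    seed: object = None


@dataclass(frozen=True)
class AgentStateMachine:
    states: tuple[str, ...]
    #: (from_state, to_state, rate expression)
    spontaneous: tuple[tuple[str, str, sp.Expr], ...]
    #: (own_state, partner_state, own_next, partner_next, rate expression)
    interactive: tuple[tuple[str, str, str, str, sp.Expr], ...]


@dataclass(frozen=True)
class AgentTrajectory:
    times: np.ndarray
    counts: np.ndarray  # (steps + 1, n_states)
    states: tuple[str, ...]
    dt: float
    agent_states: np.ndarray | None = None  # (steps + 1, n) state indices
    positions: np.ndarray | None = None  # (steps + 1, n, 2) for geometric kinds
    seed: object = None


def build_topology(kind: str, n: int, kind_params: dict | None = None, seed=None) -> InteractionTopology:
    """Construct a reproducible interaction graph.

    ``kind_params``: ``p`` (edge probability) for ``erdos_renyi``, ``m``
    (attachment count) for ``barabasi_albert``, ``radius`` (interaction
    distance) plus optionally ``speed`` and ``turning_noise`` for the
    geometric kinds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"unknown topology kind {kind!r}; choose from {TOPOLOGY_KINDS}")
    kind_params = dict(kind_params or {})
    rng = np.random.Generator(np.random.PCG64(seed))
    positions = None
    neighbors: tuple | None = None

    if kind == "complete":
        neighbors = None
    elif kind == "erdos_renyi":
        import networkx as nx

        p = float(kind_params.get("p", 0.1))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"edge probability must be in [0, 1], got {p}")
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        neighbors = tuple(np.array(sorted(g.neighbors(i)), dtype=np.int64) for i in range(n))
    elif kind == "barabasi_albert":
        import networkx as nx

        m = int(kind_params.get("m", 2))
        if not 1 <= m < n:
            raise ValueError(f"attachment count must satisfy 1 <= m < n, got {m}")
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        neighbors = tuple(np.array(sorted(g.neighbors(i)), dtype=np.int64) for i in range(n))
    else:  # geometric kinds
        radius = float(kind_params.get("radius", 0.1))
        if radius <= 0:
            raise ValueError(f"interaction radius must be positive, got {radius}")
        kind_params.setdefault("speed", 0.01)
        kind_params.setdefault("turning_noise", 0.3)
        positions = rng.random((n, 2))
        neighbors = _geometric_neighbors(positions, radius)
    return InteractionTopology(
        kind=kind, n=n, kind_params=kind_params, positions=positions, neighbors=neighbors, seed=seed
    )


def _geometric_neighbors(positions: np.ndarray, radius: float) -> tuple:
    from scipy.spatial import cKDTree

    tree = cKDTree(positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(positions)
    lists: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        lists[a].append(b)
        lists[b].append(a)
    return tuple(np.array(sorted(l), dtype=np.int64) for l in lists)


def compile_state_machine(model: ReactionModel) -> AgentStateMachine:
    """Compile rules into per-agent transitions.

    Every reaction must be agent-interpretable: at most two dynamic reactant
    molecules, the same number of dynamic product molecules (agents are
    conserved), and no reservoir species.
    """
    states = tuple(s.name for s in model.dynamic_species)
    spontaneous = []
    interactive = []
    for r in model.reactions:
        if any(s.is_constant for s, _ in r.reactants + r.products):
            raise ValueError(f"rule {r} involves a reservoir species; not agent-interpretable")
        lhs = [s.name for s, c in r.reactants for _ in range(c)]
        rhs = [s.name for s, c in r.products for _ in range(c)]
        if len(lhs) != len(rhs):
            raise ValueError(f"rule {r} changes the agent count; not agent-interpretable")
        if len(lhs) == 0:
            raise ValueError(f"rule {r} has no reactants; not agent-interpretable")
        if len(lhs) == 1:
            spontaneous.append((lhs[0], rhs[0], r.rate))
        elif len(lhs) == 2:
            interactive.append((lhs[0], lhs[1], rhs[0], rhs[1], r.rate))
        else:
            raise ValueError(f"rule {r} involves more than two agents; not agent-interpretable")
    return AgentStateMachine(states=states, spontaneous=tuple(spontaneous), interactive=tuple(interactive))


def _rates(machine: AgentStateMachine, params: dict) -> tuple[list, list]:
    subs = _param_subs(params)
    spont = []
    for frm, to, rate in machine.spontaneous:
        val = sp.sympify(rate).subs(subs)
        if val.free_symbols:
            raise ValueError(f"unbound parameters in rate {rate}")
        spont.append((frm, to, float(val)))
    inter = []
    for own, partner, own2, partner2, rate in machine.interactive:
        val = sp.sympify(rate).subs(subs)
        if val.free_symbols:
            raise ValueError(f"unbound parameters in rate {rate}")
        inter.append((own, partner, own2, partner2, float(val)))
    return spont, inter


def _directed_entries(inter: list) -> list:
    """Per-initiator forms: distinct-state rules from either side at rate/2,
    same-state rules one form at full rate (ordered-pair propensity)."""
    out = []
    for own, partner, own2, partner2, rate in inter:
        if own == partner:
            out.append((own, partner, own2, partner2, rate))
        else:
            out.append((own, partner, own2, partner2, rate / 2.0))
            out.append((partner, own, partner2, own2, rate / 2.0))
    return out


def choose_timestep(machine: AgentStateMachine, params: dict, safety: float = 0.5) -> float:
    """dt = safety / R_max over states (worst-case partner availability)."""
    if not 0 < safety <= 1:
        raise ValueError("safety must lie in (0, 1]")
    spont, inter = _rates(machine, params)
    directed = _directed_entries(inter)
    r_max = 0.0
    for state in machine.states:
        total = sum(rate for frm, _, rate in spont if frm == state)
        total += sum(rate for own, *_ , rate in [(e[0], e[4]) for e in directed] if own == state)
        r_max = max(r_max, total)
    if r_max <= 0:
        raise ValueError("all transition rates are zero; timestep undefined")
    return safety / r_max


def multiagent_trajectory(
    machine: AgentStateMachine,
    topology: InteractionTopology,
    init: Sequence,
    params: dict,
    t_max: float,
    seed,
    dt: float | None = None,
    safety: float = 0.5,
    record_agents: bool = False,
) -> AgentTrajectory:
    """Simulate the agent population on the given topology.

    ``init`` assigns each agent a state (names or state indices).  Each
    step, agents act in randomised order: an agent first attempts each of
    its spontaneous transitions (probability ``rate*dt``), otherwise picks
    one neighbour uniformly at random and, if the ordered state pair matches
    an interactive form, fires it with its per-initiation probability,
    updating both agents; an agent already involved in an event this step
    neither acts nor serves as a partner again.
    """
    n = topology.n
    state_index = {name: i for i, name in enumerate(machine.states)}
    agent_state = np.array(
        [state_index[s] if isinstance(s, str) else int(s) for s in init], dtype=np.int64
    )
    if agent_state.shape != (n,):
        raise ValueError(f"init must assign a state to each of the {n} agents")

    spont, inter = _rates(machine, params)
    if dt is None:
        dt = choose_timestep(machine, params, safety)
    n_states = len(machine.states)
    # per-state spontaneous transition table: cumulative probabilities + targets
    spont_cum: list[np.ndarray] = [np.empty(0)] * n_states
    spont_to: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * n_states
    for si, name in enumerate(machine.states):
        rows = [(rate * dt, state_index[to]) for frm, to, rate in spont if frm == name]
        spont_cum[si] = np.cumsum([p for p, _ in rows])
        spont_to[si] = np.array([t for _, t in rows], dtype=np.int64)
    # interactive lookup: (own, partner) -> list of (prob, own_next, partner_next)
    pair_table: dict[tuple[int, int], list[tuple[float, int, int]]] = {}
    for own, partner, own2, partner2, rate in _directed_entries(inter):
        key = (state_index[own], state_index[partner])
        pair_table.setdefault(key, []).append((rate * dt, state_index[own2], state_index[partner2]))
    spont_total = [spont_cum[si][-1] if len(spont_cum[si]) else 0.0 for si in range(n_states)]
    worst = max(
        (spont_total[si] + sum(p for p, _, _ in sum((pair_table.get((si, sj), []) for sj in range(n_states)), [])))
        for si in range(n_states)
    )
    if worst > safety + 1e-12:
        raise ValueError(f"per-step transition probability {worst:.3g} exceeds safety {safety}")

    rng = np.random.Generator(np.random.PCG64(seed))
    geometric_dynamic = topology.kind == "geometric_dynamic"
    positions = None if topology.positions is None else topology.positions.copy()
    neighbors = topology.neighbors
    heading = rng.random(n) * 2 * np.pi if geometric_dynamic else None
    speed = float(topology.kind_params.get("speed", 0.01)) if geometric_dynamic else 0.0
    sigma = float(topology.kind_params.get("turning_noise", 0.3)) if geometric_dynamic else 0.0
    radius = float(topology.kind_params.get("radius", 0.1)) if positions is not None else 0.0

    n_steps = int(math.ceil(t_max / dt))
    counts = np.zeros((n_steps + 1, n_states), dtype=np.int64)
    counts[0] = np.bincount(agent_state, minlength=n_states)
    rec_states = [agent_state.copy()] if record_agents else None
    rec_pos = [positions.copy()] if (record_agents and positions is not None) else None

    complete = topology.kind == "complete"
    for step in range(1, n_steps + 1):
        if geometric_dynamic:
            heading = heading + rng.normal(0.0, sigma, n)
            positions[:, 0] = (positions[:, 0] + speed * np.cos(heading)) % 1.0
            positions[:, 1] = (positions[:, 1] + speed * np.sin(heading)) % 1.0
            neighbors = _geometric_neighbors(positions, radius)
        order = rng.permutation(n)
        updated = np.zeros(n, dtype=bool)
        draws = rng.random(n)
        for a in order:
            if updated[a]:
                continue
            sa = agent_state[a]
            u = draws[a]
            cum = spont_cum[sa]
            if len(cum) and u < cum[-1]:
                k = int(np.searchsorted(cum, u, side="right"))
                agent_state[a] = spont_to[sa][k]
                updated[a] = True
                continue
            base = spont_total[sa]
            if complete:
                if n < 2:
                    continue
                b = int(rng.integers(n - 1))
                if b >= a:
                    b += 1
            else:
                nbrs = neighbors[a]
                if len(nbrs) == 0:
                    continue
                b = int(nbrs[rng.integers(len(nbrs))])
            if updated[b]:
                continue
            entries = pair_table.get((sa, agent_state[b]))
            if not entries:
                continue
            acc = base
            for prob, own_next, partner_next in entries:
                acc += prob
                if u < acc:
                    agent_state[a] = own_next
                    agent_state[b] = partner_next
                    updated[a] = updated[b] = True
                    break
        counts[step] = np.bincount(agent_state, minlength=n_states)
        if record_agents:
            rec_states.append(agent_state.copy())
            if rec_pos is not None:
                rec_pos.append(positions.copy())

    return AgentTrajectory(
        times=np.arange(n_steps + 1) * dt,
        counts=counts,
        states=machine.states,
        dt=dt,
        agent_states=np.array(rec_states) if record_agents else None,
        positions=np.array(rec_pos) if rec_pos is not None else None,
        seed=seed,
    )


def multiagent_ensemble(
    machine: AgentStateMachine,
    topology_factory,
    init: Sequence,
    params: dict,
    t_max: float,
    runs: int,
    seed,
    dt: float | None = None,
    safety: float = 0.5,
):
    """Repeat independent simulations; returns (final counts matrix,
    mean count trajectory, times).

    ``topology_factory`` is either a fixed :class:`InteractionTopology` or a
    callable ``seed -> InteractionTopology`` so each run can draw its own
    graph realisation.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    children = np.random.SeedSequence(seed).spawn(runs)
    finals = []
    mean_counts = None
    times = None
    for r in range(runs):
        topo_seed, run_seed = children[r].spawn(2)
        topo = topology_factory(topo_seed) if callable(topology_factory) else topology_factory
        traj = multiagent_trajectory(
            machine, topo, init, params, t_max, run_seed, dt=dt, safety=safety
        )
        finals.append(traj.counts[-1])
        if mean_counts is None:
            mean_counts = traj.counts.astype(float)
            times = traj.times
        else:
            mean_counts += traj.counts
    mean_counts /= runs
    return np.array(finals), mean_counts, times
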