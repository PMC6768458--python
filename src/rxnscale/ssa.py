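"""Exact stochastic simulation (Gillespie direct method).

Propensities follow the master-equation convention: for a reaction with
rate ``r`` and dynamic reactant multiplicities ``a_j``,

    propensity = r * V * prod_j ff(n_j, a_j) / V^a_j

with ``ff`` the falling factorial, so a unimolecular propensity is ``r*n``
and a bimolecular one ``r*n*(n-1)/V``.  Constant reservoir species
contribute their fixed concentration ``Phi^a`` and are never decremented;
an eliminated species contributes through its count expression.  Waiting
times are exponential with the total propensity and the firing reaction is
chosen proportionally to its propensity (the direct method), which samples
master-equation trajectories exactly.

Randomness: runs use numpy ``PCG64`` generators; ensembles draw
statistically independent per-run sub-seeds from a single ``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp

from .meanfield import _param_subs
from .model_dsl import ReactionModel

__all__ = [
    "StateTrajectory",
    "EnsembleResult",
    "compute_propensities",
    "ssa_trajectory",
    "ssa_ensemble",
    "resample_trajectory",
]


@dataclass(frozen=True)
class StateTrajectory:
    jump_times: np.ndarray  # event-resolved, starting at 0
    states: np.ndarray  # (events + 1, n_dynamic_species) integer counts
    species: tuple[str, ...]
    seed: object


@dataclass(frozen=True)
class EnsembleResult:
    runs: int
    final_states: np.ndarray  # (runs, n_species)
    mean: np.ndarray
    covariance: np.ndarray
    histograms: dict  # species name -> {count: frequency}
    grid_times: np.ndarray
    mean_trajectory: np.ndarray  # (grid, n_species) ensemble-averaged counts
    species: tuple[str, ...]
    seed: object


class _CompiledPropensities:
    """Per-reaction numeric propensity evaluators, independent of sympy at
    call time: plain falling-factorial arithmetic on integer counts."""

    def __init__(self, model: ReactionModel, params: dict, volume: float):
        self.model = model
        self.V = float(volume)
        dyn = model.dynamic_species
        self.species = tuple(s.name for s in dyn)
        index = {name: i for i, name in enumerate(self.species)}
        subs = _param_subs(params)

        elim = model.elimination_map("counts")
        self._elim_fns = []  # (callable(counts) -> count expr value) per eliminated species
        elim_index: dict[str, int] = {}
        for k, (s, _) in enumerate(model.eliminated):
            expr = elim[s.symbol].subs(subs)
            extra = expr.free_symbols - {sp.Symbol(n) for n in self.species}
            if extra:
                raise ValueError(
                    f"unbound symbols in elimination of {s.name!r}: {sorted(map(str, extra))}"
                )
            fn = sp.lambdify([sp.Symbol(n) for n in self.species], expr, modules="math")
            self._elim_fns.append(fn)
            elim_index[s.name] = k

        self._reactions = []
        self.stoich = np.zeros((len(dyn), len(model.reactions)), dtype=np.int64)
        for j, r in enumerate(model.reactions):
            rate = r.rate.subs(subs)
            if rate.free_symbols:
                raise ValueError(f"unbound parameters in rate {r.rate}: {sorted(map(str, rate.free_symbols))}")
            rate = float(rate)
            if rate <= 0:
                raise ValueError(f"rate of reaction {r} must be positive, got {rate}")
            base = rate * self.V
            dyn_terms = []  # (state index or ('elim', k), multiplicity)
            for s, a in r.reactants:
                if s.is_constant:
                    phi = sp.Symbol(f"Phi_{s.name}")
                    if phi not in subs:
                        raise ValueError(f"reservoir concentration Phi_{s.name} must be given in params")
                    base *= float(subs[phi]) ** a
                elif s.name in elim_index:
                    dyn_terms.append((("elim", elim_index[s.name]), a))
                    base /= self.V**a
                else:
                    dyn_terms.append((index[s.name], a))
                    base /= self.V**a
            for i, s in enumerate(dyn):
                self.stoich[i, j] = r.net_change(s.name)
            self._reactions.append((base, dyn_terms))

    def __call__(self, counts: np.ndarray) -> np.ndarray:
        out = np.empty(len(self._reactions))
        for j, (base, terms) in enumerate(self._reactions):
            p = base
            for ref, a in terms:
                n = self._elim_fns[ref[1]](*counts) if isinstance(ref, tuple) else counts[ref]
                for step in range(a):
                    p *= n - step
            out[j] = max(p, 0.0)
        return out


def compute_propensities(
    model: ReactionModel, state: Sequence[int], params: dict, volume: float
) -> np.ndarray:
    """Propensity vector at an integer state (one entry per reaction)."""
    compiled = _CompiledPropensities(model, params, volume)
    counts = np.asarray(state, dtype=np.int64)
    if counts.shape != (len(compiled.species),):
        raise ValueError(f"state must list counts for {compiled.species}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return compiled(counts)


def _simulate(
    compiled: _CompiledPropensities,
    init: np.ndarray,
    t_max: float,
    rng: np.random.Generator,
    record: bool,
):
    t = 0.0
    x = init.copy()
    times = [0.0]
    states = [x.copy()] if record else None
    stoich_cols = compiled.stoich.T.copy()
    while True:
        props = compiled(x)
        total = props.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        j = int(np.searchsorted(np.cumsum(props), rng.random() * total))
        j = min(j, len(props) - 1)
        x += stoich_cols[j]
        if record:
            times.append(t)
            states.append(x.copy())
    if record:
        return np.array(times), np.array(states, dtype=np.int64)
    return x


def ssa_trajectory(
    model: ReactionModel,
    init: Sequence[int],
    params: dict,
    volume: float,
    t_max: float,
    seed,
) -> StateTrajectory:
    """One event-resolved trajectory; reproducible given ``seed``."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    compiled = _CompiledPropensities(model, params, volume)
    x0 = np.asarray(init, dtype=np.int64)
    if np.any(x0 < 0):
        raise ValueError("initial counts must be non-negative")
    rng = np.random.Generator(np.random.PCG64(seed))
    times, states = _simulate(compiled, x0, t_max, rng, record=True)
    return StateTrajectory(jump_times=times, states=states, species=compiled.species, seed=seed)


def resample_trajectory(traj: StateTrajectory, grid: np.ndarray) -> np.ndarray:
    """Piecewise-constant (step function) values of a trajectory on a time grid."""
    idx = np.searchsorted(traj.jump_times, grid, side="right") - 1
    return traj.states[np.clip(idx, 0, len(traj.jump_times) - 1)]


def ssa_ensemble(
    model: ReactionModel,
    init: Sequence[int],
    params: dict,
    volume: float,
    t_max: float,
    runs: int,
    seed,
    grid_points: int = 200,
) -> EnsembleResult:
    """Independent repeated simulations with aggregate summaries.

    Returns the final-state distribution at ``t_max`` (per-run final states,
    their mean, sample covariance and per-species histograms) together with
    the ensemble-averaged count trajectory on a fixed time grid.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    compiled = _CompiledPropensities(model, params, volume)
    x0 = np.asarray(init, dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(runs)
    grid = np.linspace(0.0, t_max, grid_points)
    finals = np.empty((runs, len(compiled.species)), dtype=np.int64)
    mean_traj = np.zeros((grid_points, len(compiled.species)))
    for r in range(runs):
        rng = np.random.Generator(np.random.PCG64(children[r]))
        times, states = _simulate(compiled, x0, t_max, rng, record=True)
        traj = StateTrajectory(times, states, compiled.species, seed)
        finals[r] = states[-1]
        mean_traj += resample_trajectory(traj, grid)
    mean_traj /= runs
    mean = finals.mean(axis=0)
    if runs > 1:
        cov = np.cov(finals, rowvar=False, ddof=1).reshape(len(compiled.species), -1)
    else:
        cov = np.zeros((len(compiled.species), len(compiled.species)))
    hists = {
        name: dict(zip(*np.unique(finals[:, i], return_counts=True)))
        for i, name in enumerate(compiled.species)
    }
    return EnsembleResult(
        runs=runs,
        final_states=finals,
        mean=mean,
        covariance=cov,
        histograms=hists,
        grid_times=grid,
        mean_trajectory=mean_traj,
        species=compiled.species,
        seed=seed,
    )
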