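"""Mean-field (infinite population, well mixed) analysis.

Mass-action ODEs are derived directly from the rules: the drift of species X
is ``sum over reactions of (beta_X - alpha_X) * rate * prod(state^alpha)``.
Two representations are available:

* ``counts`` — state symbols are the raw species names and mass action is
  applied to them unscaled (bimolecular terms like ``A*B*s`` carry no system
  size factor).
* ``concentrations`` — state symbols are the proportions ``Phi_<name>``;
  this is the macroscopic limit of the finite-population descriptions and
  the representation in which ODE, stochastic and agent-based time scales
  coincide.

Constant reservoir species enter as their own symbol in count form and as
``Phi_<name>`` in concentration form; either way they act as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .model_dsl import ReactionModel

__all__ = [
    "ODESystem",
    "FixedPoint",
    "Trajectory",
    "derive_odes",
    "integrate_odes",
    "find_fixed_points",
    "sample_field",
    "stream_field",
]

_ROOT_TOL = 1e-9  # max-norm drift tolerance for accepting an equilibrium
_MERGE_TOL = 1e-6  # duplicate-merging distance
_STAB_EPS = 1e-9  # eigenvalue real-part threshold for stability calls


@dataclass(frozen=True)
class ODESystem:
    """Symbolic drift field of a reaction model."""

    variables: tuple[sp.Symbol, ...]
    drift: tuple[sp.Expr, ...]
    form: Literal["counts", "concentrations"]

    @property
    def jacobian(self) -> sp.Matrix:
        return sp.Matrix([[sp.diff(f, v) for v in self.variables] for f in self.drift])

    @property
    def parameters(self) -> frozenset[sp.Symbol]:
        free: set[sp.Symbol] = set()
        for f in self.drift:
            free |= f.free_symbols
        return frozenset(free - set(self.variables))

    @property
    def dim(self) -> int:
        return len(self.variables)

    def bind(self, params: dict) -> tuple[sp.Expr, ...]:
        """Substitute parameter values; error on any left unbound."""
        subs = _param_subs(params)
        bound = tuple(sp.sympify(f).subs(subs) for f in self.drift)
        leftover = set().union(*(f.free_symbols for f in bound)) - set(self.variables) if bound else set()
        if leftover:
            raise ValueError(f"unbound parameters: {sorted(map(str, leftover))}")
        return bound

    def rhs_function(self, params: dict) -> Callable[[float, np.ndarray], np.ndarray]:
        bound = self.bind(params)
        funcs = [sp.lambdify(self.variables, f, modules="numpy") for f in bound]
        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return np.array([f(*y) for f in funcs], dtype=float)
        return rhs

    def jacobian_function(self, params: dict) -> Callable[[np.ndarray], np.ndarray]:
        subs = _param_subs(params)
        jac = self.jacobian.subs(subs)
        fn = sp.lambdify(self.variables, jac, modules="numpy")
        return lambda y: np.asarray(fn(*y), dtype=float)


@dataclass(frozen=True)
class FixedPoint:
    location: tuple[float, ...]
    eigenvalues: tuple[complex, ...]
    classification: Literal["stable", "unstable", "saddle"]
    marginal: bool = False

    @property
    def is_stable(self) -> bool:
        return self.classification == "stable"


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_variables)
    variables: tuple[str, ...]
    units: Literal["counts", "proportions"] = "counts"


def _param_subs(params: dict) -> dict:
    return {sp.Symbol(k) if isinstance(k, str) else k: v for k, v in params.items()}


def derive_odes(
    model: ReactionModel, form: Literal["counts", "concentrations"] = "counts"
) -> ODESystem:
    """Mass-action ODE system over the model's dynamic species."""
    if form == "counts":
        state = {s.name: s.symbol for s in model.species}
    else:
        state = {s.name: s.concentration for s in model.species}
    dyn = model.dynamic_species
    elim = model.elimination_map("counts" if form == "counts" else "concentrations")
    drifts = []
    for s in dyn:
        expr = sp.Integer(0)
        for r in model.reactions:
            net = r.net_change(s.name)
            if net == 0:
                continue
            flux = r.rate
            for rs, c in r.reactants:
                flux *= state[rs.name] ** c
            expr += net * flux
        drifts.append(sp.expand(expr.subs(elim)))
    variables = tuple(state[s.name] for s in dyn)
    return ODESystem(variables=variables, drift=tuple(drifts), form=form)


def integrate_odes(
    odes: ODESystem,
    init: Sequence[float],
    params: dict,
    t_end: float,
    n_points: int = 200,
    proportions: bool = False,
) -> Trajectory:
    """Integrate with an adaptive stiff/non-stiff (LSODA) solver.

    With ``proportions=True`` the output states are divided by the total of
    the initial state, giving population proportions.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (odes.dim,):
        raise ValueError(f"initial state must have dimension {odes.dim}")
    rhs = odes.rhs_function(params)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), init, method="LSODA", rtol=1e-8, atol=1e-10, t_eval=t_eval)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"integration failed near t = {t_fail:g}: {sol.message}")
    states = sol.y.T
    units = "counts"
    if proportions:
        total = init.sum()
        if total <= 0:
            raise ValueError("proportions output requires a positive initial total")
        states = states / total
        units = "proportions"
    return Trajectory(times=sol.t, states=states, variables=tuple(map(str, odes.variables)), units=units)


def _classify(eigs: np.ndarray) -> tuple[str, bool]:
    re = eigs.real
    marginal = bool(np.any(np.abs(re) <= _STAB_EPS))
    if np.all(re < -_STAB_EPS):
        return "stable", False
    if np.all(re > _STAB_EPS):
        return "unstable", marginal
    if np.any(re < -_STAB_EPS) and np.any(re > _STAB_EPS):
        return "saddle", marginal
    # marginal directions present: report unstable (conservative call)
    return "unstable", True


def _make_fixed_point(x: np.ndarray, jac_fn) -> FixedPoint:
    eigs = np.linalg.eigvals(jac_fn(x))
    cls, marginal = _classify(eigs)
    return FixedPoint(
        location=tuple(float(v) for v in x),
        eigenvalues=tuple(complex(e) for e in eigs),
        classification=cls,  # type: ignore[arg-type]
        marginal=marginal,
    )


def _damped_newton(f, jac, x0: np.ndarray, maxiter: int = 60) -> np.ndarray | None:
    x = np.asarray(x0, dtype=float)
    for _ in range(maxiter):
        fx = f(x)
        if not np.all(np.isfinite(fx)):
            return None
        if np.max(np.abs(fx)) < 1e-13:
            return x
        try:
            step = np.linalg.solve(jac(x), -fx)
        except np.linalg.LinAlgError:
            return None
        lam, base = 1.0, np.max(np.abs(fx))
        for _ in range(30):
            xn = x + lam * step
            fn = f(xn)
            if np.all(np.isfinite(fn)) and np.max(np.abs(fn)) < base:
                x = xn
                break
            lam *= 0.5
        else:
            return None
    return x if np.max(np.abs(f(x))) < _ROOT_TOL else None


def find_fixed_points(
    odes: ODESystem,
    params: dict,
    domain: Sequence[tuple[float, float]],
    constraint: Callable[[np.ndarray], bool] | None = None,
    grid: int = 8,
    symbolic: bool = True,
) -> list[FixedPoint]:
    """Equilibria of the bound drift field inside a box domain.

    A symbolic solve is attempted first (exact for the polynomial fields of
    mass-action kinetics); multi-start damped Newton iteration from a
    ``grid``-per-dimension lattice of starts supplements it.  Near-duplicates
    are merged and each point is classified by the Jacobian eigenvalues.
    An optional ``constraint`` predicate further filters points (e.g. a
    simplex condition on a closed population).
    """
    domain = [(float(lo), float(hi)) for lo, hi in domain]
    if len(domain) != odes.dim:
        raise ValueError("domain must give one (lo, hi) interval per variable")
    bound = odes.bind(params)
    funcs = [sp.lambdify(odes.variables, f, modules="numpy") for f in bound]
    f_vec = lambda y: np.array([fn(*y) for fn in funcs], dtype=float)
    jac_fn = odes.jacobian_function(params)
    scale = max(1.0, max(abs(lo) for lo, _ in domain), max(abs(hi) for _, hi in domain))

    candidates: list[np.ndarray] = []
    sols = []
    if symbolic:
        try:
            sols = sp.solve(bound, list(odes.variables), dict=True)
        except Exception:
            sols = []
    for sol in sols:
        if set(sol) != set(odes.variables):
            continue
        vals = [sp.nsimplify(sol[v]).evalf(chop=True) for v in odes.variables]
        try:
            arr = np.array([complex(v) for v in vals])
        except (TypeError, ValueError):
            continue
        if np.max(np.abs(arr.imag)) < 1e-10:
            candidates.append(arr.real.astype(float))

    axes = [np.linspace(lo, hi, grid) for lo, hi in domain]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.stack([m.ravel() for m in mesh], axis=-1)
    for x0 in starts:
        x = _damped_newton(f_vec, jac_fn, x0)
        if x is not None:
            candidates.append(x)

    merged: list[np.ndarray] = []
    tol = _MERGE_TOL * scale
    for x in candidates:
        if np.max(np.abs(f_vec(x))) > _ROOT_TOL * scale:
            continue
        if any(np.max(np.abs(x - m)) < tol for m in merged):
            continue
        if any(x[i] < domain[i][0] - tol or x[i] > domain[i][1] + tol for i in range(len(domain))):
            continue
        if constraint is not None and not constraint(x):
            continue
        merged.append(x)
    merged.sort(key=lambda x: tuple(x))
    return [_make_fixed_point(x, jac_fn) for x in merged]


@dataclass(frozen=True)
class FieldSamples:
    points: np.ndarray  # (n, dim)
    vectors: np.ndarray  # (n, dim) drift at each point
    speed: np.ndarray  # (n,) Euclidean norm of the drift
    fixed_points: tuple[FixedPoint, ...] = ()


def sample_field(
    odes: ODESystem,
    params: dict,
    bounds: Sequence[tuple[float, float]],
    n: int = 10,
) -> FieldSamples:
    """Drift direction and magnitude on an ``n``-per-axis lattice (1-D or 2-D)."""
    if odes.dim > 2:
        raise ValueError(
            "phase portraits support 1- or 2-dimensional systems; "
            "reduce the model with substitute() first"
        )
    if len(bounds) != odes.dim:
        raise ValueError("bounds must match system dimension")
    rhs = odes.rhs_function(params)
    axes = [np.linspace(lo, hi, n) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    vectors = np.array([rhs(0.0, p) for p in points])
    speed = np.linalg.norm(vectors, axis=1)
    return FieldSamples(points=points, vectors=vectors, speed=speed)


def stream_field(
    odes: ODESystem,
    params: dict,
    bounds: Sequence[tuple[float, float]],
    n: int = 10,
    constraint: Callable[[np.ndarray], bool] | None = None,
) -> FieldSamples:
    """Like :func:`sample_field`, with fixed points located for overlay."""
    samples = sample_field(odes, params, bounds, n)
    fps = find_fixed_points(odes, params, bounds, constraint=constraint)
    return FieldSamples(
        points=samples.points,
        vectors=samples.vectors,
        speed=samples.speed,
        fixed_points=tuple(fps),
    )
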