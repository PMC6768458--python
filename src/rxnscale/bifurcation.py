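"""One-parameter continuation of equilibria with BP/LP detection.

Equilibrium curves of 1- and 2-dimensional systems are traced by
pseudo-arclength continuation (tangent predictor, Newton corrector on the
drift plus an arclength constraint, adaptive step halving).  Along a branch
two test functions are monitored between accepted points:

* the parameter component of the unit tangent — a sign change marks a fold
  (limit point, LP), where two equilibria collide;
* ``det`` of the state Jacobian — a sign change without a fold marks a
  branch point (BP), where a second equilibrium curve crosses (e.g. a
  pitchfork).  A simultaneous change is reported as an LP.

Special points are refined by bisection along the curve.  At a BP the
bifurcating branch is re-seeded along the Jacobian null direction (both
orientations) and continued.  Hopf points are not detected; oscillatory
regimes are found by direct integration instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .meanfield import ODESystem, _STAB_EPS, _param_subs
from .model_dsl import ReactionModel

__all__ = [
    "SpecialPoint",
    "Branch",
    "BifurcationDiagram",
    "continue_branch",
    "switch_branch",
    "build_diagram",
]

_NEWTON_TOL = 1e-11
_REFINE_PTOL = 1e-6
_MAX_STEPS = 2000


@dataclass(frozen=True)
class SpecialPoint:
    kind: str  # "LP" | "BP"
    parameter: float
    state: tuple[float, ...]


@dataclass(frozen=True)
class Branch:
    parameter_values: np.ndarray
    states: np.ndarray  # (points, dim)
    stability: np.ndarray  # bool per point
    special_points: tuple[SpecialPoint, ...]
    # continuation context, kept so a branch can be switched at a BP
    odes: ODESystem = field(repr=False, default=None)
    param: sp.Symbol = field(repr=False, default=None)
    prange: tuple[float, float] = field(repr=False, default=(0.0, 0.0))
    state_bounds: tuple | None = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.parameter_values)


@dataclass(frozen=True)
class BifurcationDiagram:
    branches: tuple[Branch, ...]
    bifurcation_parameter: sp.Symbol
    response: sp.Expr
    warnings: tuple[str, ...] = ()

    @property
    def special_points(self) -> tuple[SpecialPoint, ...]:
        return tuple(p for b in self.branches for p in b.special_points)

    def response_values(self, branch: Branch) -> np.ndarray:
        fn = sp.lambdify(list(branch.odes.variables), self.response, modules="numpy")
        return np.array([fn(*x) for x in branch.states], dtype=float)


class _Problem:
    """Lambdified F(x, p), its Jacobians, and Newton helpers."""

    def __init__(self, odes: ODESystem, param: sp.Symbol):
        free = set().union(*(f.free_symbols for f in odes.drift)) if odes.drift else set()
        extra = free - set(odes.variables) - {param}
        if extra:
            raise ValueError(f"unbound parameters: {sorted(map(str, extra))}; bind them first")
        if odes.dim > 2:
            raise ValueError("continuation supports 1- and 2-dimensional systems")
        args = list(odes.variables) + [param]
        self.dim = odes.dim
        fs = [sp.lambdify(args, f, modules="numpy") for f in odes.drift]
        jx = odes.jacobian
        jp = sp.Matrix([sp.diff(f, param) for f in odes.drift])
        self._f = lambda x, p: np.array([fn(*x, p) for fn in fs], dtype=float)
        jx_fn = sp.lambdify(args, jx, modules="numpy")
        jp_fn = sp.lambdify(args, jp, modules="numpy")
        self._jx = lambda x, p: np.asarray(jx_fn(*x, p), dtype=float)
        self._jp = lambda x, p: np.asarray(jp_fn(*x, p), dtype=float).reshape(self.dim)

    def f(self, x, p):
        return self._f(x, p)

    def jx(self, x, p):
        return self._jx(x, p)

    def jp(self, x, p):
        return self._jp(x, p)

    def newton_fixed_p(self, x0, p, maxiter=50):
        x = np.asarray(x0, dtype=float).copy()
        for _ in range(maxiter):
            fx = self.f(x, p)
            if np.max(np.abs(fx)) < _NEWTON_TOL:
                return x
            try:
                step = np.linalg.solve(self.jx(x, p), -fx)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            base = np.max(np.abs(fx))
            for _ in range(25):
                xn = x + lam * step
                if np.all(np.isfinite(self.f(xn, p))) and np.max(np.abs(self.f(xn, p))) < base:
                    x = xn
                    break
                lam *= 0.5
            else:
                return None
        return x if np.max(np.abs(self.f(x, p))) < 1e-8 else None

    def corrector(self, u_pred, tangent, u_ref, ds, maxiter=12):
        """Newton on [F(x,p); tangent . (u - u_ref) - ds]."""
        u = u_pred.copy()
        for _ in range(maxiter):
            x, p = u[:-1], u[-1]
            fx = self.f(x, p)
            g = np.append(fx, tangent @ (u - u_ref) - ds)
            if np.max(np.abs(g)) < _NEWTON_TOL:
                return u
            J = np.zeros((self.dim + 1, self.dim + 1))
            J[: self.dim, : self.dim] = self.jx(x, p)
            J[: self.dim, -1] = self.jp(x, p)
            J[-1] = tangent
            try:
                u = u + np.linalg.solve(J, -g)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(u)):
                return None
        x, p = u[:-1], u[-1]
        ok = np.max(np.abs(self.f(x, p))) < 1e-9 and abs(tangent @ (u - u_ref) - ds) < 1e-7
        return u if ok else None

    def tangent(self, u, prev=None):
        """Unit tangent of the equilibrium curve at u, via the null space of
        the (dim x dim+1) extended Jacobian; oriented to follow ``prev``."""
        x, p = u[:-1], u[-1]
        ext = np.zeros((self.dim, self.dim + 1))
        ext[:, : self.dim] = self.jx(x, p)
        ext[:, -1] = self.jp(x, p)
        _, _, vt = np.linalg.svd(ext)
        tau = vt[-1]
        tau = tau / np.linalg.norm(tau)
        if prev is not None and prev @ tau < 0:
            tau = -tau
        if prev is None and tau[-1] < 0:
            tau = -tau
        return tau

    def is_stable(self, u):
        eigs = np.linalg.eigvals(self.jx(u[:-1], u[-1]))
        return bool(np.all(eigs.real < -_STAB_EPS))

    def det_jx(self, u):
        return float(np.linalg.det(self.jx(u[:-1], u[-1])))


def _as_symbol(param) -> sp.Symbol:
    return sp.Symbol(param) if isinstance(param, str) else param


def _walk(prob: _Problem, u0, tau, ds0, prange, max_steps, state_bounds=None):
    """One continuation direction; returns (points, tangents)."""
    lo, hi = min(prange), max(prange)
    width = hi - lo
    pts = [u0.copy()]
    taus = [tau.copy()]
    ds = ds0
    u, t = u0, tau
    for _ in range(max_steps):
        if not (lo - 1e-12 <= u[-1] <= hi + 1e-12):
            break
        if state_bounds is not None and any(
            u[i] < b_lo or u[i] > b_hi for i, (b_lo, b_hi) in enumerate(state_bounds)
        ):
            break
        success = None
        while ds > 1e-8 * width:
            u_new = prob.corrector(u + ds * t, t, u, ds)
            if u_new is not None:
                success = u_new
                break
            ds *= 0.5
        if success is None:
            break
        u = success
        t = prob.tangent(u, prev=t)
        pts.append(u.copy())
        taus.append(t.copy())
        ds = min(ds * 1.3, ds0 * 4)
        if u[-1] < lo - 1e-9 or u[-1] > hi + 1e-9:
            break
    return pts, taus


def _refine(prob: _Problem, u_a, u_b, test_fn):
    """Bisection along the curve segment for a zero of ``test_fn``."""
    fa = test_fn(u_a)
    for _ in range(60):
        if abs(u_b[-1] - u_a[-1]) < _REFINE_PTOL and np.max(np.abs(u_b - u_a)) < 1e-5:
            break
        mid = 0.5 * (u_a + u_b)
        sec = u_b - u_a
        norm = np.linalg.norm(sec)
        if norm == 0:
            break
        sec = sec / norm
        u_m = prob.corrector(mid, sec, u_a, 0.5 * norm)
        if u_m is None:
            break
        fm = test_fn(u_m)
        if fa * fm <= 0:
            u_b = u_m
        else:
            u_a, fa = u_m, fm
    return 0.5 * (u_a + u_b)


def continue_branch(
    odes: ODESystem,
    param,
    start_state,
    start_value: float,
    prange: tuple[float, float],
    step: float | None = None,
    max_steps: int = _MAX_STEPS,
    state_bounds=None,
) -> Branch:
    """Trace the equilibrium branch through ``(start_state, start_value)``.

    The start state is Newton-refined to an equilibrium; if that fails the
    system is integrated from it for a long horizon and the final state used
    as the start.  The branch is traced in both parameter directions until
    the range is exhausted.
    """
    param = _as_symbol(param)
    prob = _Problem(odes, param)
    lo, hi = float(min(prange)), float(max(prange))
    width = hi - lo
    ds0 = step if step is not None else 1e-2 * width

    x0 = prob.newton_fixed_p(np.asarray(start_state, dtype=float), start_value)
    if x0 is None:
        from .meanfield import integrate_odes

        traj = integrate_odes(
            odes, np.asarray(start_state, dtype=float), {param: start_value}, t_end=200.0
        )
        x0 = prob.newton_fixed_p(traj.states[-1], start_value)
        if x0 is None:
            raise RuntimeError(
                f"no equilibrium found near start state at {param} = {start_value}"
            )
    u0 = np.append(x0, start_value)
    tau0 = prob.tangent(u0)

    fwd_pts, fwd_taus = _walk(prob, u0, tau0, ds0, (lo, hi), max_steps, state_bounds)
    bwd_pts, bwd_taus = _walk(prob, u0, -tau0, ds0, (lo, hi), max_steps, state_bounds)
    pts = bwd_pts[::-1] + fwd_pts[1:]
    taus = [-t for t in bwd_taus[::-1]] + fwd_taus[1:]

    specials = []
    for (u_a, t_a), (u_b, t_b) in zip(zip(pts, taus), zip(pts[1:], taus[1:])):
        fold_change = t_a[-1] * t_b[-1] < 0
        det_change = prob.det_jx(u_a) * prob.det_jx(u_b) < 0
        if fold_change:
            if det_change:
                warnings.warn(
                    "simultaneous fold and determinant sign change; reporting LP",
                    stacklevel=2,
                )
            u_s = _refine(prob, u_a, u_b, lambda u, _t=t_a: prob.tangent(u, prev=_t)[-1])
            specials.append(SpecialPoint("LP", float(u_s[-1]), tuple(u_s[:-1])))
        elif det_change:
            u_s = _refine(prob, u_a, u_b, prob.det_jx)
            specials.append(SpecialPoint("BP", float(u_s[-1]), tuple(u_s[:-1])))

    arr = np.array(pts)
    return Branch(
        parameter_values=arr[:, -1],
        states=arr[:, :-1],
        stability=np.array([prob.is_stable(u) for u in pts]),
        special_points=tuple(specials),
        odes=odes,
        param=param,
        prange=(lo, hi),
        state_bounds=state_bounds,
    )


def switch_branch(branch: Branch, bp: SpecialPoint, step: float | None = None) -> Branch:
    """Continue the second equilibrium curve crossing at a branch point.

    The new branch is seeded just off the BP along the null direction of the
    state Jacobian, at parameter values slightly to either side; both null
    orientations are attempted and the resulting arms are joined through the
    BP (for a pitchfork this yields the full bifurcating curve).
    """
    if bp.kind != "BP":
        raise ValueError(f"branch switching requires a BP, got {bp.kind}")
    prob = _Problem(branch.odes, branch.param)
    lo, hi = branch.prange
    width = hi - lo
    ds0 = step if step is not None else 1e-2 * width
    x_bp = np.asarray(bp.state, dtype=float)
    p_bp = bp.parameter

    jx = prob.jx(x_bp, p_bp)
    _, svals, vt = np.linalg.svd(jx)
    if svals[-1] > 1e-4 * max(1.0, svals[0]):
        raise RuntimeError("Jacobian at the BP has no near-null direction; tangent degenerate")
    null = vt[-1]
    scale = max(1.0, np.max(np.abs(x_bp)))

    arms = []
    for orient in (null, -null):
        found = None
        for dp in (ds0, -ds0, 2 * ds0, -2 * ds0):
            p_try = p_bp + dp
            if not (lo <= p_try <= hi):
                continue
            x_main = prob.newton_fixed_p(x_bp, p_try)
            for eps in (0.03, 0.1, 0.3):
                x_new = prob.newton_fixed_p(x_bp + eps * scale * orient, p_try)
                if x_new is None:
                    continue
                if x_main is not None and np.max(np.abs(x_new - x_main)) < 1e-6 * scale:
                    continue  # fell back onto the original branch
                found = (x_new, p_try)
                break
            if found:
                break
        if found is None:
            continue
        arms.append(
            continue_branch(
                branch.odes,
                branch.param,
                found[0],
                found[1],
                (lo, hi),
                step=step,
                state_bounds=branch.state_bounds,
            )
        )
    if not arms:
        raise RuntimeError("branch switching failed: no off-branch equilibrium found near the BP")

    if len(arms) == 1:
        return arms[0]
    a, b = arms
    # join the two arms into one curve through the BP (drop duplicate overlap)
    params = np.concatenate([a.parameter_values[::-1], b.parameter_values])
    states = np.concatenate([a.states[::-1], b.states])
    stab = np.concatenate([a.stability[::-1], b.stability])
    specials = tuple(set(a.special_points) | set(b.special_points))
    return Branch(
        params,
        states,
        stab,
        specials,
        odes=branch.odes,
        param=branch.param,
        prange=branch.prange,
        state_bounds=branch.state_bounds,
    )


def _point_on_branch(b: Branch, x0: np.ndarray, p0: float, tol: float = 1e-4) -> bool:
    """Whether (x0, p0) lies on the curve, by linear interpolation between
    the pairs of consecutive branch points whose parameters bracket p0."""
    ps, xs = b.parameter_values, b.states
    scale = max(1.0, float(np.max(np.abs(xs))))
    for k in range(len(ps) - 1):
        pa, pb = ps[k], ps[k + 1]
        if not (min(pa, pb) - 1e-12 <= p0 <= max(pa, pb) + 1e-12):
            continue
        w = 0.5 if pa == pb else (p0 - pa) / (pb - pa)
        x_interp = (1 - w) * xs[k] + w * xs[k + 1]
        if np.max(np.abs(x_interp - x0)) < tol * scale:
            return True
    return False


def _branch_covered(b: Branch, others: list[Branch]) -> bool:
    """Whether every sampled point of b already lies on an existing branch."""
    if not others:
        return False
    idx = np.linspace(0, len(b) - 1, min(len(b), 12)).astype(int)
    return all(
        any(_point_on_branch(o, b.states[i], b.parameter_values[i], tol=5e-3) for o in others)
        for i in idx
    )


def build_diagram(
    model_or_odes,
    param,
    response,
    params: dict,
    init,
    prange: tuple[float, float],
    domain=None,
    form: str = "concentrations",
    step: float | None = None,
) -> BifurcationDiagram:
    """Equilibrium search, continuation and branch switching in one call.

    Equilibria are sought at both ends (and midpoint) of the parameter range
    (within ``domain`` when given, else from ``init`` only), each distinct
    one is continued, and every detected BP spawns a switched branch.
    Failures in switching are attached as warnings rather than raised.
    """
    from .meanfield import derive_odes, find_fixed_points

    param = _as_symbol(param)
    if isinstance(model_or_odes, ReactionModel):
        odes = derive_odes(model_or_odes, form)
    else:
        odes = model_or_odes
    subs = {k: v for k, v in _param_subs(params).items() if k != param}
    odes = ODESystem(
        variables=odes.variables,
        drift=tuple(sp.expand(f.subs(subs)) for f in odes.drift),
        form=odes.form,
    )
    if isinstance(response, str):
        from .model_dsl import _parse_rate

        response = _parse_rate(response, None)
    # map species names in the response onto the system's variables
    var_names = {str(v): v for v in odes.variables}
    rmap = {}
    for sym in response.free_symbols:
        if sym.name in var_names:
            rmap[sym] = var_names[sym.name]
        elif f"Phi_{sym.name}" in var_names:
            rmap[sym] = var_names[f"Phi_{sym.name}"]
    response = response.subs(rmap)

    lo, hi = float(min(prange)), float(max(prange))
    state_bounds = None
    if domain is not None:
        state_bounds = tuple(
            (b_lo - 0.25 * (b_hi - b_lo), b_hi + 0.25 * (b_hi - b_lo)) for b_lo, b_hi in domain
        )
    starts: list[tuple[np.ndarray, float]] = []
    if init is not None:
        starts.append((np.asarray(init, dtype=float), lo))
    if domain is not None:
        for p0 in (lo, hi, 0.5 * (lo + hi)):
            for fp in find_fixed_points(odes, {param: p0}, domain, symbolic=False):
                starts.append((np.array(fp.location), p0))

    branches: list[Branch] = []
    notes: list[str] = []
    for x0, p0 in starts:
        if any(_point_on_branch(b, x0, p0) for b in branches):
            continue
        try:
            nb = continue_branch(
                odes, param, x0, p0, (lo, hi), step=step, state_bounds=state_bounds
            )
        except RuntimeError as exc:
            notes.append(str(exc))
            continue
        if not _branch_covered(nb, branches):
            branches.append(nb)

    for b in list(branches):
        for spt in b.special_points:
            if spt.kind != "BP":
                continue
            try:
                nb = switch_branch(b, spt, step=step)
            except RuntimeError as exc:
                notes.append(f"branch switch at {param}={spt.parameter:.6g} failed: {exc}")
                continue
            if not _branch_covered(nb, branches):
                branches.append(nb)
    return BifurcationDiagram(
        branches=tuple(branches),
        bifurcation_parameter=param,
        response=response,
        warnings=tuple(notes),
    )
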