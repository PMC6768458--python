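"""System-size (van Kampen) expansion and linear noise approximation.

Writing each count as ``n_k = V*Phi_k + sqrt(V)*eta_k`` and expanding every
step operator to second order,

    E_k^m = 1 + (m/sqrt(V)) d/deta_k + (m^2 / 2V) d^2/deta_k^2,

the master equation separates by powers of ``sqrt(V)``.  The order
``sqrt(V)`` terms give the macroscopic (mass-action) rate equations for the
proportions ``Phi_k``; the order ``V^0`` terms give a Fokker-Planck equation
linear in the fluctuations ``eta_k`` (the linear noise approximation), fully
characterised by the drift matrix ``A`` (Jacobian of the macroscopic field)
and the diffusion matrix ``B``.  Lower orders are discarded.

From the linear FPE this module derives first/second moment ODEs by
integration by parts, the stationary fluctuation covariance ``C`` solving
the Lyapunov equation ``A C + C A^T + B = 0`` at a stable fixed point, the
lagged correlation ``<eta(t+tau) eta(t)^T> = expm(A tau) C``, and 1-sigma
noise ellipses for phase-portrait overlays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.linalg import expm, solve_continuous_lyapunov

from .master_equation import MasterEquationRep, V
from .meanfield import FixedPoint, ODESystem, _param_subs

__all__ = [
    "LinearNoiseResult",
    "MomentSystem",
    "CovarianceResult",
    "van_kampen_expand",
    "moment_equations",
    "stationary_covariance",
    "noise_correlation",
]


@dataclass(frozen=True)
class LinearNoiseResult:
    """Order ``sqrt(V)`` and ``V^0`` content of the expansion."""

    macroscopic_odes: ODESystem  # in Phi variables
    drift_matrix: sp.Matrix  # A(Phi)
    diffusion_matrix: sp.Matrix  # B(Phi), symmetric PSD on the positive orthant
    fpe: sp.Expr  # right-hand side of dP/dt, P = P(eta_1, ..., eta_K)
    etas: tuple[sp.Symbol, ...]
    distribution: sp.Expr  # the P function the fpe acts on

    @property
    def dim(self) -> int:
        return len(self.etas)


@dataclass(frozen=True)
class MomentSystem:
    """ODEs for <eta_i> and <eta_i eta_j> derived from the linear FPE."""

    first_symbols: tuple[sp.Symbol, ...]
    first_rhs: tuple[sp.Expr, ...]
    second_symbols: dict  # (i, j) i<=j -> Symbol
    second_rhs: dict  # (i, j) i<=j -> Expr


@dataclass(frozen=True)
class CovarianceResult:
    covariance: np.ndarray  # stationary <eta eta^T>
    fixed_point: FixedPoint
    # principal-axis (eigendecomposition of C) 1-sigma ellipse
    ellipse_center: tuple[float, ...]
    ellipse_axes: np.ndarray  # orthonormal columns
    ellipse_lengths: tuple[float, ...]
    # variance of the noise projected on the (normalised) eigenvectors of A
    eigvec_projections: tuple[float, ...]
    lyapunov_residual: float


def van_kampen_expand(meq: MasterEquationRep) -> LinearNoiseResult:
    """Perform the expansion symbolically and collect orders.

    Each term's propensity and operator act on the product ``a(n) P``; after
    substituting ``n = V Phi + sqrt(V) eta`` (and any conserved total
    ``N = V``) the result is an exact Laurent polynomial in ``sqrt(V)``
    whose coefficients are read off directly.  The macroscopic drift comes
    from requiring the order ``sqrt(V)`` terms to cancel against the time
    dependence of the ``eta`` variables; the order ``V^0`` remainder is the
    linear Fokker-Planck operator.
    """
    model = meq.model
    dyn = model.dynamic_species
    w = sp.Symbol("_sqrtV", positive=True)
    phis = tuple(s.concentration for s in dyn)
    etas = tuple(s.noise for s in dyn)
    P = sp.Function("P")(*etas)

    subs = {V: w**2}
    if model.conserved_total is not None:
        subs[model.conserved_total] = w**2
    for s, phi, eta in zip(dyn, phis, etas):
        subs[s.symbol] = w**2 * phi + w * eta

    rhs = sp.Integer(0)
    for term in meq.terms:
        a = term.propensity.subs(subs)
        operand = sp.expand(a) * P
        shift = {name: m for name, m in term.shifts}
        ms = [sp.Integer(shift.get(s.name, 0)) for s in dyn]
        # (prod_k E_k^{m_k} - 1) truncated at second order in 1/sqrt(V)
        first = sum(m / w * sp.diff(operand, eta) for m, eta in zip(ms, etas))
        second = sum(
            mi * mj / (2 * w**2) * sp.diff(operand, ei, ej)
            for (mi, ei), (mj, ej) in itertools.product(zip(ms, etas), repeat=2)
        )
        rhs += first + second
    rhs = sp.expand(rhs)

    # order sqrt(V): coefficient of d/deta_k is -dPhi_k/dt
    order1 = rhs.coeff(w, 1)
    drift = []
    for eta in etas:
        c = order1.coeff(sp.Derivative(P, eta))
        drift.append(sp.expand(-c))
    macro = ODESystem(variables=phis, drift=tuple(drift), form="concentrations")

    fpe = sp.expand(rhs.coeff(w, 0))

    n = len(etas)
    A = sp.zeros(n, n)
    B = sp.zeros(n, n)
    for i, ei in enumerate(etas):
        ci = fpe.coeff(sp.Derivative(P, ei))
        for j, ej in enumerate(etas):
            # drift part: -sum_ij A_ij d/deta_i (eta_j P)
            A[i, j] = sp.expand(-sp.diff(ci, ej))
        for j in range(i, n):
            if j == i:
                B[i, i] = sp.expand(2 * fpe.coeff(sp.Derivative(P, (ei, 2))))
            else:
                cij = fpe.coeff(sp.Derivative(P, ei, etas[j]))
                B[i, j] = B[j, i] = sp.expand(cij)
    return LinearNoiseResult(
        macroscopic_odes=macro,
        drift_matrix=A,
        diffusion_matrix=B,
        fpe=fpe,
        etas=etas,
        distribution=P,
    )


def _expectation(expr: sp.Expr, etas: Sequence[sp.Symbol], m1: dict, m2: dict) -> sp.Expr:
    """<expr> for a polynomial of degree <= 2 in the eta variables."""
    expr = sp.expand(expr)
    if expr.is_zero:
        return sp.Integer(0)
    out = sp.Integer(0)
    for mono in sp.Add.make_args(expr):
        if mono.is_zero:
            continue
        degs = [sp.degree(mono, e) for e in etas]
        total = sum(degs)
        coeff = mono
        for e, d in zip(etas, degs):
            coeff = coeff / e**d
        if total == 0:
            out += mono
        elif total == 1:
            i = next(i for i, d in enumerate(degs) if d)
            out += coeff * m1[i]
        elif total == 2:
            idx = [i for i, d in enumerate(degs) for _ in range(d)]
            i, j = min(idx), max(idx)
            out += coeff * m2[(i, j)]
        else:  # pragma: no cover - cannot arise from a linear FPE
            raise ValueError(f"moment of degree {total} encountered")
    return sp.expand(out)


def moment_equations(lnr: LinearNoiseResult) -> MomentSystem:
    """First- and second-moment ODEs via integration by parts.

    Each FPE term ``c(eta) * D^alpha P`` contributes
    ``(-1)^|alpha| <D^alpha (weight * c)>`` to ``d<weight>/dt``.
    """
    etas = lnr.etas
    P = lnr.distribution
    n = len(etas)
    m1 = {i: sp.Symbol(f"m1_{e.name[4:]}") for i, e in enumerate(etas)}
    m2 = {
        (i, j): sp.Symbol(f"m2_{etas[i].name[4:]}_{etas[j].name[4:]}")
        for i in range(n)
        for j in range(i, n)
    }

    def rhs_for(weight: sp.Expr) -> sp.Expr:
        total = sp.Integer(0)
        for term in sp.Add.make_args(lnr.fpe):
            if term.is_zero:
                continue
            deriv = None
            coeff = sp.Integer(1)
            for factor in sp.Mul.make_args(term):
                if isinstance(factor, sp.Derivative) or factor == P:
                    deriv = factor
                else:
                    coeff *= factor
            if deriv is None:
                raise ValueError(f"FPE term without distribution factor: {term}")
            if deriv == P:
                total += _expectation(weight * coeff, etas, m1, m2)
                continue
            order = 0
            integrand = weight * coeff
            for var, count in deriv.variable_count:
                order += count
                integrand = sp.diff(integrand, var, count)
            total += (-1) ** order * _expectation(integrand, etas, m1, m2)
        return total

    first_rhs = tuple(rhs_for(e) for e in etas)
    second_rhs = {
        (i, j): rhs_for(etas[i] * etas[j]) for i in range(n) for j in range(i, n)
    }
    return MomentSystem(
        first_symbols=tuple(m1[i] for i in range(n)),
        first_rhs=first_rhs,
        second_symbols=m2,
        second_rhs=second_rhs,
    )


def _bind_matrix(mat: sp.Matrix, lnr: LinearNoiseResult, fp: FixedPoint, params: dict) -> np.ndarray:
    subs = _param_subs(params)
    subs.update({phi: val for phi, val in zip(lnr.macroscopic_odes.variables, fp.location)})
    bound = mat.subs(subs)
    free = bound.free_symbols
    if free:
        raise ValueError(f"unbound symbols in LNA matrices: {sorted(map(str, free))}")
    return np.array(bound.evalf(), dtype=float)


def stationary_covariance(
    lnr: LinearNoiseResult, fp: FixedPoint, params: dict
) -> CovarianceResult:
    """Stationary fluctuation covariance at a stable macroscopic fixed point.

    Solves ``A C + C A^T + B = 0`` exactly (linear solve on the independent
    entries of the symmetric ``C``) and falls back to a numerical Lyapunov
    solver for larger systems.
    """
    if not fp.is_stable:
        raise ValueError("stationary noise requires a stable fixed point")
    A = _bind_matrix(lnr.drift_matrix, lnr, fp, params)
    B = _bind_matrix(lnr.diffusion_matrix, lnr, fp, params)
    n = A.shape[0]
    C: np.ndarray | None = None
    if n <= 3:
        # exact linear solve on the n(n+1)/2 independent entries
        pairs = [(i, j) for i in range(n) for j in range(i, n)]
        Asym = sp.Matrix(A)
        Bsym = sp.Matrix(B)
        unknowns = {p: sp.Symbol(f"c_{p[0]}{p[1]}") for p in pairs}
        Csym = sp.Matrix(n, n, lambda i, j: unknowns[(min(i, j), max(i, j))])
        eqs = Asym * Csym + Csym * Asym.T + Bsym
        system = [eqs[i, j] for i, j in pairs]
        sol = sp.solve(system, list(unknowns.values()), dict=True)
        if sol:
            C = np.array(
                [[float(sol[0][unknowns[(min(i, j), max(i, j))]]) for j in range(n)] for i in range(n)]
            )
    if C is None:
        C = solve_continuous_lyapunov(A, -B)
    C = (C + C.T) / 2
    residual = float(np.max(np.abs(A @ C + C @ A.T + B)))

    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lengths = tuple(float(np.sqrt(max(v, 0.0))) for v in evals)

    proj = []
    for vec in np.linalg.eig(A)[1].T:
        v = np.real_if_close(vec)
        v = np.real(v)
        norm = np.linalg.norm(v)
        if norm == 0:
            proj.append(float("nan"))
            continue
        v = v / norm
        proj.append(float(v @ C @ v))
    return CovarianceResult(
        covariance=C,
        fixed_point=fp,
        ellipse_center=fp.location,
        ellipse_axes=evecs,
        ellipse_lengths=lengths,
        eigvec_projections=tuple(proj),
        lyapunov_residual=residual,
    )


def noise_correlation(
    lnr: LinearNoiseResult,
    fp: FixedPoint,
    cov: CovarianceResult,
    lags: Sequence[float],
    params: dict,
) -> list[np.ndarray]:
    """Stationary lagged correlation matrices ``<eta(t+tau) eta(t)^T>``."""
    if not fp.is_stable:
        raise ValueError("noise correlations require a stable fixed point")
    lags = [float(tau) for tau in lags]
    if any(tau < 0 for tau in lags):
        raise ValueError("lags must be non-negative")
    A = _bind_matrix(lnr.drift_matrix, lnr, fp, params)
    return [expm(A * tau) @ cov.covariance for tau in lags]
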