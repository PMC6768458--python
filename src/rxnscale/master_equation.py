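"""Chemical master equation construction.

For a reaction ``alpha_1 X_1 + ... -> beta_1 X_1 + ...`` with constant rate
``r``, the master equation for the joint distribution ``P({n_k}; t)`` gains
the term::

    r * V * (prod_k E_k^(alpha_k - beta_k) - 1) * prod_j ff(n_j, alpha_j) / V^alpha_j * P

where ``E_k^m`` is the step operator shifting ``n_k`` by ``+m`` inside its
operand, ``ff(n, a) = n! / (n - a)!`` is the falling factorial, and ``V`` is
the system size.  A reversible process is written as two explicit rules, each
contributing its own term.  Constant reservoir species enter through their
fixed concentration (count ``Phi * V``), contributing ``Phi^alpha`` to the
propensity and carrying no step operator; likewise an eliminated species is
replaced by its count expression and carries no operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from .model_dsl import ReactionModel, Reaction

__all__ = ["V", "MasterTerm", "MasterEquationRep", "derive_master_equation"]

#: the system-size symbol shared by all finite-population descriptions
V = sp.Symbol("V", positive=True)

#: formal step operator for display: StepE(n_k, m) means E_k^m
StepE = sp.Function("E")


@dataclass(frozen=True)
class MasterTerm:
    """One reaction's contribution: ``propensity * (prod E^shift - 1) * P``."""

    reaction: Reaction
    #: full symbolic propensity in dynamic count symbols, reservoir Phi
    #: symbols, parameters and V (the factor multiplying the operator)
    propensity: sp.Expr
    #: step-operator exponents alpha_k - beta_k per dynamic species name
    shifts: tuple[tuple[str, int], ...]

    def operator_expression(self, P: sp.Expr) -> sp.Expr:
        """Formal expression with unevaluated step operators."""
        op = sp.Integer(1)
        for name, m in self.shifts:
            op *= StepE(sp.Symbol(name), sp.Integer(m))
        return self.propensity * (op - 1) * P


@dataclass(frozen=True)
class MasterEquationRep:
    """Symbolic master equation: ``dP/dt = sum of terms``."""

    model: ReactionModel
    terms: tuple[MasterTerm, ...]

    @property
    def state_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(s.symbol for s in self.model.dynamic_species)

    @property
    def distribution(self) -> sp.Expr:
        t = sp.Symbol("t")
        return sp.Function("P")(*self.state_symbols, t)

    def to_expression(self) -> sp.Expr:
        """The right-hand side with formal (unevaluated) step operators."""
        P = self.distribution
        return sp.Add(*(term.operator_expression(P) for term in self.terms))

    def with_identity_operators(self) -> sp.Expr:
        """The right-hand side with every step operator set to the identity.

        Probability conservation requires this to vanish identically (each
        operator factor ``E^m - 1`` collapses to zero).
        """
        P = self.distribution
        total = sp.Integer(0)
        for term in self.terms:
            total += term.propensity * (sp.Integer(1) - 1) * P
        return sp.simplify(total)

    def __str__(self) -> str:
        return f"dP/dt = {self.to_expression()}"


def derive_master_equation(model: ReactionModel) -> MasterEquationRep:
    """Build the master equation of ``model`` term by term.

    The propensity of each reaction is ``rate * V * prod_j ff(n_j, a_j)/V^a_j``
    over its dynamic reactants (so a unimolecular propensity is ``rate * n``
    and a bimolecular one ``rate * n * (n-1) / V``), times ``Phi_j^a_j`` for
    reservoir reactants.  Eliminated species appear through their replacement
    count expression.
    """
    elim = model.elimination_map("counts")
    elim_names = {s.name for s, _ in model.eliminated}
    dyn_names = {s.name for s in model.dynamic_species}
    terms = []
    for r in model.reactions:
        prop = r.rate * V
        for s, a in r.reactants:
            if s.is_constant:
                prop *= s.concentration ** a
            else:
                prop *= sp.ff(s.symbol, a) / V**a
        prop = prop.subs(elim)
        shifts = []
        for name in sorted({s.name for s, _ in r.reactants} | {s.name for s, _ in r.products}):
            if name not in dyn_names or name in elim_names:
                continue
            m = -r.net_change(name)  # alpha - beta: the shift undoing the reaction
            if m != 0:
                shifts.append((name, m))
        terms.append(MasterTerm(reaction=r, propensity=sp.expand(prop), shifts=tuple(shifts)))
    return MasterEquationRep(model=model, terms=tuple(terms))
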