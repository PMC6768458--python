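"""Textual reaction-rule models.

A model is written one rule per line (or ``;``-separated)::

    U -> A : g_A
    A + U -> A + A : r_A
    (A) -> X : k          # "(A)" is a constant reservoir species
    X + X -> EMPTY : h    # "EMPTY" denotes the empty set

The left- and right-hand sides are ``+``-separated terms, each an optional
positive integer coefficient followed by a species name.  Rates are symbolic
expressions over model parameters (species symbols are not allowed in rates;
mass-action kinetics supply all state dependence).

Models support algebraic manipulation: parameter rates can be rewritten in
terms of new quantities, and a dynamic species can be eliminated from the
state (e.g. ``U = N - A - B`` for a closed population), which reduces the
dimension of every derived description by one.  Species elimination acts on
derived expressions (ODEs, master equation, propensities), never on the rules
themselves.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr

__all__ = [
    "Species",
    "Reaction",
    "ReactionModel",
    "SubstitutionSpec",
    "ModelSyntaxError",
    "parse_model",
    "parse_substitutions",
    "substitute",
    "stoichiometry",
    "serialize_model",
]

#: symbols with a fixed meaning in derived descriptions; they cannot be used
#: as species or parameter names ("Phi_" prefixes concentrations, "eta_"
#: noise variables, V is the system size, t time, E the step operator,
#: P the probability distribution).
RESERVED_NAMES = frozenset({"V", "t", "E", "P", "Phi", "eta", "EMPTY"})
RESERVED_PREFIXES = ("Phi_", "eta_")

_TERM_RE = re.compile(r"^\s*(\d+)?\s*(\(\s*([A-Za-z_]\w*)\s*\)|([A-Za-z_]\w*))\s*$")


class ModelSyntaxError(ValueError):
    """Raised when rule text does not match the grammar."""


@dataclass(frozen=True)
class Species:
    name: str
    is_constant: bool = False

    @property
    def symbol(self) -> sp.Symbol:
        return sp.Symbol(self.name)

    @property
    def concentration(self) -> sp.Symbol:
        """The proportion/concentration symbol Phi_<name>."""
        return sp.Symbol(f"Phi_{self.name}")

    @property
    def noise(self) -> sp.Symbol:
        """The fluctuation symbol eta_<name> of the system-size expansion."""
        return sp.Symbol(f"eta_{self.name}")


@dataclass(frozen=True)
class Reaction:
    """One rule ``reactants -> products : rate``.

    ``reactants``/``products`` are tuples of (species, integer coefficient).
    """

    reactants: tuple[tuple[Species, int], ...]
    products: tuple[tuple[Species, int], ...]
    rate: sp.Expr

    def coefficient(self, name: str, side: str) -> int:
        terms = self.reactants if side == "reactants" else self.products
        return sum(c for s, c in terms if s.name == name)

    def net_change(self, name: str) -> int:
        return self.coefficient(name, "products") - self.coefficient(name, "reactants")

    def __str__(self) -> str:
        def side(terms: tuple[tuple[Species, int], ...]) -> str:
            if not terms:
                return "EMPTY"
            parts = []
            for s, c in terms:
                token = f"({s.name})" if s.is_constant else s.name
                parts.append(token if c == 1 else f"{c} {token}")
            return " + ".join(parts)

        return f"{side(self.reactants)} -> {side(self.products)} : {self.rate}"


@dataclass(frozen=True)
class SubstitutionSpec:
    """A single rewrite ``target = replacement``."""

    target: sp.Symbol
    replacement: sp.Expr

    @classmethod
    def from_string(cls, text: str) -> "SubstitutionSpec":
        if "=" not in text:
            raise ModelSyntaxError(f"substitution {text!r} must have the form 'target = expr'")
        lhs, rhs = text.split("=", 1)
        lhs = lhs.strip()
        if not re.fullmatch(r"[A-Za-z_]\w*", lhs):
            raise ModelSyntaxError(f"substitution target {lhs!r} is not an identifier")
        return cls(sp.Symbol(lhs), _parse_rate(rhs, line_no=None))


@dataclass(frozen=True)
class ReactionModel:
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    #: species eliminated from the dynamic state, mapped to their
    #: count-expression replacement (e.g. U -> N - A - B); insertion ordered.
    eliminated: tuple[tuple[Species, sp.Expr], ...] = ()
    #: symbol introduced by a closed-system elimination (e.g. the total N)
    conserved_total: sp.Symbol | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")

    # -- views ---------------------------------------------------------
    @property
    def dynamic_species(self) -> tuple[Species, ...]:
        gone = {s.name for s, _ in self.eliminated}
        return tuple(s for s in self.species if not s.is_constant and s.name not in gone)

    @property
    def constant_species(self) -> tuple[Species, ...]:
        return tuple(s for s in self.species if s.is_constant)

    @property
    def parameters(self) -> frozenset[sp.Symbol]:
        """Free symbols of all rates and elimination expressions that are not species."""
        species_syms = {s.symbol for s in self.species}
        syms: set[sp.Symbol] = set()
        for r in self.reactions:
            syms |= r.rate.free_symbols
        for _, repl in self.eliminated:
            syms |= repl.free_symbols
        return frozenset(syms - species_syms)

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def elimination_map(self, representation: str = "counts") -> dict[sp.Symbol, sp.Expr]:
        """Replacements for eliminated species symbols.

        In the ``concentrations`` representation, species symbols inside a
        replacement are mapped to their Phi counterparts; any other symbol
        (e.g. a conserved total N) is kept and is then measured in
        proportion units (N = 1 for a closed unit population).
        """
        out: dict[sp.Symbol, sp.Expr] = {}
        if representation == "counts":
            for s, repl in self.eliminated:
                out[s.symbol] = repl
        else:
            phi = {sp2.symbol: sp2.concentration for sp2 in self.species}
            for s, repl in self.eliminated:
                out[s.concentration] = repl.subs(phi)
        # allow earlier eliminations to refer to later ones
        for _ in range(len(out)):
            out = {k: v.subs(out) for k, v in out.items()}
        return out

    def substitute(self, spec) -> "ReactionModel":
        return substitute(self, spec)

    def __str__(self) -> str:
        return serialize_model(self)


def _check_name(name: str, line_no: int | None) -> None:
    if name in RESERVED_NAMES or name.startswith(RESERVED_PREFIXES):
        where = "" if line_no is None else f" (line {line_no})"
        raise ModelSyntaxError(f"{name!r} is a reserved symbol and cannot be used{where}")


#: function names usable inside rate expressions; every other identifier is a symbol
_EXPR_FUNCS = {"sqrt": sp.sqrt, "exp": sp.exp, "log": sp.log, "Abs": sp.Abs, "pi": sp.pi}


def _parse_rate(text: str, line_no: int | None) -> sp.Expr:
    idents = set(re.findall(r"[A-Za-z_]\w*", text))
    local = {name: sp.Symbol(name) for name in idents if name not in _EXPR_FUNCS}
    local.update(_EXPR_FUNCS)
    try:
        expr = parse_expr(text.strip(), local_dict=local, evaluate=True)
    except Exception as exc:  # sympy raises a zoo of error types
        where = "" if line_no is None else f" on line {line_no}"
        raise ModelSyntaxError(f"cannot parse expression {text.strip()!r}{where}: {exc}") from exc
    for sym in expr.free_symbols:
        _check_name(sym.name, line_no)
    return expr


def _parse_side(text: str, line_no: int) -> list[tuple[str, int, bool]]:
    """Return [(name, coefficient, is_constant), ...]; EMPTY gives []."""
    text = text.strip()
    if text in ("EMPTY", "∅"):
        return []
    terms = []
    for raw in text.split("+"):
        m = _TERM_RE.match(raw)
        if m is None:
            raise ModelSyntaxError(f"bad term {raw.strip()!r} on line {line_no}")
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff < 1:
            raise ModelSyntaxError(f"coefficient must be >= 1 on line {line_no}: {raw.strip()!r}")
        is_const = m.group(3) is not None
        name = m.group(3) or m.group(4)
        if name == "EMPTY":
            raise ModelSyntaxError(f"EMPTY cannot carry a coefficient or parentheses (line {line_no})")
        _check_name(name, line_no)
        terms.append((name, coeff, is_const))
    # aggregate repeated mentions ("X + X" == "2 X") into a multiset
    merged: dict[str, tuple[int, bool]] = {}
    for name, coeff, is_const in terms:
        if name in merged:
            prev_c, prev_k = merged[name]
            if prev_k != is_const:
                raise ModelSyntaxError(
                    f"species {name!r} written both as constant and dynamic (line {line_no})"
                )
            merged[name] = (prev_c + coeff, is_const)
        else:
            merged[name] = (coeff, is_const)
    return [(n, c, k) for n, (c, k) in merged.items()]


def parse_model(text: str) -> ReactionModel:
    """Parse rule text into a :class:`ReactionModel`.

    Species are registered in order of first appearance; a name written
    ``(name)`` anywhere is a constant reservoir species (it must be written
    that way consistently).  Duplicate identical rules are kept as separate
    reactions with a warning.
    """
    if not text or not text.strip():
        raise ModelSyntaxError("empty model description")
    species: dict[str, bool] = {}  # name -> is_constant, insertion ordered
    raw_rules: list[tuple[int, list, list, sp.Expr]] = []
    line_no = 0
    for physical_line in text.splitlines():
        line_no += 1
        for chunk in physical_line.split(";"):
            rule = chunk.split("#", 1)[0].strip()
            if not rule:
                continue
            if "->" not in rule:
                raise ModelSyntaxError(f"missing '->' on line {line_no}: {rule!r}")
            lhs, rest = rule.split("->", 1)
            if ":" not in rest:
                raise ModelSyntaxError(f"missing ': rate' on line {line_no}: {rule!r}")
            rhs, rate_text = rest.rsplit(":", 1)
            left = _parse_side(lhs, line_no)
            right = _parse_side(rhs, line_no)
            if not left and not right:
                raise ModelSyntaxError(f"rule on line {line_no} has empty reactants and products")
            rate = _parse_rate(rate_text, line_no)
            for name, _, is_const in left + right:
                if name in species and species[name] != is_const:
                    raise ModelSyntaxError(
                        f"species {name!r} written both as constant and dynamic (line {line_no})"
                    )
                species.setdefault(name, is_const)
            raw_rules.append((line_no, left, right, rate))

    sp_objs = {name: Species(name, is_constant=c) for name, c in species.items()}
    reactions = []
    for _, left, right, rate in raw_rules:
        for sym in rate.free_symbols:
            if sym.name in species:
                raise ModelSyntaxError(
                    f"rate {rate} references species {sym.name!r}; rates must be "
                    "expressions over parameters only"
                )
        reactions.append(
            Reaction(
                reactants=tuple((sp_objs[n], c) for n, c, _ in left),
                products=tuple((sp_objs[n], c) for n, c, _ in right),
                rate=rate,
            )
        )
    seen: set[str] = set()
    for r in reactions:
        key = str(r)
        if key in seen:
            warnings.warn(f"duplicate rule kept as separate reaction: {key}", stacklevel=2)
        seen.add(key)
    return ReactionModel(species=tuple(sp_objs.values()), reactions=tuple(reactions))


def parse_substitutions(spec) -> list[SubstitutionSpec]:
    """Accept a SubstitutionSpec, a string (``,``-separated), or a sequence of either."""
    if isinstance(spec, SubstitutionSpec):
        return [spec]
    if isinstance(spec, str):
        return [SubstitutionSpec.from_string(p) for p in spec.split(",") if p.strip()]
    out: list[SubstitutionSpec] = []
    for item in spec:
        out.extend(parse_substitutions(item))
    return out


def substitute(model: ReactionModel, spec) -> ReactionModel:
    """Apply substitutions in order, returning a new model.

    A parameter target rewrites every rate (and pending elimination
    expression).  A dynamic-species target eliminates that species from the
    state: derived descriptions replace its symbol by the given expression
    and lose one dimension.  New symbols introduced by the replacement become
    parameters of the result; for a single-symbol closed-system elimination
    (``U = N - A - B``) the new symbol is recorded as the conserved total.
    """
    specs = parse_substitutions(spec)
    species_names = {s.name for s in model.species}
    reactions = list(model.reactions)
    eliminated = list(model.eliminated)
    conserved = model.conserved_total

    for sub in specs:
        tname = sub.target.name
        if tname in species_names:
            target_sp = model.species_by_name(tname)
            if target_sp.is_constant:
                raise ValueError(f"cannot eliminate constant species {tname!r}")
            if any(s.name == tname for s, _ in eliminated):
                raise ValueError(f"species {tname!r} already eliminated")
            new_syms = {
                s for s in sub.replacement.free_symbols if s.name not in species_names
            }
            for s in new_syms:
                _check_name(s.name, None)
            eliminated.append((target_sp, sub.replacement))
            introduced = sorted(new_syms - {p for p in model.parameters}, key=str)
            if conserved is None and len(introduced) == 1:
                conserved = introduced[0]
        else:
            current_params = set().union(*(r.rate.free_symbols for r in reactions)) if reactions else set()
            current_params |= set().union(*(repl.free_symbols for _, repl in eliminated)) if eliminated else set()
            if sub.target not in current_params:
                raise ValueError(f"substitution target {tname!r} is neither a species nor a parameter")
            for s in sub.replacement.free_symbols:
                if s.name in species_names:
                    raise ValueError(
                        f"replacement for parameter {tname!r} introduces species symbol {s.name!r}"
                    )
                _check_name(s.name, None)
            reactions = [
                Reaction(r.reactants, r.products, r.rate.subs(sub.target, sub.replacement))
                for r in reactions
            ]
            eliminated = [(s, repl.subs(sub.target, sub.replacement)) for s, repl in eliminated]

    return ReactionModel(
        species=model.species,
        reactions=tuple(reactions),
        eliminated=tuple(eliminated),
        conserved_total=conserved,
    )


def stoichiometry(model: ReactionModel):
    """Net-change matrix (dynamic species x reactions), entries beta - alpha."""
    import numpy as np

    dyn = model.dynamic_species
    mat = np.zeros((len(dyn), len(model.reactions)), dtype=int)
    for j, r in enumerate(model.reactions):
        for i, s in enumerate(dyn):
            mat[i, j] = r.net_change(s.name)
    return mat


def serialize_model(model: ReactionModel) -> str:
    """Canonical text form; re-parsing yields a symbolically identical model."""
    return "\n".join(str(r) for r in model.reactions)
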