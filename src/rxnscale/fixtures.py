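"""Packaged reference models with their published parameter sets.

* ``honeybee`` — the stop-signal model of nest-site selection in honeybee
  swarms: uncommitted scouts U discover site A or B (rates g_A, g_B),
  abandon (a_A, a_B), recruit (r_A, r_B), and committed bees cross-inhibit
  each other at rate s.  Rates are re-expressed in terms of site qualities
  v_A = mu + Delta/2, v_B = mu - Delta/2 (discovery and recruitment
  proportional to quality, abandonment inversely proportional).
* ``honeybee_reduced`` — the same model with U eliminated through the
  closed-population relation U = N - A - B, giving a two-dimensional system.
* ``brusselator`` — the classic autocatalytic oscillator: constant feeds
  alpha, beta; X produced from alpha (rate chi), converted to Y by beta
  (delta), autocatalytically regenerated via 2X + Y -> 3X (gamma), and
  degraded (xi).  With all rates and feed concentrations at their reference
  values the fixed point is stable; raising Phi_beta to 5.5 crosses the
  oscillatory (limit-cycle) threshold, which for this kinetics with equal
  rate constants sits at Phi_beta = 1 + Phi_alpha^2 (consistent with the
  stable/oscillatory split of the two reference sets either side of
  ~Phi_alpha^2).
* ``lotka_volterra`` — predator-prey kinetics: prey X reproduce on a
  constant resource A, predators Y convert prey, predators die.
* ``toy_birth_annihilation`` — reservoir birth (A) -> X at rate k with
  pairwise annihilation X + X -> 0 at rate h; the standard worked example
  for master-equation expansion.
* ``birth_death`` — immigration-death process with Poisson stationary law.
"""

from __future__ import annotations

from .model_dsl import ReactionModel, parse_model

__all__ = [
    "FIXTURES",
    "load_fixture",
    "honeybee_quality_substitutions",
    "honeybee_reduction_substitution",
]

#: the rate re-parameterisation in terms of site qualities, applied in order
honeybee_quality_substitutions = (
    "a_A = 1/v_A, a_B = 1/v_B, g_A = v_A, g_B = v_B, r_A = v_A, r_B = v_B",
    "v_A = mu + Delta/2, v_B = mu - Delta/2",
)
#: the closed-population species elimination
honeybee_reduction_substitution = "U = N - A - B"

_HONEYBEE_RULES = """\
U -> A : g_A
U -> B : g_B
A -> U : a_A
B -> U : a_B
A + U -> A + A : r_A
B + U -> B + B : r_B
A + B -> A + U : s
A + B -> B + U : s
"""

_FIXTURE_RULES = {
    "honeybee": _HONEYBEE_RULES,
    "honeybee_reduced": _HONEYBEE_RULES,
    "brusselator": """\
(alpha) -> X : chi
(beta) + X -> Y : delta
2 X + Y -> 3 X : gamma
X -> EMPTY : xi
""",
    "lotka_volterra": """\
(A) + X -> 2 X : alpha
X + Y -> 2 Y : beta
Y -> EMPTY : gamma
""",
    "toy_birth_annihilation": """\
(A) -> X : k
X + X -> EMPTY : h
""",
    "birth_death": """\
EMPTY -> X : b
X -> EMPTY : d
""",
}

#: reference parameter sets, keyed by the figure panel they reproduce
_REFERENCE_PARAMS = {
    "honeybee": {
        "fig6_left": {
            "Delta": 0.0, "mu": 3.0, "s": 3.0,
            "system_size": 50, "t_max": 10.0, "runs": 10,
        },
    },
    "honeybee_reduced": {
        "fig4_lower_right": {"Delta": 0.0, "mu": 3.0, "s": 10.0, "N": 20.0, "system_size": 20},
        "fig5_left": {"Delta": 0.0, "mu": 4.0, "N": 1.0},
        "fig5_centre": {"Delta": 0.1, "mu": 4.0, "N": 1.0},
        "fig5_right": {"mu": 4.0, "s": 4.0, "N": 1.0},
    },
    "brusselator": {
        "fig3_left": {
            "Phi_alpha": 2.0, "Phi_beta": 2.0, "chi": 2.0, "delta": 2.0,
            "gamma": 2.0, "xi": 2.0, "system_size": 10,
        },
        "fig3_right": {
            "Phi_alpha": 2.0, "Phi_beta": 5.5, "chi": 2.0, "delta": 2.0,
            "gamma": 2.0, "xi": 2.0, "system_size": 10,
        },
    },
    "lotka_volterra": {
        "fig4_upper_left": {"Phi_A": 2.0, "alpha": 2.0, "beta": 2.0, "gamma": 2.0},
    },
    "toy_birth_annihilation": {
        "unit_rates": {"k": 1.0, "h": 1.0, "Phi_A": 1.0},
    },
    "birth_death": {
        "default": {"b": 1.0, "d": 1.0},
    },
}

FIXTURES = tuple(_FIXTURE_RULES)


def load_fixture(name: str) -> tuple[ReactionModel, dict]:
    """Return (parsed model, reference parameter sets keyed by figure panel).

    ``honeybee`` is returned with rates already expressed in (mu, Delta, s);
    ``honeybee_reduced`` additionally has U eliminated via U = N - A - B.
    """
    if name not in _FIXTURE_RULES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    model = parse_model(_FIXTURE_RULES[name])
    if name in ("honeybee", "honeybee_reduced"):
        if name == "honeybee_reduced":
            model = model.substitute(honeybee_reduction_substitution)
        for sub in honeybee_quality_substitutions:
            model = model.substitute(sub)
    sets = {k: dict(v) for k, v in _REFERENCE_PARAMS[name].items()}
    return model, sets
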