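import pytest

from rxnscale import load_fixture, parse_model


@pytest.fixture(scope="session")
def toy_model():
    """Reservoir birth plus pairwise annihilation: (A) -> X : k, X + X -> 0 : h."""
    model, _ = load_fixture("toy_birth_annihilation")
    return model


@pytest.fixture(scope="session")
def honeybee():
    """8-rule stop-signal model, rates in (mu, Delta, s) quality form."""
    model, _ = load_fixture("honeybee")
    return model


@pytest.fixture(scope="session")
def honeybee_reduced():
    """Stop-signal model with U eliminated via U = N - A - B."""
    model, _ = load_fixture("honeybee_reduced")
    return model


@pytest.fixture(scope="session")
def honeybee_raw():
    """8-rule stop-signal model with raw rates g, a, r, s."""
    return parse_model(
        "U -> A : g_A\n"
        "U -> B : g_B\n"
        "A -> U : a_A\n"
        "B -> U : a_B\n"
        "A + U -> A + A : r_A\n"
        "B + U -> B + B : r_B\n"
        "A + B -> A + U : s\n"
        "A + B -> B + U : s\n"
    )


@pytest.fixture(scope="session")
def brusselator():
    model, params = load_fixture("brusselator")
    return model, params


@pytest.fixture(scope="session")
def birth_death():
    model, _ = load_fixture("birth_death")
    return model
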