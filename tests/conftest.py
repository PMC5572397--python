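import pytest

from enzgem import assign_kcats, make_overflow_model, make_toy_ec, make_toy_gem
from enzgem.fixtures import ORGANISM


@pytest.fixture()
def toy_bundle():
    """(model, enzymes, kinetics) for the TOY1 network."""
    return make_toy_gem()


@pytest.fixture()
def toy_assignments(toy_bundle):
    model, enzymes, kinetics = toy_bundle
    return assign_kcats(model, enzymes, kinetics, ORGANISM)


@pytest.fixture()
def toy_ec():
    """TOY1 expanded, usage bounds +inf."""
    return make_toy_ec()


@pytest.fixture()
def overflow():
    """Factory for OVF1 at a given substrate availability."""
    return make_overflow_model
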