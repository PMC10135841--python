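from fractions import Fraction

import pytest

from c1flux import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    add_module,
    build_stack,
    c1_module,
    core_module,
    nog_module,
    phb_module,
)


@pytest.fixture(scope="session")
def rump_net():
    """core + C1 + PHB with methanol fixed at 6 mmol/gDCW/h."""
    return build_stack("rump")


@pytest.fixture(scope="session")
def mcc_net():
    """core + C1 + NOG + PHB with methanol fixed at 6 mmol/gDCW/h."""
    return build_stack("mcc")


@pytest.fixture(scope="session")
def mcc_frma_net():
    """MCC stack including the formaldehyde drain (frmA present)."""
    return build_stack("mcc", with_frma=True)


@pytest.fixture
def toy_chain():
    """EX_A(<=1) -> A -> B -> sink_B; optimum 1 by construction."""
    mets = [Metabolite("A", carbon_count=1), Metabolite("B", carbon_count=1)]
    rxns = [
        Reaction("EX_A", {"A": Fraction(1)}, lower_bound=0, upper_bound=1, kind="exchange"),
        Reaction("R_AB", {"A": Fraction(-1), "B": Fraction(1)}, lower_bound=0, upper_bound=10),
        Reaction("SINK_B", {"B": Fraction(-1)}, lower_bound=0, upper_bound=10, kind="sink"),
    ]
    return MetabolicNetwork(mets, rxns)


@pytest.fixture(scope="session")
def bare_network():
    """Empty network plus the full module union, for assembly tests."""
    net = MetabolicNetwork()
    for mod in (core_module(), c1_module(), nog_module(), phb_module()):
        net = add_module(net, mod)
    return net
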