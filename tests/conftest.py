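import numpy as np
import pytest

from synprime import (
    DEFAULT_CALCIUM,
    FSIN_PARAMS,
    OLM_PARAMS,
    FitProblem,
    simulate,
    standard_protocols,
)
from synprime.protocols import SIMPLE_FIT_PROTOCOLS


@pytest.fixture(scope="session")
def protos():
    return standard_protocols()


@pytest.fixture(scope="session")
def cap():
    return DEFAULT_CALCIUM


@pytest.fixture(scope="session")
def fsin():
    return FSIN_PARAMS


@pytest.fixture(scope="session")
def olm():
    return OLM_PARAMS


@pytest.fixture(scope="session")
def fsin_sims(protos, fsin, cap):
    """Deterministic simulations of all seven protocols, FSIN parameters."""
    return {name: simulate(p, fsin, cap) for name, p in protos.items()}


@pytest.fixture(scope="session")
def olm_sims(protos, olm, cap):
    return {name: simulate(p, olm, cap) for name, p in protos.items()}


@pytest.fixture(scope="session")
def five_protocol_problem(protos, fsin, cap, fsin_sims):
    """Noise-free five-simple-protocol fit problem with FSIN-generated data."""
    names = SIMPLE_FIT_PROTOCOLS
    return FitProblem(
        datasets={n: fsin_sims[n].quanta for n in names},
        protocols={n: protos[n] for n in names},
        base_params=fsin,
        cap=cap,
    )
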