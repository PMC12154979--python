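import numpy as np
import pytest

from pbdmelt import CrowderConfig, ModelParams, parse_duplex
from pbdmelt.crowders import effective_depths


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_params():
    """Reduced 60-node grid: exact same physics, cheap brute-force oracles."""
    return ModelParams(n_grid=60)


@pytest.fixture(scope="session")
def chain_a():
    return parse_duplex("GGGAGAAG", label="chain-A")


@pytest.fixture(scope="session")
def chain_b():
    return parse_duplex("GGAAGAGG", label="chain-B")


def free_depths(duplex, params):
    """Crowder-free per-site Morse depths."""
    return effective_depths(duplex, CrowderConfig(), params)
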