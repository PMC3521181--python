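import numpy as np
import pytest

from palseq import (
    SimParams,
    default_amplicon,
    default_construct,
    mmei_digest,
    simulate_library,
)


@pytest.fixture(scope="session")
def construct():
    return default_construct()


@pytest.fixture(scope="session")
def amplicon():
    return default_amplicon()


@pytest.fixture(scope="session")
def tag1_templates_10k(amplicon):
    """10,000 canonical (zero-jitter) templates copying the Tag1-led strand."""
    return mmei_digest(amplicon, {0: 1.0}, rng_seed=101, n=10_000, both_strands=False)


@pytest.fixture(scope="session")
def default_library(tag1_templates_10k):
    """Default-parameter simulation of the palindromic library (10^4 reads)."""
    params = SimParams(seed=11)
    return simulate_library(params, tag1_templates_10k), params


@pytest.fixture(scope="session")
def noblock_library(amplicon):
    """Blocking-disabled control library over both strands, zero jitter."""
    templates = mmei_digest(amplicon, {0: 1.0}, rng_seed=202, n=2_000, both_strands=True)
    params = SimParams(blocking_enabled=False, seed=12)
    return simulate_library(params, templates), templates
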