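"""Shared fixtures: one simulated pangenome reused across the suite."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from panfam import (
    SimConfig,
    simulate_expression,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def truth(default_config):
    """The reference simulated pangenome: 10 genomes, 50 base OGGs, seed 7."""
    return simulate_pangenome(default_config)


@pytest.fixture(scope="session")
def expression(truth):
    return simulate_expression(truth, seed=11, noise_sd=0.2)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, truth, expression):
    """The simulated study written to disk once for IO/pipeline tests."""
    from panfam import write_pangenome

    out = tmp_path_factory.mktemp("sim")
    write_pangenome(truth, out, expression=expression)
    return out
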