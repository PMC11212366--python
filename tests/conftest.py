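import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from introscape import simulate
from introscape.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=3,
        chromosome_lengths=[200_000],
        tract_count=3,
        tract_length_distribution={"mu": 9.0, "sigma": 0.4},
        gene_count=20,
        gene_length_distribution={"mu": 7.0, "sigma": 0.4},
        family_gene_count=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture(scope="session")
def fitted_small(small_study):
    """A 5-restart HMM fit of the small study (shared: it is expensive)."""
    from introscape import hmm

    return hmm.fit(small_study.alignments[0], n_restarts=5, seed=1, max_iter=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
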