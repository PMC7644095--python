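import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from flysleep import ArborSimParams, ExperimentDesign, SleepSimParams, generate_arbor


@pytest.fixture
def rng():
    return np.random.default_rng(20210101)


@pytest.fixture
def design_zt12():
    """12:12 LD recording of 2 cycles, starvation starting at ZT12 of day 0."""
    return ExperimentDesign(starvation_start_zt=12.0)


@pytest.fixture
def sim_params():
    return SleepSimParams(seed=7)


def random_arbor(seed: int, sigma: float = 25.0, n_branches: int = 5) -> "Skeleton":
    """A moderately wiggly test arbor long enough to cross every default ring."""
    return generate_arbor(ArborSimParams(
        n_branches=n_branches, spread_sigma_deg=sigma, branch_len_um=160.0,
        wiggle_deg=2.0, step_um=1.0, seed=seed,
    ))
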