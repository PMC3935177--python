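import numpy as np
import pytest

from npars.dag import phenotype, snp, transcript
from npars.simulate import ScenarioSpec, simulate_scenario


@pytest.fixture
def triplet_nodes():
    return [snp("L"), transcript("E"), phenotype("D")]


@pytest.fixture
def five_nodes():
    return [snp("L1"), snp("L2"), transcript("E1"), transcript("E2"),
            phenotype("D")]


@pytest.fixture
def scenario1_small():
    """One scenario-1 draw at a strong effect, small n (fast)."""
    return simulate_scenario(ScenarioSpec(1, 1.2, 150, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
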