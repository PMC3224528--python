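import numpy as np
import pytest

from regraft.simulate import SimulationConfig, simulate_hgt_dataset
from regraft.substmodel import SubstitutionModel


@pytest.fixture(scope="session")
def wag():
    return SubstitutionModel.wag()


@pytest.fixture(scope="session")
def wag_ig():
    return SubstitutionModel.wag(alpha=0.8, p_inv=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def hgt_fixture():
    """One deterministic 56-taxon / 327-site synthetic HGT dataset."""
    cfg = SimulationConfig(seed=42)
    aln, tree, truth = simulate_hgt_dataset(cfg)
    return cfg, aln, tree, truth
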