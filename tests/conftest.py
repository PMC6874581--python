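import numpy as np
import pytest

from coreflow import pipeline, synthetic
from coreflow.mie_sizing import MieModel


@pytest.fixture(scope="session")
def sim3():
    """Small ground-truthed cruise shared across tests (3 files)."""
    return synthetic.simulate_cruise(synthetic.default_config(seed=42, n_files=3))


@pytest.fixture(scope="session")
def processed3(sim3):
    """Full pipeline result on the shared cruise."""
    return pipeline.process_cruise(sim3.events, sim3.metadata, sim3.bead_table,
                                   sim3.gating_spec, seed=0)


@pytest.fixture(scope="session")
def mie_model():
    return MieModel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
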