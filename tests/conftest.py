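import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from ensdyn import synth


@pytest.fixture(scope="session")
def toy_spec():
    return synth.ToyComplexSpec(n_protein_nodes=20, n_dna_nodes=4)


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return synth.build_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_nodes(toy_spec):
    return synth.toy_selection(toy_spec)


@pytest.fixture(scope="session")
def anm_ensemble(toy_model, toy_nodes):
    """Moderate-size ANM Gaussian ensemble with its analytic ground truth."""
    ens, truth = synth.sample_anm_ensemble(
        toy_model, n_frames=2000, temperature_scale=0.4, seed=7,
        selection=toy_nodes,
    )
    return ens, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
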