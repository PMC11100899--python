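import numpy as np
import pytest

from nfpscreen import datapipe, synthdata


@pytest.fixture(scope="session")
def small_table():
    """300-molecule synthetic score table shared across tests."""
    cfg = synthdata.SynthConfig(n_molecules=300, seed=123)
    smiles = synthdata.generate_molecules(cfg)
    return synthdata.assign_energies(smiles, cfg), cfg


@pytest.fixture(scope="session")
def small_dataset(small_table):
    pairs, _ = small_table
    return datapipe.prepare_dataset(pairs, hit_fraction=0.20, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
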