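import numpy as np
import pytest

from costructure.dtw import build_distance_table
from costructure.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def coupled_dataset():
    """Small strongly-coupled dataset shared across test modules."""
    return generate_dataset(
        SynthConfig(n_performers=3, motifs_per_performer=8, coupling=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def coupled_table(coupled_dataset):
    ds = coupled_dataset
    return build_distance_table(ds.sonic, ds.kinematic, ds.motif_frame())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
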