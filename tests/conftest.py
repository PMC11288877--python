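import numpy as np
import pytest

from errpsim import headmodel, simulator


@pytest.fixture(scope="session")
def leadfield():
    """Shared small spherical lead field (2000 sources, BioSemi-64)."""
    return headmodel.build_spherical_leadfield(
        simulator.biosemi64_labels(), n_sources=2000, seed=0
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale simulation config for fast unit tests."""
    return simulator.SimConfig(
        n_epochs=60, n_train_subjects=2, n_val_subjects=2,
        n_leadfield_sources=2000, master_seed=0,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_config, leadfield):
    return simulator.simulate_subject(tiny_config, leadfield, 123, subject_id="tiny")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
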