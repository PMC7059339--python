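"""Shared fixtures: synthetic datasets and a trained coding-potential model.

Session scope keeps dataset generation and model training to one pass for
the whole suite.
"""

import numpy as np
import pytest

from saltlnc import coding_potential, synthetic_data
from saltlnc.synthetic_data import SimulationConfig


SMALL_CONFIG_KWARGS = dict(
    n_chromosomes=2,
    chromosome_length=600_000,
    n_coding_genes=120,
    n_antisense=10,
    n_intergenic=16,
    n_junk=10,
    n_de_genes=36,
    n_de_lncrnas=18,
    n_cis_pairs=5,
    n_mirnas=6,
    n_mirna_sites=8,
    n_decoy_sites=4,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale dataset at the generator's default study conditions."""
    return synthetic_data.generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced dataset for cheap structural checks."""
    return synthetic_data.generate_dataset(SimulationConfig(seed=7, **SMALL_CONFIG_KWARGS))


@pytest.fixture(scope="session")
def codepot_model():
    return coding_potential.train_default_model(seed=999)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
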