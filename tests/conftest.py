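"""Shared fixtures: tiny synthetic datasets and a small trained model."""

import numpy as np
import pytest

import genecaps as gc


@pytest.fixture(scope="session")
def tiny_spec():
    """60 genes, 8-gene modules, 12 subjects x 5 cells: seconds to train."""
    return gc.SyntheticSpec(
        n_genes=60,
        modules=gc.default_modules(n_genes=60, module_size=8),
        n_subjects_case=6, n_subjects_control=6,
        cells_per_subject=5, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    ds, modules = gc.generate_single_cell(tiny_spec)
    return ds


@pytest.fixture(scope="session")
def tiny_config():
    return gc.TrainConfig(epochs=4, seed=11, n_primary=2, n_capsules=4,
                          d_primary=4, d_capsule=4, n_heads=2, n_hidden=12)


@pytest.fixture(scope="session")
def tiny_checkpoint(tiny_dataset, tiny_config):
    tr, va, te = gc.split_cells(tiny_dataset, seed=11)
    return gc.train(tr, va, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
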