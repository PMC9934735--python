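"""Shared fixtures: small network configs, templates, and the two trained
toy models used by the recovery tests (built once per session)."""

import numpy as np
import pytest

from gcdiff.denoiser import DenoiserConfig, DenoiserNetwork
from gcdiff.diffusion import make_schedule
from gcdiff.fixtures import make_templates, sample_dataset, toy_bond_table
from gcdiff.model import GCDM

TOY_T = 500
TOY_LAYERS = 4
TOY_DIM = 64


def small_config(**kw):
    base = dict(n_layers=3, node_scalar_dim=32, node_vector_channels=8,
                edge_scalar_dim=16, edge_vector_channels=8)
    base.update(kw)
    return DenoiserConfig(**base)


@pytest.fixture(scope="session")
def templates():
    return make_templates()


@pytest.fixture(scope="session")
def toy_table():
    return toy_bond_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_net():
    """Untrained network with generic (non-zero) output heads."""
    return DenoiserNetwork(small_config(zero_init_output=False), seed=1)


@pytest.fixture(scope="session")
def toy_dataset():
    return sample_dataset(n=2000, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def trained_model(toy_dataset):
    """Unconditional 4-layer/64-dim model trained on the fixture set."""
    cfg = DenoiserConfig(n_layers=TOY_LAYERS, node_scalar_dim=TOY_DIM,
                         node_vector_channels=8, edge_scalar_dim=16,
                         edge_vector_channels=8)
    model = GCDM(cfg, schedule=make_schedule("polynomial", TOY_T), seed=0)
    model.fit(toy_dataset, epochs=100, batch_size=64, lr=1e-3, seed=0)
    return model


@pytest.fixture(scope="session")
def conditional_model(toy_dataset):
    """Model conditioned on the radius-of-gyration toy property."""
    cfg = DenoiserConfig(n_layers=TOY_LAYERS, node_scalar_dim=TOY_DIM,
                         node_vector_channels=8, edge_scalar_dim=16,
                         edge_vector_channels=8, condition_dim=1)
    model = GCDM(cfg, schedule=make_schedule("polynomial", TOY_T), seed=1)
    model.fit(toy_dataset, epochs=100, batch_size=64, lr=1e-3,
              condition="radius_of_gyration", seed=1)
    return model
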