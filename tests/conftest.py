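"""Shared fixtures: tiny datasets and a small trained autoencoder.

Everything is generated programmatically; the autoencoder fixture is
session-scoped because several modules exercise the encode/decode path.
"""

from __future__ import annotations

import numpy as np
import pytest

from histosynth.synthetic import generate_dataset
from histosynth.vqgan import desk_vqgan_config, train_vqgan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """24 labeled tiles (3 distinct phenotypes, size 16)."""
    return generate_dataset(3, 8, size=16, seed=0, preset_indices=[0, 6, 2])


@pytest.fixture(scope="session")
def tiny_vqgan_config():
    return desk_vqgan_config(
        codebook_size=16,
        codebook_dim=4,
        base_channels=8,
        epochs=3,
        batch_size=8,
        disc_warmup_steps=4,
        extractor_channels=(4, 8),
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_vqgan(tiny_dataset, tiny_vqgan_config):
    """A briefly trained autoencoder plus its discriminator and loss history."""
    model, disc, history = train_vqgan(tiny_dataset, tiny_vqgan_config)
    return model, disc, history
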