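"""Shared fixtures.

The heavy session fixture trains, for three seeds, the desk-scale
segmentation cascade (on high-contrast phantom renderings) and the
cross-modality translation network (on unpaired phantoms); the
end-to-end recovery and indirect-vs-direct tests share these models.
"""

from __future__ import annotations

import numpy as np
import pytest

from cascadegan.config import TrainConfig
from cascadegan.losses import LossConfig
from cascadegan.phantom import PhantomParams, make_dataset
from cascadegan.segmentation import train_segmentation
from cascadegan.translation import train_translation

STUDY_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def tiny_params():
    return PhantomParams.for_size(32)


@pytest.fixture(scope="session")
def train_samples(phantom_params):
    """200 labelled phantoms (the segmentation training pool)."""
    return make_dataset(phantom_params, 200, seed=11, paired=True).samples_a


@pytest.fixture(scope="session")
def heldout_samples(phantom_params):
    """50 held-out paired phantoms for evaluation."""
    return make_dataset(phantom_params, 50, seed=977, paired=True).samples_a


@pytest.fixture(scope="session")
def unpaired_pool(phantom_params):
    """60 unpaired anatomies per modality (translation training pool)."""
    return make_dataset(phantom_params, 60, seed=55, paired=False)


@pytest.fixture(scope="session")
def seg_loss_config():
    return LossConfig(gan_mode="lsgan", perceptual_mode="manh",
                      omega_g=(0.5, 0.5), omega_1=(0.5, 0.5))


@pytest.fixture(scope="session")
def trained_seg_models(train_samples, seg_loss_config):
    """Desk-scale segmentation cascades (n=2, U-net), one per study seed."""
    pairs = [(s.image_B, s.mask) for s in train_samples]
    models = {}
    for seed in STUDY_SEEDS:
        models[seed] = train_segmentation(
            pairs, seg_loss_config,
            TrainConfig(epochs=3, lr=1e-3, seed=seed),
            first_depth=4)
    return models


@pytest.fixture(scope="session")
def trained_translation_models(unpaired_pool):
    """Desk-scale cycle-consistency translation models, one per seed."""
    da = [s.image_A for s in unpaired_pool.samples_a]
    db = [s.image_B for s in unpaired_pool.samples_b]
    lc = LossConfig(gan_mode="lsgan")
    models = {}
    for seed in STUDY_SEEDS:
        models[seed] = train_translation(
            da, db, lc, TrainConfig(epochs=6, lr=1e-3, seed=seed))
    return models
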