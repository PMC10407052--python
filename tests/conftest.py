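"""Shared fixtures: toy images, backbones, and planted activation datasets.

Heavy objects are session-scoped so the full suite builds each of them once.
All randomness is seeded; the fixtures are deterministic across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from numsense import (
    gen_activation_dataset, gen_image_dataset, normalize_unit_range,
    train_mock_backbone, untrained_backbone,
)
from numsense.config import SynthActivationConfig


@pytest.fixture(scope="session")
def toy_images():
    images, labels = gen_image_dataset(10, 30, image_size=64, seed=3)
    return images, labels


@pytest.fixture(scope="session")
def backbone(toy_images):
    images, labels = toy_images
    return train_mock_backbone(images, labels, epochs=30, seed=3, input_size=48,
                               n_augment=4, scale_range=(0.2, 1.0))


@pytest.fixture(scope="session")
def random_backbone():
    return untrained_backbone(10, input_size=48, seed=3)


@pytest.fixture(scope="session")
def planted_small():
    """Small planted dataset: 100 units (15 up / 5 down), 200 pictures/group."""
    cfg = SynthActivationConfig(n_units=100, n_pictures_per_group=200,
                                n_increasing=15, n_decreasing=5,
                                slope_mean=0.05, sigma_scale=0.9, seed=21)
    return gen_activation_dataset(cfg)


@pytest.fixture(scope="session")
def planted_small_norm(planted_small):
    return normalize_unit_range(planted_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_acts(rng, n_pictures=20, n_units=12, groups=None):
    """Helper: a random ActivationMatrix for oracle tests."""
    from numsense.activations import ActivationMatrix

    values = rng.random((n_pictures, n_units))
    if groups is None:
        groups = rng.integers(1, 4, n_pictures)
    meta = pd.DataFrame({"picture_id": np.arange(n_pictures), "group": groups})
    return ActivationMatrix(values=values, meta=meta)
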