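"""Shared fixtures: phantom cohorts and the (expensive) trained desk model.

The trained model and the cohort are session-scoped so the training run and
cohort generation happen once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from caaseg.commissioning import build_cohort
from caaseg.phantom import PhantomSpec, generate_thorax_phantom
from caaseg.segmenter import (
    DESK_CROP_SIZE,
    ModelConfig,
    TrainConfig,
    prepare_case,
    train,
)

#: Study conditions for the training sanity check: 20 desk phantoms, fixed seed.
TRAIN_COHORT_SEEDS = tuple(range(100, 120))
TRAIN_SEED = 0


@pytest.fixture(scope="session")
def desk_training_data():
    """Preprocessed (input tensor, label map) pairs for 20 desk phantoms."""
    data = []
    for s in TRAIN_COHORT_SEEDS:
        ct, truth = generate_thorax_phantom(PhantomSpec.desk(seed=s))
        x, y, _ = prepare_case(ct, truth.to_label_map(), crop_size=DESK_CROP_SIZE)
        data.append((x, y))
    return data


@pytest.fixture(scope="session")
def trained_desk_model(desk_training_data):
    """Desk-profile UNet trained once per session; returns (model, history)."""
    return train(desk_training_data, ModelConfig.desk(), TrainConfig.desk(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def phantom_cohort(tmp_path_factory):
    """10-case desk phantom cohort with 3 simulated observers each."""
    cohort = tmp_path_factory.mktemp("cohort")
    build_cohort(cohort, 10, seed=7)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape, n_seeds=3):
    """Random connected-ish blob mask for metric oracle tests."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        centre = [rng.integers(0, s) for s in shape]
        radius = rng.integers(2, max(3, min(shape) // 2))
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        mask |= dist2 <= radius**2
    if rng.random() < 0.5:
        mask = ndimage.binary_dilation(mask, iterations=1)
    return mask.astype(np.uint8)
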