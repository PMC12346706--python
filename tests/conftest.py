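"""Shared fixtures: synthetic datasets and models at the tiny test scale.

The expensive fixtures (a trained tiny model, the full-size model) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import lesionbag as lb


@pytest.fixture(scope="session")
def tiny_dataset():
    """300-image synthetic set at 57 px (100/class, 60/20/20 split)."""
    return lb.generate_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def tiny_model():
    """Untrained tiny model with a fixed seed (read-only: do not train)."""
    return lb.build_model(lb.TINY_MODEL_CONFIG, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """300-image synthetic set at 105 px (13x13 feature grid), dense
    enough that masking 20 of the 169 candidate windows removes ~12% of
    the grid — the regime the occlusion analyses are about."""
    return lb.generate_fixture("small", seed=0)


@pytest.fixture(scope="session")
def trained(small_dataset):
    """A small (105-px) model trained for 20 epochs with PSAM, plus its
    history. This is the single expensive fixture; the end-to-end
    accuracy, occlusion and heatmap-fidelity tests all share it."""
    model = lb.build_model(lb.SMALL_MODEL_CONFIG, seed=0)
    config = lb.TrainConfig(epochs=20, optimizer="psam", seed=0)
    history = lb.train(
        model, small_dataset.subset("train"), config,
        val_set=small_dataset.subset("val"),
    )
    return model, history, small_dataset


@pytest.fixture(scope="session")
def full_model():
    """The full-size (225 px / 2048-channel) model, randomly initialized."""
    return lb.build_model(lb.FULL_MODEL_CONFIG, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
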