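"""Shared fixtures: synthetic datasets and one trained model per session.

Everything is generated programmatically and seeded; nothing is read from
disk.  The trained model is shared across the tests that need a
converged classifier (classification accuracy, embeddings, Grad-CAM) to
keep the suite within a desk-scale runtime.
"""

import numpy as np
import pytest

from cbgm.model import CBGMModel, ModelConfig
from cbgm.synthetic_ecg import SynthConfig, make_classification_fixture
from cbgm.training import TrainConfig, split, train


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 5 x 40 segment dataset with default noise."""
    ds, _ = make_classification_fixture(40, SynthConfig(seed=11))
    return ds


@pytest.fixture(scope="session")
def fixture_200():
    """The acceptance-scale fixture: 200 pulses per class, default noise."""
    ds, _ = make_classification_fixture(200, SynthConfig(seed=7))
    return ds


@pytest.fixture(scope="session")
def trained_model(fixture_200):
    """A model trained on the 7:3 split of the 1000-pulse fixture.

    Capped at 15 epochs (early stopping on validation accuracy).
    Returns (model, train_set, test_set, history).
    """
    tr, te = split(fixture_200, 0.7, seed=7)
    model = CBGMModel(ModelConfig(), seed=7)
    cfg = TrainConfig(max_epochs=15, early_stopping_patience=3, seed=7)
    _, hist = train(model, tr, te, cfg)
    return model, tr, te, hist


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
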