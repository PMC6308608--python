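"""Shared fixtures: small synthetic datasets and quickly trained models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ttcoach import lstm_core as lc
from ttcoach import synthetic_imu as si
from ttcoach.dataio import apply_scaler, fit_scaler


@pytest.fixture(scope="session")
def default_dataset():
    """The full 2x5x10 benchmark design at its default style settings."""
    return si.synth_dataset(si.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced 2x5x4 design for fast training tests."""
    return si.synth_dataset(
        si.GeneratorConfig(seed=5, reps_per_cell=4, train_reps=3)
    )


@pytest.fixture(scope="session")
def small_scaled(small_dataset):
    train = small_dataset.subset("train")
    test = small_dataset.subset("test")
    sp = fit_scaler(train)
    return apply_scaler(sp, train), apply_scaler(sp, test), sp


@pytest.fixture(scope="session")
def tiny_classifier(small_scaled):
    """A small bidirectional model trained briefly; shared across tests that
    need *a* trained classifier rather than an accurate one."""
    train, test, _ = small_scaled
    cfg = lc.TrainConfig(epochs=30, seed=3, batch_size=10)
    params, curves = lc.train_classifier(train, cfg, direction="bi", hidden=8)
    return params, curves, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
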