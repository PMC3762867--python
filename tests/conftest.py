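"""Shared fixtures: one default synthetic session, preprocessed and
categorized, reused across test modules to keep the suite fast."""
from __future__ import annotations

import numpy as np
import pytest

from mcgurk_ecog import SimConfig, simulate_dataset
from mcgurk_ecog.experiment import categorize_trials, select_electrodes
from mcgurk_ecog.workflows import preprocess_epochs


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_session(default_cfg):
    """(cfg, categorized trials, preprocessed epochs) for the default
    study conditions."""
    trials, epochs = simulate_dataset(default_cfg)
    epochs = preprocess_epochs(epochs)
    trials = categorize_trials(trials)
    return default_cfg, trials, epochs


@pytest.fixture(scope="session")
def default_selection(default_session):
    _, _, epochs = default_session
    return select_electrodes(epochs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
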