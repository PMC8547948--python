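"""Shared fixtures: one moderately sized synthetic trial and its derived
products, simulated once per session so individual tests stay fast."""

from __future__ import annotations

import numpy as np
import pytest

import echokin as ek
from echokin.click_buzz import ClickTrain


@pytest.fixture(scope="session")
def default_config() -> ek.SimConfig:
    return ek.SimConfig(seed=101)


@pytest.fixture(scope="session")
def default_trial(default_config) -> ek.TrialBundle:
    return ek.simulate_trial(default_config)


@pytest.fixture(scope="session")
def detected_train(default_trial) -> ClickTrain:
    return ek.detect_clicks(default_trial.audio, preset="pp")


@pytest.fixture(scope="session")
def default_echogram(default_trial, detected_train) -> ek.Echogram:
    return ek.form_echogram(
        default_trial.audio, detected_train, preset="pp", max_range=5.0
    )


@pytest.fixture(scope="session")
def null_trial() -> ek.TrialBundle:
    return ek.simulate_null_trial(ek.SimConfig(seed=202))


def make_train(times) -> ClickTrain:
    return ClickTrain(times=np.asarray(times, dtype=np.float64))


def train_from_ici(ici, t0: float = 0.0) -> ClickTrain:
    """Build a train whose forward ICI sequence is exactly ``ici``."""
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(ici, float))])
    return ClickTrain(times=times)
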