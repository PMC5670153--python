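"""Shared fixtures: small, fast configurations and cached trained networks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import msinet as M


@pytest.fixture(scope="session")
def default_config() -> M.ModelConfig:
    return M.ModelConfig()


@pytest.fixture(scope="session")
def noiseless_config(default_config) -> M.ModelConfig:
    stim = dataclasses.replace(default_config.stimulus, noise_amplitude=0.0)
    return dataclasses.replace(default_config, stimulus=stim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def untrained_network(default_config) -> M.Network:
    return M.build_network(default_config)


@pytest.fixture(scope="session")
def short_td_training(default_config):
    """A short typical-development training run shared across tests.

    600 exposures: long enough for measurable synaptic growth, short enough
    for the test suite.
    """
    schedule = M.make_schedule("TD", total_epochs=600)
    result = M.train(
        default_config, schedule, checkpoints=[0, 300, 600], rng=np.random.default_rng(7)
    )
    return result
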