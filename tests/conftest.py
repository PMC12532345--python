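"""Shared fixtures: small, fast simulator configurations.

Everything is generated programmatically; heavier artifacts (a converged
agent) are session-scoped so the expensive work runs once.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from octfocus import SystemParams, make_phantom
from octfocus.agent import AgentConfig, DDPGAgent, train
from octfocus.environment import SimulatedOCTEnv


@pytest.fixture(scope="session")
def params() -> SystemParams:
    # 32 lateral columns keep rendering cheap; the lateral mean is what all
    # downstream stages consume
    return replace(SystemParams(), n_lateral_ascans=32)


@pytest.fixture(scope="session")
def full_params() -> SystemParams:
    """Default geometry (full lateral width), used by session-level tests."""
    return SystemParams()


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def foveal_phantom():
    return make_phantom(foveal=True)


@pytest.fixture(scope="session")
def quiet_params(params) -> SystemParams:
    """Noise-free variant for exact-arithmetic checks."""
    return replace(params, noise_floor_sigma=0.0)


@pytest.fixture(scope="session")
def tiny_agent(params) -> DDPGAgent:
    """A structurally complete but untrained (beyond a few steps) agent for
    mechanics tests."""
    cfg = AgentConfig.desk(train_steps=3, rng_seed=5, buffer_capacity=200,
                           batch_size=8, n_noise_profiles_per_step=2)
    return DDPGAgent(cfg, params.n_depth_pixels)


@pytest.fixture(scope="session")
def converged_agent(params, phantom) -> DDPGAgent:
    """Agent trained to convergence under the in-silico study conditions.

    Shared across the evaluation-grade tests; the training run is the same
    desk-scale configuration the acceptance script uses.
    """
    cfg = AgentConfig.desk(rng_seed=0)
    agent = DDPGAgent(cfg, params.n_depth_pixels)
    env = SimulatedOCTEnv(phantom, params, rng=10)
    train(agent, env)
    return agent
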