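"""Shared fixtures: simulated sessions are expensive, so the main ones are
built once per test session and reused read-only."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneegait.pipeline import analyze_session
from kneegait.sim import GaitParams, ProtocolParams, simulate_activity_session

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def walk_params() -> GaitParams:
    # cadence 120 at 100 Hz puts the swing-peak phase exactly on the grid
    return GaitParams(cadence=120.0, step_length=0.75)


@pytest.fixture(scope="session")
def walk_session(walk_params):
    """100-m walk session with default noise, plus its ground truth."""
    protocol = ProtocolParams(walk=walk_params)
    return simulate_activity_session(protocol, ["walk"], seed=1)


@pytest.fixture(scope="session")
def walk_analysis(walk_session):
    session, _ = walk_session
    return analyze_session(session)


@pytest.fixture(scope="session")
def mini_protocol():
    """tug + walk + stairs session exercising every detector, with truth."""
    protocol = ProtocolParams(
        walk=GaitParams(cadence=114.0, step_length=60 * 1.5 / 114),
        stair_flights=1,
        tug_repetitions=1,
        walk_path_length=60.0,
    )
    return protocol, *simulate_activity_session(
        protocol, ["tug", "walk", "stairs_up", "stairs_down"], seed=11
    )


@pytest.fixture(scope="session")
def mini_analysis(mini_protocol):
    _, session, _ = mini_protocol
    return analyze_session(session)


@pytest.fixture(scope="session")
def quiet_params() -> GaitParams:
    """Noise-free, bias-free sensing for closed-form comparisons."""
    return GaitParams(
        cadence=120.0, step_length=0.75,
        noise_sd_accel=0.0, noise_sd_gyro=0.0, noise_sd_mag=0.0, gyro_bias=0.0,
    )


@pytest.fixture(scope="session")
def quiet_walk_session(quiet_params):
    protocol = ProtocolParams(walk=quiet_params)
    return simulate_activity_session(protocol, ["walk"], seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
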