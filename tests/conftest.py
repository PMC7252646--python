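"""Shared fixtures: scenario pipelines run once per session."""

from __future__ import annotations

import numpy as np
import pytest

import eigenlock as el


def run_scenario(name: str, step: int = 1, seed: int = 1):
    """Scenario -> binary network series on the scripted angular speeds."""
    script = el.build_scenario(name)
    traj = el.simulate_phase_network(script, seed=seed)
    window = el.WindowSpec(width=40, step=step, fs=script.fs)
    distances = el.windowed_plv_distance(traj.speeds.T, window)
    networks = el.binarize(distances, el.DEFAULT_THRESHOLD)
    return script, traj, networks


@pytest.fixture(scope="session")
def scenario1_run():
    return run_scenario("scenario1")


@pytest.fixture(scope="session")
def scenario2_run():
    return run_scenario("scenario2")


@pytest.fixture(scope="session")
def benchmark_run():
    return run_scenario("benchmark")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n, p=0.3):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    return a + a.T
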