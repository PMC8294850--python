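"""Shared fixtures: the default maze and event-train generators."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erf

from treemaze.insight import EventTrain
from treemaze.maze import MazeConfig, build_maze


@pytest.fixture(scope="session")
def maze():
    return build_maze(MazeConfig())


@pytest.fixture(scope="session")
def small_maze():
    return build_maze(MazeConfig(n_junction_levels=2))


def make_step_train(rng: np.random.Generator, ri: float = 0.002,
                    rf: float = 0.02, ts: float = 2000.0,
                    T: float = 1e4) -> EventTrain:
    """Inhomogeneous Poisson train with a sudden rate step at ts."""
    n1 = rng.poisson(ri * ts)
    n2 = rng.poisson(rf * (T - ts))
    times = np.concatenate([rng.uniform(0, ts, n1), rng.uniform(ts, T, n2)])
    return EventTrain(times, T)


def make_sigmoid_train(rng: np.random.Generator, ri: float = 0.002,
                       rf: float = 0.02, ts: float = 5000.0,
                       w: float = 1500.0, T: float = 1e4) -> EventTrain:
    """Poisson train with a sigmoidal rate rise (thinning sampler)."""
    rmax = max(ri, rf)
    n = rng.poisson(rmax * T)
    cand = rng.uniform(0, T, n)
    r = ri + (rf - ri) * 0.5 * (1.0 + erf((cand - ts) / w))
    keep = rng.uniform(0, rmax, n) < r
    return EventTrain(cand[keep], T)
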