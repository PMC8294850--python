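"""Discovery curves, efficiency, and end-node preference statistics."""

import numpy as np
import pytest

from treemaze.agents import AgentPolicy, simulate
from treemaze.biases import BiasSet
from treemaze.exploration import (DiscoveryCurve, EfficiencyUndefined,
                                  _model, _window_distinct_sums,
                                  discovery_curve, endnode_occupancy,
                                  endnode_visit_clips, fit_discovery,
                                  n32_efficiency, outer_inner_ratio,
                                  split_half_efficiency, variance_explained)
from treemaze.maze import classify_rings
from treemaze.reduction import NodeSequence


def test_window_sums_match_brute_force():
    rng = np.random.default_rng(0)
    v = rng.integers(0, 12, 300)
    for n in (1, 3, 10, 47, 299, 300):
        brute = sum(len(set(v[t:t + n])) for t in range(len(v) - n + 1))
        s, w = _window_distinct_sums(v, np.array([n]))
        assert s[0] == brute
        assert w[0] == len(v) - n + 1


def test_discovery_curve_invariants():
    rng = np.random.default_rng(1)
    clips = [rng.integers(63, 127, 400), rng.integers(63, 127, 250)]
    c = discovery_curve(clips, n_max=200)
    assert c.d[0] == pytest.approx(1.0)
    assert np.all(np.diff(c.d) >= -1e-9)           # nondecreasing
    assert np.all(c.d <= np.minimum(c.n, 64) + 1e-9)


def test_repeating_single_leaf():
    c = discovery_curve([np.full(100, 70)], n_max=50)
    assert np.all(c.d == 1.0)
    with pytest.raises(EfficiencyUndefined):
        n32_efficiency(c)


def test_optimal_sequence_efficiency_one():
    seq = np.concatenate([np.random.default_rng(2).permutation(64) + 63
                          for _ in range(3)])
    c = discovery_curve([seq], stop_past=33.0)
    assert n32_efficiency(c) == pytest.approx(1.0)


def test_n32_interpolation_brackets_brute_force():
    rng = np.random.default_rng(3)
    sess = simulate(AgentPolicy("unbiased"),
                    _maze(), 40_000, seed=4)
    clips = endnode_visit_clips(sess.seq, _maze())
    c = discovery_curve(clips, stop_past=33.0)
    E = n32_efficiency(c)
    n32 = 32.0 / E
    # smallest window whose mean distinct count reaches 32
    k = int(np.argmax(c.d >= 32))
    assert abs(n32 - c.n[k]) <= 1.0


def _maze():
    from treemaze.maze import build_maze
    return build_maze()


def test_fit_self_consistency():
    n = np.arange(1, 260)
    d = _model(n.astype(float), 80.0, 0.1, 64)
    fit = fit_discovery(DiscoveryCurve(n, d, np.ones_like(n), 64))
    assert fit.a == pytest.approx(80.0, rel=0.01)
    assert fit.b == pytest.approx(0.1, rel=0.01)
    assert fit.E == pytest.approx(32.0 / 80.0, rel=0.01)


def test_fit_on_simulated_walk(maze):
    sess = simulate(AgentPolicy("unbiased"), maze, 80_000, seed=5)
    clips = endnode_visit_clips(sess.seq, maze)
    c = discovery_curve(clips, n_max=400)
    fit = fit_discovery(c)
    # fitted half-coverage point agrees with the interpolated one
    assert fit.E == pytest.approx(n32_efficiency(c), rel=0.15)
    assert fit.b < 1.0
    assert fit.rmse < 1.5


def test_split_half_stationary_ratio_near_one(maze):
    sess = simulate(AgentPolicy("four_bias",
                                biases=BiasSet(0.85, 0.55, 0.90, 0.60)),
                    maze, 120_000, seed=6)
    E1, E2, ratio = split_half_efficiency(sess.seq, maze)
    assert ratio == pytest.approx(1.0, abs=0.15)


def test_split_half_detects_policy_degradation(maze):
    """An agent whose forward biases collapse to the unbiased values in
    the second half of the session explores less efficiently there."""
    from treemaze.reduction import NodeSequence as NS
    good = simulate(AgentPolicy("four_bias",
                                biases=BiasSet(0.85, 0.55, 0.90, 0.60)),
                    maze, 60_000, seed=7)
    bad = simulate(AgentPolicy("unbiased"), maze, 60_000, seed=8)
    nodes = np.concatenate([good.seq.nodes, bad.seq.nodes])
    times = np.concatenate([good.seq.times,
                            good.seq.times[-1] + 1 + bad.seq.times])
    seq = NS(nodes, times)
    _, _, ratio = split_half_efficiency(seq, maze)
    assert ratio < 0.85


def test_occupancy_uniform_and_ratio(maze):
    rng = np.random.default_rng(9)
    visits = np.tile(np.arange(63, 127), 50)
    seq = NodeSequence(visits, np.arange(len(visits), dtype=float))
    occ = endnode_occupancy(seq, maze)
    assert occ.sum() == pytest.approx(1.0)
    assert outer_inner_ratio(occ, maze) == pytest.approx(1.0)
    assert variance_explained(occ, occ) == 1.0


def test_forward_biased_agent_prefers_outer_ring(maze):
    sess = simulate(AgentPolicy("four_bias",
                                biases=BiasSet(0.85, 0.55, 0.90, 0.60)),
                    maze, 400_000, seed=10)
    occ = endnode_occupancy(sess.seq, maze)
    ratio = outer_inner_ratio(occ, maze)
    assert ratio > 1.0
    # the four-bias structure explains most of an independent replicate
    sess2 = simulate(AgentPolicy("four_bias",
                                 biases=BiasSet(0.85, 0.55, 0.90, 0.60)),
                     maze, 400_000, seed=11)
    occ2 = endnode_occupancy(sess2.seq, maze)
    assert variance_explained(occ, occ2) > 0.5
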