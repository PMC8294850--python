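"""Inhomogeneous-Poisson changepoint fitting and classification."""

import numpy as np
import pytest

from conftest import make_sigmoid_train, make_step_train
from treemaze.insight import (EventTrain, classify_sudden, fit_sigmoid,
                              fit_step, loglik_sigmoid, loglik_step,
                              long_path_event_train, width_evidence,
                              SigmoidRateFit, StepRateFit)


def test_event_train_validation():
    with pytest.raises(ValueError):
        EventTrain(np.array([1.0, 20.0]), T=10.0)
    with pytest.raises(ValueError):
        EventTrain(np.array([1.0]), T=0.0)
    tr = EventTrain(np.array([3.0, 1.0, 2.0]), T=5.0)
    assert list(tr.times) == [1.0, 2.0, 3.0]


def test_constant_rate_closed_form():
    rng = np.random.default_rng(0)
    T, r = 1e4, 0.01
    tr = EventTrain(rng.uniform(0, T, 100), T)
    expected = 100 * np.log(r) - r * T
    assert loglik_step(tr, r, r, 5000.0) == pytest.approx(expected)
    # step at ts = T reduces to a constant-ri model
    assert loglik_step(tr, r, 123.0, T) == pytest.approx(expected)


def test_sigmoid_small_width_matches_step():
    rng = np.random.default_rng(1)
    tr = make_step_train(rng)
    ll_step = loglik_step(tr, 0.002, 0.02, 2000.0)
    ll_sig = loglik_sigmoid(tr, 0.002, 0.02, 2000.0, 1e-4)
    assert ll_sig == pytest.approx(ll_step, abs=1e-6)


def test_zero_rate_gives_minus_infinity():
    tr = EventTrain(np.array([1.0, 2.0]), 10.0)
    assert loglik_step(tr, 0.0, 1.0, 5.0) == -np.inf
    assert loglik_sigmoid(tr, 0.0, 0.0, 5.0, 1.0) == -np.inf


def test_time_translation_invariance():
    rng = np.random.default_rng(2)
    tr = make_step_train(rng)
    shifted = EventTrain(tr.times + 0.0, tr.T)     # same window
    assert loglik_step(shifted, 0.002, 0.02, 2000.0) == \
        pytest.approx(loglik_step(tr, 0.002, 0.02, 2000.0))


def test_step_fit_localizes_jump():
    rng = np.random.default_rng(3)
    errs = []
    for _ in range(20):
        st = fit_step(make_step_train(rng))
        errs.append(abs(st.ts_mean - 2000.0))
        assert st.rf > st.ri
    assert np.median(errs) < 150.0


def test_step_mle_rates_match_counts():
    rng = np.random.default_rng(4)
    tr = make_step_train(rng)
    st = fit_step(tr)
    n1 = int(np.searchsorted(tr.times, st.ts))
    assert st.ri == pytest.approx(n1 / st.ts)
    assert st.rf == pytest.approx((tr.n - n1) / (tr.T - st.ts))


def test_homogeneous_train_broad_profile():
    rng = np.random.default_rng(5)
    tr = EventTrain(rng.uniform(0, 1e4, 120), 1e4)
    st = fit_step(tr)
    assert st.ts_sd > 500.0          # profile close to flat


def test_sigmoid_fit_recovers_null_and_step():
    rng = np.random.default_rng(6)
    # homogeneous: no step, ri ~ rf
    tr = EventTrain(rng.uniform(0, 1e4, 150), 1e4)
    sig = fit_sigmoid(tr)
    assert max(sig.ri, sig.rf) / max(min(sig.ri, sig.rf), 1e-9) < 5.0
    # genuine step: narrow width, ts near truth
    tr = make_step_train(rng)
    sig = fit_sigmoid(tr)
    assert sig.w < 300.0
    assert sig.ts == pytest.approx(2000.0, abs=400.0)


def test_width_evidence_separates_regimes():
    rng = np.random.default_rng(7)
    sudden = [width_evidence(make_step_train(rng)).margin > 0
              for _ in range(12)]
    gradual = [width_evidence(make_sigmoid_train(rng)).margin <= 0
               for _ in range(12)]
    assert sum(sudden) >= 9
    assert sum(gradual) >= 9


def test_classification_thresholds():
    sig = SigmoidRateFit(0.002, 0.02, 2000.0, 100.0, 0.0, True, 1)
    mk = lambda sd: StepRateFit(0.002, 0.02, 2000.0, 2000.0, sd, 0.0,
                                np.empty(0), np.empty(0))
    assert classify_sudden(sig, mk(150.0)) == "sudden"
    assert classify_sudden(sig, mk(950.0)) == "dropped"
    wide = SigmoidRateFit(0.002, 0.02, 2000.0, 1000.0, 0.0, True, 1)
    assert classify_sudden(wide, mk(150.0)) == "gradual"
    with pytest.raises(ValueError):
        classify_sudden(None, mk(150.0))


def test_long_path_train_uses_maze_clock(maze):
    """Event times are measured in cumulative in-maze seconds."""
    from treemaze.maze import shortest_path
    from treemaze.reduction import CAGE, NodeSequence
    w = maze.water_port_leaf
    run = shortest_path(maze, 0, w)
    # one hour in the cage before the run must not shift the event time
    nodes = [CAGE] + run
    times = [0.0] + list(3600.0 + np.arange(len(run), dtype=float))
    seq = NodeSequence(np.array(nodes), np.array(times))
    train = long_path_event_train(seq, maze, w, min_junctions=5)
    assert train.n == 1
    assert train.times[0] == pytest.approx(len(run) - 1)
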