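"""Sudden-insight detection: inhomogeneous-Poisson changepoint fits.

Behavioral event trains (e.g. long direct paths to the water port,
counted on the in-maze clock) are modeled as an inhomogeneous Poisson
process whose rate rises from an initial level ri to a final level rf.
Two rate models are fitted by maximum likelihood,

    sigmoid: r(t) = ri + (rf - ri) * (1 + erf((t - ts)/w)) / 2
    step:    r(t) = ri for t < ts, rf for t > ts

using ln L = sum_i ln r(t_i) - integral_0^T r(t) dt.  A change is
classified "sudden" when the fitted sigmoid width w is below 300 s and
the step-time uncertainty (SD of ts over its normalized likelihood
profile) is below 900 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf

__all__ = ["EventTrain", "SigmoidRateFit", "StepRateFit",
           "loglik_sigmoid", "loglik_step", "fit_sigmoid", "fit_step",
           "classify_sudden", "SUDDEN_WIDTH_S", "STEP_SD_DROP_S"]

SUDDEN_WIDTH_S = 300.0   # sigmoid width below which a change is sudden
STEP_SD_DROP_S = 900.0   # step-time SD above which a candidate is dropped


@dataclass
class EventTrain:
    """Point-event times on an observation interval [0, T]."""

    times: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if self.T <= 0:
            raise ValueError("observation window must have positive length")
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.T):
            raise ValueError("event times outside [0, T]")

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class SigmoidRateFit:
    ri: float
    rf: float
    ts: float
    w: float
    loglik: float
    converged: bool
    n_starts: int


@dataclass
class StepRateFit:
    ri: float
    rf: float
    ts: float                    # maximum-likelihood step time
    ts_mean: float               # mean of ts over the likelihood profile
    ts_sd: float                 # SD of ts over the likelihood profile
    loglik: float
    grid: np.ndarray = field(repr=False)
    profile: np.ndarray = field(repr=False)  # normalized likelihood over grid
    degenerate: bool = False


# ---------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------

def _sigmoid_rate(t, ri, rf, ts, w):
    return ri + (rf - ri) * 0.5 * (1.0 + erf((t - ts) / w))


def _erf_antideriv(x):
    # antiderivative of erf: x*erf(x) + exp(-x^2)/sqrt(pi)
    x = np.asarray(x, dtype=float)
    return x * erf(x) + np.exp(-np.minimum(np.square(x), 700.0)) \
        / math.sqrt(math.pi)


def loglik_sigmoid(train: EventTrain, ri: float, rf: float,
                   ts: float, w: float) -> float:
    """Exact Poisson log-likelihood of the sigmoid rate model.

    The rate integral is evaluated in closed form via the erf
    antiderivative.  Returns -inf when the rate vanishes at an event.
    """
    if ri < 0 or rf < 0 or w <= 0:
        return -np.inf
    r = _sigmoid_rate(train.times, ri, rf, ts, w)
    if np.any(r <= 0):
        return -np.inf
    xs0 = -ts / w
    xs1 = (train.T - ts) / w
    integral = (ri * train.T
                + (rf - ri) * 0.5
                * (train.T + w * (_erf_antideriv(xs1) - _erf_antideriv(xs0))))
    return float(np.log(r).sum() - integral)


def loglik_step(train: EventTrain, ri: float, rf: float, ts: float) -> float:
    """Exact Poisson log-likelihood of the step rate model."""
    if ri < 0 or rf < 0 or not (0 <= ts <= train.T):
        return -np.inf
    n1 = int(np.searchsorted(train.times, ts))
    n2 = train.n - n1
    with np.errstate(divide="ignore"):
        term1 = n1 * np.log(ri) if n1 else 0.0
        term2 = n2 * np.log(rf) if n2 else 0.0
    if not np.isfinite(term1) or not np.isfinite(term2):
        return -np.inf
    return float(term1 + term2 - ri * ts - rf * (train.T - ts))


# ---------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------

def fit_sigmoid(train: EventTrain,
                w_starts=(10.0, 100.0, 1000.0)) -> SigmoidRateFit:
    """Maximize the sigmoid-model likelihood with a multi-start search.

    Start points: ts at the deciles of the event times crossed with the
    widths in *w_starts* (the likelihood surface is multi-modal).  Rates
    are optimized on a log scale to keep them positive.
    """
    if train.n < 2:
        raise ValueError("need at least two events")
    T = train.T
    ts_starts = np.quantile(train.times, np.linspace(0.1, 0.9, 9))

    def neg(params):
        lri, lrf, ts, lw = params
        return -loglik_sigmoid(train, math.exp(lri), math.exp(lrf),
                               ts, math.exp(lw))

    best = None
    n_ok = 0
    for ts0 in ts_starts:
        n1 = max(int(np.searchsorted(train.times, ts0)), 1)
        ri0 = max(n1 / max(ts0, 1e-9), 1e-9)
        rf0 = max((train.n - n1) / max(T - ts0, 1e-9), 1e-9)
        for w0 in w_starts:
            x0 = [math.log(ri0), math.log(rf0), ts0, math.log(w0)]
            res = minimize(neg, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-3,
                                    "fatol": 1e-6})
            if not np.isfinite(res.fun):
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("all sigmoid fit starts failed")
    lri, lrf, ts, lw = best.x
    return SigmoidRateFit(ri=math.exp(lri), rf=math.exp(lrf),
                          ts=float(ts), w=math.exp(lw),
                          loglik=float(-best.fun),
                          converged=bool(best.success), n_starts=n_ok)


def fit_step(train: EventTrain, grid_step: float = 10.0) -> StepRateFit:
    """Profile the step-model likelihood over the step time ts.

    For each ts on a uniform grid the before/after rates have the
    closed-form MLEs n1/ts and n2/(T-ts); the normalized likelihood
    profile over ts yields the mean and SD of the step time.
    """
    if train.n < 2:
        raise ValueError("need at least two events")
    T = train.T
    grid = np.arange(grid_step, T, grid_step)
    n1 = np.searchsorted(train.times, grid).astype(float)
    n2 = train.n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (np.where(n1 > 0, n1 * np.log(n1 / grid), 0.0)
              + np.where(n2 > 0, n2 * np.log(n2 / (T - grid)), 0.0)
              - train.n)
    ll = np.where(np.isfinite(ll), ll, -np.inf)
    k = int(np.argmax(ll))
    prof = np.exp(ll - ll[k])
    prof /= prof.sum()
    ts_mean = float(np.sum(grid * prof))
    ts_sd = float(math.sqrt(max(np.sum(grid ** 2 * prof) - ts_mean ** 2, 0.0)))
    ts_hat = float(grid[k])
    degenerate = n1[k] == 0 or n2[k] == 0
    return StepRateFit(
        ri=float(n1[k] / grid[k]), rf=float(n2[k] / (T - grid[k])),
        ts=ts_hat, ts_mean=ts_mean, ts_sd=ts_sd,
        loglik=float(ll[k]), grid=grid, profile=prof, degenerate=degenerate)


@dataclass
class WidthEvidence:
    """Marginal-likelihood comparison of a sudden step against a
    reference gradual sigmoid.

    The joint ML of (ts, w) is degenerate: w -> 0 with ts placed inside
    a fortuitous gap between events can always gain a little likelihood,
    so the raw fitted width over-diagnoses sudden changes.  Here the
    change time is marginalized (uniformly over the window, rates
    profiled per candidate ts), which charges the step model's sharper
    ts-peak its proper Occam factor.  margin > 0 favors the step.
    """

    margin: float
    evidence_step: float
    evidence_ref: float
    ref_width: float


def _profile_ll_step(times: np.ndarray, T: float,
                     grid: np.ndarray) -> np.ndarray:
    n1 = np.searchsorted(times, grid).astype(float)
    n2 = len(times) - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        return (np.where(n1 > 0, n1 * np.log(n1 / grid), 0.0)
                + np.where(n2 > 0, n2 * np.log(n2 / (T - grid)), 0.0)
                - len(times))


def _profile_ll_sigmoid(times: np.ndarray, T: float, w: float,
                        grid: np.ndarray, iters: int = 150) -> np.ndarray:
    """Profiled-rate log-likelihood of the sigmoid shape at each ts on
    *grid* (gradient ascent on log-rates; concave in the rates)."""
    s = 0.5 * (1.0 + erf((times[None, :] - grid[:, None]) / w))
    V = 0.5 * (T + w * (_erf_antideriv((T - grid) / w)
                        - _erf_antideriv(-grid / w)))
    U = T - V
    n = max(len(times), 1)
    la = np.full(len(grid), math.log(n / T))
    lb = la.copy()
    u, v = 1.0 - s, s
    with np.errstate(all="ignore"):
        for _ in range(iters):
            a, b = np.exp(la), np.exp(lb)
            den = np.maximum(a[:, None] * u + b[:, None] * v, 1e-300)
            ga = a * ((u / den).sum(1) - U)
            gb = b * ((v / den).sum(1) - V)
            la += np.clip(ga / n, -0.3, 0.3)
            lb += np.clip(gb / n, -0.3, 0.3)
        a, b = np.exp(la), np.exp(lb)
        den = np.maximum(a[:, None] * u + b[:, None] * v, 1e-300)
        return np.log(den).sum(1) - a * U - b * V


def width_evidence(train: EventTrain, ref_width: float | None = None,
                   grid_step: float = 50.0) -> WidthEvidence:
    """Compare step vs reference-width sigmoid by ts-marginalized
    profile likelihood.

    *ref_width* defaults to the geometric midpoint of the gradual
    range, sqrt(300 * T/2) (about 1200 s for a 10^4 s window).
    """
    from scipy.special import logsumexp

    if train.n < 2:
        raise ValueError("need at least two events")
    T = train.T
    if ref_width is None:
        ref_width = math.sqrt(SUDDEN_WIDTH_S * T / 2.0)
    grid = np.arange(grid_step, T, grid_step)
    fine = np.arange(grid_step / 5.0, T, grid_step / 5.0)
    e_step = float(logsumexp(_profile_ll_step(train.times, T, fine))
                   - math.log(len(fine)))
    e_ref = float(logsumexp(_profile_ll_sigmoid(train.times, T,
                                                ref_width, grid))
                  - math.log(len(grid)))
    return WidthEvidence(margin=e_step - e_ref, evidence_step=e_step,
                         evidence_ref=e_ref, ref_width=ref_width)


def long_path_event_train(seq, maze, target: int,
                          min_junctions: int = 6,
                          divide_by: int = 1) -> EventTrain:
    """Event train of long direct paths to *target* on the in-maze clock.

    Path completion times are mapped to cumulative time spent in the
    maze (cage time excised).  *divide_by* thins deterministically for
    control-node tallies pooled over several nodes (every divide_by-th
    event kept, preserving the rate division).
    """
    from .reduction import find_direct_paths, maze_time

    paths = find_direct_paths(seq, target, min_junctions, maze)
    mt = maze_time(seq)
    total = float(mt[-1]) if len(mt) else 1.0
    ends = np.array([p.end_time for p in paths])
    times = np.interp(ends, seq.times, mt) if len(ends) else np.empty(0)
    if divide_by > 1:
        times = times[::divide_by]
    return EventTrain(times, max(total, 1e-9))


def classify_sudden(sig: SigmoidRateFit | None, step: StepRateFit,
                    evidence: WidthEvidence | None = None) -> str:
    """Classify a rate change: "sudden" (width regime below 300 s and
    step-time SD small enough), "dropped" (sudden-looking width but step
    time too uncertain), else "gradual".

    When a :class:`WidthEvidence` is supplied, the width regime is
    decided by its marginal-likelihood margin (robust against the w -> 0
    spike degeneracy of the joint ML fit); otherwise the raw fitted
    width is thresholded.
    """
    if evidence is None and sig is None:
        raise ValueError("need a sigmoid fit or a width evidence")
    sudden_width = (evidence.margin > 0 if evidence is not None
                    else sig.w < SUDDEN_WIDTH_S)
    if not sudden_width:
        return "gradual"
    if step.ts_sd > STEP_SD_DROP_S:
        return "dropped"
    return "sudden"
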