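"""Cage/maze transition-rate estimation from residency durations.

The instantaneous rate r(t) of leaving a location after t seconds of
residency relates to the residency-time distribution p(t) through the
cumulative-hazard identity

    R(t) = integral_0^t r = -ln(1 - integral_0^t p),

so R is estimated from the empirical distribution of residency durations
(product-limit estimate when the final, interrupted residency of a
session is included as censored) and r by smoothed differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.ndimage import gaussian_filter1d

from .reduction import CAGE, NodeSequence

__all__ = ["ResidencySample", "residencies", "cumulative_hazard",
           "instantaneous_rate"]


@dataclass
class ResidencySample:
    """Durations spent in one location before transitioning away."""

    durations: np.ndarray
    censored: np.ndarray  # True where the residency was cut short by session end

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations/censored length mismatch")


def residencies(seq: NodeSequence, location: str,
                session_end: float | None = None) -> ResidencySample:
    """Extract residency durations in ``"cage"`` or ``"maze"`` from a
    node sequence; the final residency is censored at *session_end*."""
    if location not in ("cage", "maze"):
        raise ValueError(f"unknown location {location!r}")
    in_loc = (seq.nodes == CAGE) if location == "cage" else (seq.nodes != CAGE)
    durations, censored = [], []
    n = len(seq)
    i = 0
    while i < n:
        if not in_loc[i]:
            i += 1
            continue
        j = i
        while j < n and in_loc[j]:
            j += 1
        t0 = float(seq.times[i])
        if j < n:
            durations.append(float(seq.times[j]) - t0)
            censored.append(False)
        else:
            end = session_end if session_end is not None else float(seq.times[-1])
            if end > t0:
                durations.append(end - t0)
                censored.append(True)
        i = j
    return ResidencySample(np.array(durations), np.array(censored))


def cumulative_hazard(sample: ResidencySample,
                      grid: np.ndarray) -> np.ndarray:
    """Cumulative rate R(t) = -ln(S(t)) on *grid*, with S the
    product-limit survival estimate of the residency distribution."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        return np.empty(0)
    if not np.any(~sample.censored):
        raise ValueError("need at least one uncensored duration")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.durations, event_observed=~sample.censored)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    if np.any(surv <= 0):
        warnings.warn("survival reaches 0 on the grid; "
                      "cumulative hazard clipped", stacklevel=2)
        pos = surv[surv > 0]
        floor = pos.min() if pos.size else 1.0
        surv = np.clip(surv, floor, None)
    return -np.log(surv)


def instantaneous_rate(grid: np.ndarray, R: np.ndarray,
                       bandwidth: float = 5.0) -> np.ndarray:
    """Rate r(t): smoothed numerical derivative of the cumulative hazard.

    *bandwidth* is the Gaussian kernel width in seconds; the grid must
    be uniformly spaced.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    R = np.asarray(R, dtype=float)
    if grid.size == 0:
        return np.empty(0)
    if grid.size < 2:
        raise ValueError("need at least two grid points")
    dt = np.diff(grid)
    if not np.allclose(dt, dt[0]):
        raise ValueError("grid must be uniform")
    smooth = gaussian_filter1d(R, sigma=bandwidth / dt[0], mode="nearest")
    return np.clip(np.gradient(smooth, grid), 0.0, None)
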