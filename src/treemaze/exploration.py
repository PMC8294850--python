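"""Exploration-efficiency statistics.

The discovery curve d(n) is the mean number of distinct end nodes seen
in a sliding window of n consecutive end-node visits, pooled over all
windows in all exploration clips.  Efficiency is E = 32/N32 where N32 is
the (interpolated) window size at which d crosses half coverage; the
optimal explorer achieves E = 1 and an unbiased random walk about 0.23
on the 6-level maze.  For summary fits the curve is modeled as

    d(n) ~ 64 * (1 - 1/(1+z) + b*z^3/(1+b)),   z = n/a,

where a is the number of visits to survey about half the end nodes
(E = 32/a) and b a small late-acceleration parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .maze import MazeGraph
from .reduction import NodeSequence, maze_time

__all__ = [
    "DiscoveryCurve", "EfficiencyFit", "EfficiencyUndefined",
    "endnode_visit_clips", "discovery_curve", "n32_efficiency",
    "fit_discovery", "split_half_efficiency", "endnode_occupancy",
    "outer_inner_ratio", "variance_explained",
]


class EfficiencyUndefined(RuntimeError):
    """The discovery curve never reaches half coverage."""


@dataclass
class DiscoveryCurve:
    n: np.ndarray          # window sizes
    d: np.ndarray          # mean distinct end nodes per window
    windows: np.ndarray    # number of windows supporting each n
    n_leaves: int = 64


@dataclass
class EfficiencyFit:
    a: float               # visits to half coverage
    b: float               # late-acceleration parameter
    E: float               # 32/a (half the leaf count over a in general)
    rmse: float
    n_leaves: int = 64


def endnode_visit_clips(seq: NodeSequence, maze: MazeGraph,
                        clips: Sequence[np.ndarray] | None = None,
                        flicker_rule: bool = True) -> List[np.ndarray]:
    """End-node visit subsequences, one array per clip.

    *clips* are index arrays into *seq* (e.g. from
    :func:`treemaze.modes.explore_clips`); by default the whole in-maze
    sequence forms a single clip.

    With *flicker_rule* (default) a repeat visit of the same end node
    qualifies only after the animal has moved at least two steps away,
    so rapid flickers between a leaf and its junction do not inflate the
    visit count.  Because a leaf's only neighbor is its parent, this
    reduces to: a same-leaf revisit counts once the walk has left the
    parent (any intervening leaf lies at least two steps away).
    """
    leaf_min = 2 ** maze.n_levels - 1
    if clips is None:
        idx = np.nonzero(seq.nodes >= 0)[0]
        clips = [idx]
    out = []
    for idx in clips:
        nodes = seq.nodes[idx]
        if not flicker_rule:
            out.append(nodes[nodes >= leaf_min].astype(np.int64))
            continue
        visits: List[int] = []
        last = -1
        armed = True
        for nd in nodes:
            if nd >= leaf_min:
                if nd != last or armed:
                    visits.append(int(nd))
                    last = int(nd)
                    armed = False
            elif not armed and nd != (last - 1) // 2:
                armed = True
        out.append(np.array(visits, dtype=np.int64))
    return [c for c in out if len(c)]


def _window_distinct_sums(visits: np.ndarray, n_values: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """For each window size n: total distinct count summed over all
    windows fully inside *visits*, and the window count.

    Uses the last-occurrence trick: element i is distinct within window
    [t, t+n) iff its previous occurrence lies before t, so its total
    contribution over window starts is the size of the interval
    (prev[i], i] intersected with the valid start range.
    """
    V = len(visits)
    prev = np.full(V, -1, dtype=np.int64)
    last: Dict[int, int] = {}
    for i, v in enumerate(visits):
        if v in last:
            prev[i] = last[v]
        last[v] = i
    idx = np.arange(V, dtype=np.int64)
    sums = np.zeros(len(n_values))
    wins = np.zeros(len(n_values), dtype=np.int64)
    for k, n in enumerate(n_values):
        if n > V:
            continue
        lo = np.maximum(np.maximum(0, idx - n + 1), prev + 1)
        hi = np.minimum(idx, V - n)
        sums[k] = np.maximum(0, hi - lo + 1).sum()
        wins[k] = V - n + 1
    return sums, wins


def discovery_curve(clips: Sequence[np.ndarray],
                    n_max: int | None = None,
                    n_leaves: int = 64,
                    stop_past: float | None = None) -> DiscoveryCurve:
    """Pooled discovery curve over end-node visit clips.

    Windows never span clip boundaries, every window has weight one.
    With *stop_past* set, n stops growing once d exceeds that value
    (enough to bracket half coverage cheaply); otherwise n runs to
    *n_max* (default: longest clip, capped at 8 * n_leaves).
    """
    clips = [np.asarray(c) for c in clips if len(c)]
    if not clips:
        return DiscoveryCurve(np.empty(0, int), np.empty(0), np.empty(0, int),
                              n_leaves)
    longest = max(len(c) for c in clips)
    cap = min(longest, n_max if n_max is not None else 8 * n_leaves)
    if stop_past is None:
        n_values = np.arange(1, cap + 1)
        sums = np.zeros(len(n_values))
        wins = np.zeros(len(n_values), dtype=np.int64)
        for c in clips:
            s, w = _window_distinct_sums(c, n_values)
            sums += s
            wins += w
        good = wins > 0
        return DiscoveryCurve(n_values[good], sums[good] / wins[good],
                              wins[good], n_leaves)
    # incremental: extend n until d passes stop_past
    ns: List[int] = []
    ds: List[float] = []
    ws: List[int] = []
    block = 16
    n_lo = 1
    while n_lo <= cap:
        n_values = np.arange(n_lo, min(n_lo + block, cap + 1))
        sums = np.zeros(len(n_values))
        wins = np.zeros(len(n_values), dtype=np.int64)
        for c in clips:
            s, w = _window_distinct_sums(c, n_values)
            sums += s
            wins += w
        for k in range(len(n_values)):
            if wins[k] == 0:
                continue
            ns.append(int(n_values[k]))
            ds.append(sums[k] / wins[k])
            ws.append(int(wins[k]))
        if ds and ds[-1] > stop_past:
            break
        n_lo += block
        block = min(2 * block, 128)
    return DiscoveryCurve(np.array(ns), np.array(ds), np.array(ws), n_leaves)


def n32_efficiency(curve: DiscoveryCurve) -> float:
    """E = 32/N32, with N32 found by linear interpolation of d(n)
    through half coverage."""
    half = curve.n_leaves / 2
    if curve.d.size == 0 or curve.d.max() < half:
        raise EfficiencyUndefined(
            f"discovery curve never reaches {half:g} distinct end nodes "
            f"(max {curve.d.max() if curve.d.size else 0:.2f})")
    k = int(np.argmax(curve.d >= half))
    if k == 0:
        n32 = float(curve.n[0])
    else:
        n0, n1 = curve.n[k - 1], curve.n[k]
        d0, d1 = curve.d[k - 1], curve.d[k]
        n32 = float(n0 + (half - d0) * (n1 - n0) / (d1 - d0))
    return half / n32


def _model(n: np.ndarray, a: float, b: float, n_leaves: int) -> np.ndarray:
    z = n / a
    return n_leaves * (1.0 - 1.0 / (1.0 + z) + b * z ** 3 / (1.0 + b))


def fit_discovery(curve: DiscoveryCurve) -> EfficiencyFit:
    """Least-squares fit of the two-parameter discovery-curve model."""
    half = curve.n_leaves / 2
    if curve.d.size < 4 or curve.d.max() < half:
        raise EfficiencyUndefined("curve does not span half coverage")
    a0 = float(curve.n[np.argmax(curve.d >= half)])
    try:
        popt, _ = curve_fit(
            lambda n, a, b: _model(n, a, b, curve.n_leaves),
            curve.n.astype(float), curve.d,
            p0=[a0, 0.1], bounds=([1e-6, 0.0], [np.inf, 10.0]), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"discovery-curve fit failed: {err}") from err
    a, b = float(popt[0]), float(popt[1])
    resid = curve.d - _model(curve.n.astype(float), a, b, curve.n_leaves)
    return EfficiencyFit(a=a, b=b, E=half / a,
                         rmse=float(np.sqrt(np.mean(resid ** 2))),
                         n_leaves=curve.n_leaves)


def split_half_efficiency(seq: NodeSequence, maze: MazeGraph,
                          clips: Sequence[np.ndarray] | None = None
                          ) -> tuple[float, float, float]:
    """Efficiency in the first vs second half of in-maze time.

    Returns (E1, E2, E2/E1).  Raises :class:`EfficiencyUndefined` if a
    half lacks coverage.
    """
    mt = maze_time(seq)
    t_split = mt[-1] / 2 if len(mt) else 0.0
    halves: List[List[np.ndarray]] = [[], []]
    if clips is None:
        clips = [np.nonzero(seq.nodes >= 0)[0]]
    for idx in clips:
        first = idx[mt[idx] <= t_split]
        second = idx[mt[idx] > t_split]
        halves[0].append(first)
        halves[1].append(second)
    Es = []
    for half_clips in halves:
        leaf_clips = endnode_visit_clips(seq, maze, half_clips)
        curve = discovery_curve(leaf_clips, stop_past=33.0)
        Es.append(n32_efficiency(curve))
    return Es[0], Es[1], Es[1] / Es[0]


def endnode_occupancy(seq: NodeSequence, maze: MazeGraph,
                      clips: Sequence[np.ndarray] | None = None
                      ) -> np.ndarray:
    """Fraction of end-node visits at each leaf (first-entry counting),
    indexed by leaf id order."""
    leaf_clips = endnode_visit_clips(seq, maze, clips)
    if not leaf_clips:
        raise ValueError("no end-node visits")
    visits = np.concatenate(leaf_clips)
    leaves = np.array(maze.leaves)
    counts = np.array([(visits == leaf).sum() for leaf in leaves], dtype=float)
    return counts / counts.sum()


def outer_inner_ratio(occupancy: np.ndarray, maze: MazeGraph,
                      exclude: Sequence[int] = ()) -> float:
    """Mean outer-leaf visit fraction over mean inner-leaf fraction.

    *exclude* removes leaves (typically the water port and its
    neighbor) from the outer ring before averaging.
    """
    from .maze import classify_rings
    rings = classify_rings(maze)
    leaves = maze.leaves
    outer = [k for k, leaf in enumerate(leaves)
             if rings[leaf] == "outer" and leaf not in exclude]
    inner = [k for k, leaf in enumerate(leaves) if rings[leaf] == "inner"]
    inner_mean = occupancy[inner].mean()
    if inner_mean == 0:
        raise ValueError("no visits to inner leaves; ratio undefined")
    return float(occupancy[outer].mean() / inner_mean)


def variance_explained(observed: np.ndarray, predicted: np.ndarray) -> float:
    """R^2 of *predicted* leaf-visit fractions against *observed*."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    ss_res = np.sum((observed - predicted) ** 2)
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(1.0 - ss_res / ss_tot)
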