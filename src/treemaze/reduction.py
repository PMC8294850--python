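"""Reduce continuous nose tracks to node sequences; bouts and direct paths.

The discrete representation of a session is the *node sequence*: the
ordered, time-stamped list of maze nodes the animal's nose enters, with
periods in the home cage marked by the sentinel node :data:`CAGE`.  A
*step* is one node-to-node transition, a *bout* one foray into the maze
from entrance to exit, and a *direct path* a node run without reversals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .maze import MazeGraph, shortest_path, tree_distance

__all__ = [
    "CAGE",
    "KeypointTrack",
    "NodeSequence",
    "Bout",
    "DirectPath",
    "to_node_sequence",
    "segment_bouts",
    "find_direct_paths",
    "count_errors",
    "home_run",
    "path_overlap",
    "count_visits",
    "maze_time",
]

#: Sentinel node id marking residence in the home cage.
CAGE = -1


@dataclass
class KeypointTrack:
    """Per-frame nose positions, in maze grid units."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")

    @classmethod
    def from_csv(cls, path, frame_rate: float = 30.0) -> "KeypointTrack":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["x"].to_numpy(),
                   df["y"].to_numpy(), frame_rate)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "x": self.x, "y": self.y}).to_csv(
            path, index=False)


@dataclass
class NodeSequence:
    """Time-stamped discrete trajectory; cage residencies appear as
    entries with node :data:`CAGE` and location label ``"cage"``."""

    nodes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.nodes) != len(self.times):
            raise ValueError("nodes and times must have equal length")
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def location(self) -> np.ndarray:
        return np.where(self.nodes == CAGE, "cage", "maze")

    def validate(self, maze: MazeGraph) -> None:
        """Check every in-maze step is an edge of the maze graph."""
        n = self.nodes
        inside = n != CAGE
        for i in np.nonzero(inside[:-1] & inside[1:])[0]:
            a, b = int(n[i]), int(n[i + 1])
            if b not in maze.adjacency[a]:
                raise ValueError(f"non-adjacent step {a} -> {b} at index {i}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.nodes, "t_s": self.times, "location": self.location})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NodeSequence":
        df = pd.read_csv(path)
        return cls(df["node_id"].to_numpy(), df["t_s"].to_numpy())


@dataclass
class Bout:
    """One foray into the maze, from entrance to exit."""

    entry_time: float
    exit_time: float
    start: int          # index into the parent NodeSequence (first maze node)
    stop: int           # index one past the last maze node
    nodes: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass
class DirectPath:
    """A reversal-free node run."""

    nodes: List[int]
    start_time: float
    end_time: float

    def junction_count(self, maze: MazeGraph) -> int:
        return sum(1 for n in self.nodes if maze.is_junction(n))

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------
# track -> node sequence
# ---------------------------------------------------------------------

def to_node_sequence(track: KeypointTrack, maze: MazeGraph,
                     repair: str = "split",
                     gap_reset: float = 2.0,
                     smooth: float = 0.15,
                     hysteresis: float = 0.2) -> NodeSequence:
    """Reduce a nose track to node arrival events.

    The track is first smoothed with a centered moving average of
    *smooth* seconds (within contiguous stretches only), which shrinks
    frame-to-frame tracking jitter well below the half-cell scale.  A
    node event is then registered at the first frame that lies inside a
    node cell different from the current node by at least *hysteresis*
    cell widths beyond the midline, so slow crossings cannot flicker
    back and forth.  Re-entering the same node cell without visiting
    another node cell in between is not a new event.

    Non-adjacent consecutive events ("teleports", e.g. from tracking
    dropouts) trigger a warning and are handled per *repair*:
    ``"split"`` keeps the jump (downstream code must re-validate) or
    ``"interpolate"`` inserts the unique shortest path between them.

    A gap between frames longer than *gap_reset* seconds (the nose out
    of view, e.g. in the cage) resets the dedupe state, so returning to
    the same node after a gap is a new event and adjacency is not
    enforced across the gap.
    """
    if repair not in ("split", "interpolate"):
        raise ValueError(f"unknown repair policy {repair!r}")
    if len(track.times) == 0:
        return NodeSequence(np.empty(0, int), np.empty(0, float))

    node_of_cell = {coord: n for n, coord in maze.cell_coords.items()}
    x, y = _smooth_track(track, gap_reset, smooth)
    ci = np.rint(x).astype(int)
    cj = np.rint(y).astype(int)
    inside = (np.abs(x - ci) <= 0.5 - hysteresis) &         (np.abs(y - cj) <= 0.5 - hysteresis)

    nodes: List[int] = []
    times: List[float] = []
    current = None
    for k in range(len(ci)):
        if k > 0 and track.times[k] - track.times[k - 1] > gap_reset:
            current = None
        node = node_of_cell.get((ci[k], cj[k]))
        if node is None or node == current or not inside[k]:
            continue
        if current is not None and node not in maze.adjacency[current]:
            warnings.warn(
                f"teleport {current} -> {node} at t={track.times[k]:.3f}s "
                f"(repair={repair})", stacklevel=2)
            if repair == "interpolate":
                for via in shortest_path(maze, current, node)[1:-1]:
                    nodes.append(via)
                    times.append(float(track.times[k]))
        nodes.append(node)
        times.append(float(track.times[k]))
        current = node
    return NodeSequence(np.array(nodes, int), np.array(times, float))


def _smooth_track(track: KeypointTrack, gap_reset: float,
                  smooth: float) -> Tuple[np.ndarray, np.ndarray]:
    """Centered moving average over *smooth* seconds, never across
    frame gaps longer than *gap_reset*."""
    if smooth <= 0 or len(track.times) < 3:
        return track.x, track.y
    win = int(round(smooth * track.frame_rate))
    if win < 2:
        return track.x, track.y
    win += (win + 1) % 2          # odd window
    xs = track.x.copy()
    ys = track.y.copy()
    breaks = np.nonzero(np.diff(track.times) > gap_reset)[0] + 1
    kernel = np.ones(win) / win
    start = 0
    for stop in list(breaks) + [len(xs)]:
        if stop - start >= win:
            seg = slice(start, stop)
            for arr in (xs, ys):
                sm = np.convolve(arr[seg], kernel, mode="same")
                # undo edge shrinkage of the boxcar
                norm = np.convolve(np.ones(stop - start), kernel,
                                   mode="same")
                arr[seg] = sm / norm
        start = stop
    return xs, ys


# ---------------------------------------------------------------------
# bouts
# ---------------------------------------------------------------------

def segment_bouts(seq: NodeSequence) -> List[Bout]:
    """Split a labeled node sequence into maximal in-maze runs."""
    bouts: List[Bout] = []
    n = len(seq)
    i = 0
    while i < n:
        if seq.nodes[i] == CAGE:
            i += 1
            continue
        j = i
        while j < n and seq.nodes[j] != CAGE:
            j += 1
        exit_time = float(seq.times[j]) if j < n else float(seq.times[j - 1])
        bouts.append(Bout(
            entry_time=float(seq.times[i]),
            exit_time=exit_time,
            start=i, stop=j,
            nodes=seq.nodes[i:j].copy(),
            times=seq.times[i:j].copy(),
        ))
        i = j
    return bouts


def maze_time(seq: NodeSequence) -> np.ndarray:
    """Cumulative in-maze seconds elapsed at each event of *seq*.

    Event-train analyses are run on this clock (cage time excised).
    """
    t = np.zeros(len(seq))
    acc = 0.0
    for i in range(1, len(seq)):
        if seq.nodes[i - 1] != CAGE:
            acc += float(seq.times[i] - seq.times[i - 1])
        t[i] = acc
    return t


# ---------------------------------------------------------------------
# direct paths, errors, home runs
# ---------------------------------------------------------------------

def _reversal_free_segments(nodes: np.ndarray, times: np.ndarray
                            ) -> Iterable[Tuple[List[int], List[float]]]:
    """Yield maximal reversal-free segments of one bout.

    A reversal at position i means nodes[i+1] == nodes[i-1]; a new
    segment then starts at the turning point nodes[i].
    """
    if len(nodes) == 0:
        return
    seg_n: List[int] = [int(nodes[0])]
    seg_t: List[float] = [float(times[0])]
    for i in range(1, len(nodes)):
        if len(seg_n) >= 2 and nodes[i] == seg_n[-2]:
            yield seg_n, seg_t
            seg_n, seg_t = [seg_n[-1]], [seg_t[-1]]
        seg_n.append(int(nodes[i]))
        seg_t.append(float(times[i]))
    yield seg_n, seg_t


def find_direct_paths(seq: NodeSequence, target: int,
                      min_junctions: int, maze: MazeGraph) -> List[DirectPath]:
    """Reversal-free paths ending at *target* crossing more than
    *min_junctions* junctions (strictly greater, so the 6-junction
    perfect entrance run is excluded at the default threshold of 6)."""
    maze._check(target)
    paths: List[DirectPath] = []
    for bout in segment_bouts(seq):
        for seg_n, seg_t in _reversal_free_segments(bout.nodes, bout.times):
            for k, node in enumerate(seg_n):
                if node != target or k == 0:
                    continue
                p = DirectPath(seg_n[: k + 1], seg_t[0], seg_t[k])
                if p.junction_count(maze) > min_junctions:
                    paths.append(p)
    return paths


def count_errors(path_length: int, direct_length: int) -> int:
    """Turning errors on a run: every wrong step must be backtracked,
    adding two steps, so errors = (length - direct length) / 2."""
    if path_length < direct_length:
        raise ValueError("path shorter than the direct path")
    diff = path_length - direct_length
    if diff % 2:
        raise ValueError(
            f"path/direct length difference {diff} is odd; "
            "the path is mis-segmented")
    return diff // 2


def home_run(bout: Bout, maze: MazeGraph) -> Tuple[DirectPath, int]:
    """The terminal reversal-free segment of a bout ending at the exit.

    Returns the path and the level of its starting node.
    """
    nodes, times = bout.nodes, bout.times
    if len(nodes) == 0:
        raise ValueError("empty bout")
    i = len(nodes) - 1
    while i >= 2 and nodes[i - 2] != nodes[i]:
        i -= 1
    start = max(i - 1, 0)
    path = DirectPath([int(n) for n in nodes[start:]],
                      float(times[start]), float(times[-1]))
    return path, maze.level[path.nodes[0]]


def path_overlap(outbound: Sequence[int], home: Sequence[int]) -> int:
    """Distinct nodes shared by the outbound and home paths of a bout.

    The minimum is 1 whenever both paths exist, because every path into
    or out of the maze passes through the central junction.
    """
    return len(set(int(n) for n in outbound) & set(int(n) for n in home))


def count_visits(seq: NodeSequence, target: int, maze: MazeGraph,
                 two_step: bool = True) -> int:
    """Count visits to *target*; with *two_step* the animal must move at
    least two steps away before a new visit qualifies (suppresses rapid
    flickers between adjacent nodes)."""
    maze._check(target)
    count = 0
    armed = True
    for node in seq.nodes:
        if node == CAGE:
            armed = True
            continue
        if node == target:
            if armed:
                count += 1
                armed = False or not two_step
        elif not armed and tree_distance(maze, int(node), target) >= 2:
            armed = True
    return count
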