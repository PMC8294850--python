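"""Behavioral-mode segmentation: drink / leave / explore.

Once in the maze, behavior is partitioned into three modes: walking to
the water port plus the time spent at it (*drink*), the terminal walk to
the exit (*leave*), and everything else (*explore*).  The walks are
detected retrospectively as maximal reversal-free runs ending at the
port or the exit; exploration is defined by exclusion, so the three
modes tile each bout exactly.  For unrewarded sessions only leave and
explore are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .maze import MazeGraph
from .reduction import Bout, NodeSequence, home_run, segment_bouts

__all__ = ["ModeSegment", "segment_modes", "ethogram", "mode_timecourse",
           "explore_clips"]

MODES = ("drink", "leave", "explore")


@dataclass
class ModeSegment:
    mode: str
    start_time: float
    end_time: float
    bout_index: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def _drink_intervals(bout: Bout, water_leaf: int) -> List[Tuple[float, float]]:
    """Maximal reversal-free runs ending at the port, extended through
    the dwell at the port until the first step away."""
    out: List[Tuple[float, float]] = []
    nodes, times = bout.nodes, bout.times
    seg_start = 0
    for i in range(len(nodes)):
        if i - seg_start >= 2 and nodes[i] == nodes[i - 2]:
            seg_start = i - 1
        if nodes[i] == water_leaf:
            depart = (float(times[i + 1]) if i + 1 < len(times)
                      else float(bout.exit_time))
            out.append((float(times[seg_start]), depart))
    # clip overlaps between consecutive drink runs
    merged: List[Tuple[float, float]] = []
    for t0, t1 in sorted(out):
        if merged and t0 < merged[-1][1]:
            t0 = merged[-1][1]
        if t1 > t0:
            merged.append((t0, t1))
    return merged


def segment_modes(seq: NodeSequence, maze: MazeGraph,
                  water_leaf: int | None = None) -> List[ModeSegment]:
    """Partition each bout of *seq* into drink / leave / explore segments.

    *water_leaf* None marks an unrewarded session (no drink mode).
    """
    segments: List[ModeSegment] = []
    for b_idx, bout in enumerate(segment_bouts(seq)):
        if len(bout.nodes) == 0:
            continue
        drinks = _drink_intervals(bout, water_leaf) if water_leaf is not None else []
        hr, _ = home_run(bout, maze)
        leave_start = hr.start_time
        # the home run may begin at the port itself; drink keeps priority
        for t0, t1 in drinks:
            if t0 < leave_start < t1:
                leave_start = t1
        drinks = [(t0, min(t1, leave_start)) for t0, t1 in drinks
                  if t0 < leave_start]
        labeled = [(t0, t1, "drink") for t0, t1 in drinks if t1 > t0]
        if bout.exit_time > leave_start:
            labeled.append((leave_start, bout.exit_time, "leave"))
        labeled.sort()
        # explore fills the gaps
        cursor = bout.entry_time
        tiled: List[ModeSegment] = []
        for t0, t1, mode in labeled:
            if t0 > cursor:
                tiled.append(ModeSegment("explore", cursor, t0, b_idx))
            tiled.append(ModeSegment(mode, t0, t1, b_idx))
            cursor = t1
        if bout.exit_time > cursor:
            tiled.append(ModeSegment("explore", cursor, bout.exit_time, b_idx))
        segments.extend(tiled)
    return segments


def ethogram(segments: Sequence[ModeSegment]
             ) -> Tuple[Dict[str, float], pd.DataFrame]:
    """Occupancy fractions and first-order mode-transition matrix.

    Transitions out of *leave* are read from the first mode of the next
    bout.  Rows of the matrix sum to 1 (rows with no transitions are
    left as NaN).
    """
    if not segments:
        raise ValueError("no segments")
    total = sum(s.duration for s in segments)
    occ = {m: sum(s.duration for s in segments if s.mode == m) / total
           for m in MODES}

    ordered = sorted(segments, key=lambda s: (s.start_time, s.end_time))
    counts = pd.DataFrame(0.0, index=list(MODES), columns=list(MODES))
    for a, b in zip(ordered[:-1], ordered[1:]):
        counts.loc[a.mode, b.mode] += 1
    row_sums = counts.sum(axis=1)
    trans = counts.div(row_sums.where(row_sums > 0), axis=0)
    return occ, trans


def mode_timecourse(segments: Sequence[ModeSegment], bin_width: float
                    ) -> pd.DataFrame:
    """Fraction of in-maze time per mode in bins of absolute time."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not segments:
        return pd.DataFrame(columns=["t0", "t1", *MODES])
    t_lo = min(s.start_time for s in segments)
    t_hi = max(s.end_time for s in segments)
    edges = np.arange(t_lo, t_hi + bin_width, bin_width)
    rows = []
    for e0, e1 in zip(edges[:-1], edges[1:]):
        acc = {m: 0.0 for m in MODES}
        for s in segments:
            ov = min(s.end_time, e1) - max(s.start_time, e0)
            if ov > 0:
                acc[s.mode] += ov
        tot = sum(acc.values())
        rows.append({"t0": e0, "t1": e1,
                     **{m: (acc[m] / tot if tot > 0 else np.nan) for m in MODES}})
    return pd.DataFrame(rows)


def explore_clips(seq: NodeSequence, segments: Sequence[ModeSegment]
                  ) -> List[np.ndarray]:
    """Index arrays of *seq* events falling inside explore segments.

    Used to restrict window analyses (discovery curves, bias tallies,
    Markov decisions) to exploration; windows never span clip borders.
    """
    clips: List[np.ndarray] = []
    for s in segments:
        if s.mode != "explore":
            continue
        idx = np.nonzero((seq.times >= s.start_time) &
                         (seq.times < s.end_time) &
                         (seq.nodes >= 0))[0]
        if len(idx):
            clips.append(idx)
    return clips
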