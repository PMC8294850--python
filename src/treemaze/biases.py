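"""Turning-bias estimation at T-junctions.

Every link of the maze is a left or a right branch relative to its
parent junction, so each step is one of four actions:

    0 "in left"   take a left branch deeper into the maze
    1 "in right"  take a right branch deeper into the maze
    2 "out left"  take a left branch back toward the entrance
    3 "out right" take a right branch back toward the entrance

At each junction passage the arriving action a0 and departing action a1
are tallied into conditional probabilities p(a1|a0), from which four
biases are formed: PSF (forward rather than reverse when arriving from
the stem), PSA (alternate the turn direction given forward from the
stem), PBF (forward when arriving from the bar), and PBS (branch into
the stem given forward along the bar).  An unbiased random walk gives
(2/3, 1/2, 2/3, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .maze import MazeGraph
from .reduction import CAGE, NodeSequence

__all__ = ["IN_LEFT", "IN_RIGHT", "OUT_LEFT", "OUT_RIGHT",
           "BiasSet", "UNBIASED", "encode_actions", "estimate_biases"]

IN_LEFT, IN_RIGHT, OUT_LEFT, OUT_RIGHT = 0, 1, 2, 3


@dataclass(frozen=True)
class BiasSet:
    """The four turning biases; NaN marks an inestimable bias."""

    PSF: float
    PSA: float
    PBF: float
    PBS: float
    counts: np.ndarray | None = field(default=None, compare=False, repr=False)

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.PSF, self.PSA, self.PBF, self.PBS)


#: Bias values realized by an unbiased random walk at a three-way junction.
UNBIASED = BiasSet(PSF=2 / 3, PSA=1 / 2, PBF=2 / 3, PBS=1 / 2)


def action_code(maze: MazeGraph, a: int, b: int) -> int:
    """Action code of the step a -> b."""
    if b in (2 * a + 1, 2 * a + 2):
        return IN_LEFT if b == 2 * a + 1 else IN_RIGHT
    if a > 0 and b == (a - 1) // 2:
        return OUT_LEFT if a % 2 == 1 else OUT_RIGHT
    raise ValueError(f"step {a} -> {b} is not a maze edge")


def encode_actions(seq: NodeSequence, maze: MazeGraph) -> np.ndarray:
    """Per-step action codes; steps to/from the cage are coded -1."""
    n = seq.nodes
    out = np.full(max(len(n) - 1, 0), -1, dtype=np.int8)
    for i in range(len(n) - 1):
        if n[i] == CAGE or n[i + 1] == CAGE:
            continue
        out[i] = action_code(maze, int(n[i]), int(n[i + 1]))
    return out


def estimate_biases(seq: NodeSequence, maze: MazeGraph,
                    clips: Sequence[np.ndarray] | None = None) -> BiasSet:
    """Estimate the four turning biases from junction passages.

    *clips* restricts the tallies to exploration segments (index arrays
    into *seq*); pairs never span clip or bout boundaries.  Passages
    through the central junction are excluded: within the maze the root
    has no stem corridor, so its actions do not fit the stem/bar coding.

    Estimation: tally counts n(a0, a1) over all passages, normalize per
    arrival action to p(a1|a0), and combine:

        PSF = [p(0|0)+p(0|1)+p(1|0)+p(1|1)] /
              [p(0|0)+p(0|1)+p(1|0)+p(1|1)+p(2|0)+p(3|1)]
        PSA = [p(0|1)+p(1|0)] / [p(0|0)+p(0|1)+p(1|0)+p(1|1)]
        PBF = [p(0|3)+p(1|2)+p(2|2)+p(2|3)+p(3|2)+p(3|3)] /
              [  ...  + p(0|2)+p(1|3)]
        PBS = [p(2|2)+p(2|3)+p(3|2)+p(3|3)] / [PBF numerator]
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    if clips is None:
        clips = [np.nonzero(seq.nodes >= 0)[0]]
    nodes = seq.nodes
    for idx in clips:
        for k in range(1, len(idx) - 1):
            i_prev, i_cur, i_next = idx[k - 1], idx[k], idx[k + 1]
            # consecutive events only: no pairs across gaps
            if i_cur != i_prev + 1 or i_next != i_cur + 1:
                continue
            cur = int(nodes[i_cur])
            if cur == 0 or cur == CAGE or maze.is_leaf(cur):
                continue
            if nodes[i_prev] == CAGE or nodes[i_next] == CAGE:
                continue
            a0 = action_code(maze, int(nodes[i_prev]), cur)
            a1 = action_code(maze, cur, int(nodes[i_next]))
            counts[a0, a1] += 1
    return biases_from_counts(counts)


def biases_from_counts(counts: np.ndarray) -> BiasSet:
    """Form the four biases from a 4x4 (a0, a1) count table."""
    row = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row > 0, counts / row, np.nan)

    def _ratio(num_terms: List[Tuple[int, int]],
               extra_den: List[Tuple[int, int]]) -> float:
        num = sum(p[a0, a1] for a0, a1 in num_terms)
        den = num + sum(p[a0, a1] for a0, a1 in extra_den)
        if not np.isfinite(den) or den == 0:
            return float("nan")
        return float(num / den)

    stem_fwd = [(0, 0), (1, 0), (0, 1), (1, 1)]
    psf = _ratio(stem_fwd, [(0, 2), (1, 3)])
    psa = _ratio([(1, 0), (0, 1)], [(0, 0), (1, 1)])
    bar_fwd = [(3, 0), (2, 1), (2, 2), (3, 2), (2, 3), (3, 3)]
    pbf = _ratio(bar_fwd, [(2, 0), (3, 1)])
    pbs = _ratio([(2, 2), (3, 2), (2, 3), (3, 3)],
                 [(3, 0), (2, 1)])
    return BiasSet(PSF=psf, PSA=psa, PBF=pbf, PBS=pbs, counts=counts)
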