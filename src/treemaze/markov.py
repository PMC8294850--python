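"""Fixed- and variable-depth Markov models of junction decisions.

During exploration, the action taken at a T-junction (left branch,
right branch, or out toward the entrance) is predicted from the history
of the k most recently occupied nodes.  Counts n(h, a) are turned into
probabilities with Laplace smoothing,

    p(a|h) = (n(h, a) + 1) / (sum_a' n(h, a') + 3),

optionally pooling history nodes across junctions of the same level and
branch type (L/R), and model quality is the held-out cross-entropy
H = <-log2 p(a_t | h_t)> in bits per action, estimated by five-fold
cross-validation on interleaved chunks of the decision sequence.  The
uniform baseline is log2 3 ~ 1.585 bits.  The variable-depth model
retains longer histories only where the training data support them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biases import BiasSet, estimate_biases
from .maze import MazeGraph
from .reduction import CAGE, NodeSequence

__all__ = ["Decision", "MarkovModel", "CrossEntropyReport",
           "junction_decisions", "fit", "fit_variable", "cross_entropy",
           "five_fold_splits", "cv_cross_entropy", "compare_models",
           "four_bias_prediction", "UNIFORM_BITS"]

ACT_LEFT, ACT_RIGHT, ACT_OUT = 0, 1, 2
UNIFORM_BITS = math.log2(3.0)


@dataclass(frozen=True)
class Decision:
    """One junction passage: history of nodes (ending at the junction)
    and the action taken."""

    history: Tuple[int, ...]
    action: int

    @property
    def node(self) -> int:
        return self.history[-1]


def junction_decisions(seq: NodeSequence, maze: MazeGraph,
                       clips: Sequence[np.ndarray] | None = None,
                       max_history: int = 6) -> List[Decision]:
    """Extract T-junction decisions from a node sequence.

    End-node events are not decisions (the reversal is forced) and
    histories never cross clip, bout, or gap boundaries.
    """
    if clips is None:
        clips = [np.nonzero(seq.nodes >= 0)[0]]
    nodes = seq.nodes
    decisions: List[Decision] = []
    for idx in clips:
        # split the clip into runs of consecutive events
        if len(idx) < 2:
            continue
        breaks = np.nonzero(np.diff(idx) != 1)[0] + 1
        for run in np.split(idx, breaks):
            for k in range(len(run) - 1):
                cur = int(nodes[run[k]])
                nxt = int(nodes[run[k + 1]])
                if cur == CAGE or nxt == CAGE or maze.is_leaf(cur):
                    continue
                if nxt == 2 * cur + 1:
                    a = ACT_LEFT
                elif nxt == 2 * cur + 2:
                    a = ACT_RIGHT
                elif cur > 0 and nxt == (cur - 1) // 2:
                    a = ACT_OUT
                else:
                    raise ValueError(f"non-adjacent step {cur} -> {nxt}")
                lo = max(0, k - max_history + 1)
                hist = tuple(int(nodes[i]) for i in run[lo:k + 1])
                decisions.append(Decision(hist, a))
    return decisions


def _pool_label(node: int, maze: MazeGraph):
    """Pooled (level, branch-type) label; the root stays its own label."""
    if node == 0:
        return ("root",)
    return (maze.level[node], "L" if node % 2 == 1 else "R",
            "leaf" if maze.is_leaf(node) else "junction")


@dataclass
class MarkovModel:
    """History -> action count tables with Laplace smoothing.

    depth: fixed history length k, or None for a variable-depth model
    (then *min_count* prunes the history tree: a history of length > 1
    is retained only if its training count reaches the threshold and
    its shorter suffix is retained).
    """

    maze: MazeGraph
    depth: Optional[int] = 1
    min_count: int = 10
    max_depth: int = 6
    pooling: bool = False
    counts: Dict[tuple, np.ndarray] = field(default_factory=dict, repr=False)
    _last_history_len: int = field(default=0, repr=False)

    def _key(self, nodes: Tuple[int, ...]) -> tuple:
        if self.pooling:
            return tuple(_pool_label(n, self.maze) for n in nodes)
        return tuple(nodes)

    # -- fitting -------------------------------------------------------
    def train(self, decisions: Sequence[Decision]) -> "MarkovModel":
        if not decisions:
            raise ValueError("empty training split")
        self.counts = {}
        lengths = ([self.depth] if self.depth is not None
                   else list(range(1, self.max_depth + 1)))
        for d in decisions:
            for k in lengths:
                if len(d.history) < k:
                    continue
                key = (k, self._key(d.history[-k:]))
                tab = self.counts.get(key)
                if tab is None:
                    tab = np.zeros(3, dtype=np.int64)
                    self.counts[key] = tab
                tab[d.action] += 1
        if self.depth is None:
            self._prune()
        return self

    def _prune(self) -> None:
        """Keep histories whose count reaches min_count, suffix-closed."""
        kept: Dict[tuple, np.ndarray] = {}
        for (k, key), tab in sorted(self.counts.items(),
                                    key=lambda kv: kv[0][0]):
            if k == 1:
                kept[(k, key)] = tab
                continue
            if tab.sum() < self.min_count:
                continue
            if (k - 1, key[1:]) in kept:
                kept[(k, key)] = tab
        self.counts = kept

    # -- prediction ----------------------------------------------------
    def predict(self, history: Tuple[int, ...]) -> np.ndarray:
        """Smoothed action probabilities for a node history ending at a
        junction; unseen histories give the uniform (1/3, 1/3, 1/3)."""
        if self.depth is not None:
            k = self.depth
            if len(history) < k:
                tab = None
                self._last_history_len = len(history)
            else:
                tab = self.counts.get((k, self._key(tuple(history[-k:]))))
                self._last_history_len = k
        else:
            tab = None
            self._last_history_len = 1
            for k in range(min(len(history), self.max_depth), 0, -1):
                hit = self.counts.get((k, self._key(tuple(history[-k:]))))
                if hit is not None:
                    tab = hit
                    self._last_history_len = k
                    break
        if tab is None:
            return np.full(3, 1.0 / 3.0)
        return (tab + 1.0) / (tab.sum() + 3.0)


@dataclass
class CrossEntropyReport:
    bits: float
    per_fold: List[float]
    n_decisions: int
    mean_history_length: float
    model: str = ""


def fit(decisions: Sequence[Decision], maze: MazeGraph, depth: int = 1,
        pooling: bool = False) -> MarkovModel:
    """Fit a fixed-depth model."""
    return MarkovModel(maze, depth=depth, pooling=pooling).train(decisions)


def fit_variable(decisions: Sequence[Decision], maze: MazeGraph,
                 min_count: int = 10, max_depth: int = 6,
                 pooling: bool = False) -> MarkovModel:
    """Fit a variable-depth model with count-threshold pruning."""
    return MarkovModel(maze, depth=None, min_count=min_count,
                       max_depth=max_depth, pooling=pooling).train(decisions)


def cross_entropy(model, decisions: Sequence[Decision]) -> CrossEntropyReport:
    """Mean -log2 p of the model on a decision sequence (bits/action)."""
    if not decisions:
        raise ValueError("empty test split")
    bits = 0.0
    hist_len = 0.0
    for d in decisions:
        p = model.predict(d.history)
        bits -= math.log2(p[d.action])
        hist_len += getattr(model, "_last_history_len", 0)
    n = len(decisions)
    return CrossEntropyReport(bits / n, [], n, hist_len / n)


def five_fold_splits(n: int, chunk: int = 500, n_folds: int = 5
                     ) -> List[np.ndarray]:
    """Interleaved chunk assignment: fixed-length chunks of the decision
    sequence are dealt round-robin to folds, so every fold samples the
    whole session evenly."""
    fold_of = (np.arange(n) // chunk) % n_folds
    return [np.nonzero(fold_of == f)[0] for f in range(n_folds)]


def cv_cross_entropy(decisions: Sequence[Decision], fit_fn,
                     chunk: int = 500, n_folds: int = 5
                     ) -> CrossEntropyReport:
    """Five-fold held-out cross-entropy; *fit_fn(train) -> predictor*."""
    decisions = list(decisions)
    folds = five_fold_splits(len(decisions), chunk, n_folds)
    per_fold: List[float] = []
    tot_bits = 0.0
    tot_hist = 0.0
    tot_n = 0
    for f, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        train = [decisions[i] for fo, fold in enumerate(folds) if fo != f
                 for i in fold]
        test = [decisions[i] for i in test_idx]
        model = fit_fn(train)
        rep = cross_entropy(model, test)
        per_fold.append(rep.bits)
        tot_bits += rep.bits * rep.n_decisions
        tot_hist += rep.mean_history_length * rep.n_decisions
        tot_n += rep.n_decisions
    return CrossEntropyReport(tot_bits / tot_n, per_fold, tot_n,
                              tot_hist / tot_n)


# ---------------------------------------------------------------------
# four-bias baseline predictor
# ---------------------------------------------------------------------

def four_bias_prediction(history: Tuple[int, ...], biases: BiasSet,
                         maze: MazeGraph) -> np.ndarray:
    """Action probabilities at a junction implied by the four turning
    biases and the arrival direction (uniform when no arrival node is
    available)."""
    cur = history[-1]
    if len(history) < 2:
        return np.full(3, 1.0 / 3.0)
    prev = history[-2]
    p = np.zeros(3)
    if cur == 0:
        # confined root: reverse vs cross, renormalized
        p_rev = 1.0 - biases.PBF
        p_str = biases.PBF * (1.0 - biases.PBS)
        z = p_rev + p_str
        back = ACT_LEFT if prev == 1 else ACT_RIGHT
        if z <= 0:
            p[1 - back if back <= 1 else 0] = 1.0
            return p
        p[back] = p_rev / z
        p[1 - back] = p_str / z
        return p
    if prev == (cur - 1) // 2:                     # stem arrival
        came_left = cur % 2 == 1
        p[ACT_OUT] = 1.0 - biases.PSF
        alt = ACT_RIGHT if came_left else ACT_LEFT
        same = ACT_LEFT if came_left else ACT_RIGHT
        p[alt] = biases.PSF * biases.PSA
        p[same] = biases.PSF * (1.0 - biases.PSA)
        return p
    # bar arrival from a child
    back = ACT_LEFT if prev == 2 * cur + 1 else ACT_RIGHT
    p[back] = 1.0 - biases.PBF
    p[ACT_OUT] = biases.PBF * biases.PBS
    p[1 - back] = biases.PBF * (1.0 - biases.PBS)
    return p


class FourBiasPredictor:
    """Adapter exposing the bias baseline through the model interface."""

    def __init__(self, biases: BiasSet, maze: MazeGraph) -> None:
        self.biases = biases
        self.maze = maze
        self._last_history_len = 2

    def predict(self, history: Tuple[int, ...]) -> np.ndarray:
        probs = four_bias_prediction(history, self.biases, self.maze)
        # Laplace-like floor: never assign zero probability to a test action
        probs = (probs + 1e-6) / (1.0 + 3e-6)
        return probs


class UniformPredictor:
    _last_history_len = 0

    def predict(self, history) -> np.ndarray:
        return np.full(3, 1.0 / 3.0)


# ---------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------

def compare_models(seq: NodeSequence, maze: MazeGraph,
                   clips: Sequence[np.ndarray] | None = None,
                   ks: Sequence[int] = (1, 2, 3, 4),
                   m_values: Sequence[int] = (10,),
                   pooling: bool = False,
                   chunk: int = 500) -> pd.DataFrame:
    """Held-out cross-entropy of fixed-depth, variable-depth, four-bias
    and uniform models on one decision sequence."""
    decisions = junction_decisions(seq, maze, clips)
    rows = []

    rep = cross_entropy(UniformPredictor(), decisions)
    rows.append({"model": "uniform", "bits": rep.bits,
                 "mean_history": 0.0})

    # four-parameter baseline: biases fitted to the same animal's data
    baseline = FourBiasPredictor(estimate_biases(seq, maze, clips), maze)
    rep = cross_entropy(baseline, decisions)
    rows.append({"model": "four_bias", "bits": rep.bits,
                 "mean_history": 2.0})

    for k in ks:
        rep = cv_cross_entropy(
            decisions, lambda tr, k=k: fit(tr, maze, depth=k, pooling=pooling),
            chunk=chunk)
        rows.append({"model": f"fixed_k{k}", "bits": rep.bits,
                     "mean_history": rep.mean_history_length})
    for m in m_values:
        rep = cv_cross_entropy(
            decisions,
            lambda tr, m=m: fit_variable(tr, maze, min_count=m,
                                         pooling=pooling),
            chunk=chunk)
        rows.append({"model": f"variable_m{m}", "bits": rep.bits,
                     "mean_history": rep.mean_history_length})
    return pd.DataFrame(rows)
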