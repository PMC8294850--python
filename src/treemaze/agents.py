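"""Exploratory agents on the maze.

Four policies are provided: an unbiased random walk (uniform over the
available corridors at each junction), the four-bias random walk
parameterized by (PSF, PSA, PBF, PBS), a Markov-model agent sampling
from fitted history-conditional action distributions, and the optimal
explorer (systematic depth-first traversal that encounters every end
node in exactly 64 visits).

Agents are confined to the maze.  The central junction is treated as a
junction whose stem is the entrance side: since that corridor is not
available, its probability mass is renormalized onto reversal and
crossing to the other child.  End nodes force a reversal.  Alternation
memory starts uniformly at the beginning of a walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .biases import BiasSet, UNBIASED
from .maze import MazeGraph
from .reduction import NodeSequence

__all__ = ["AgentPolicy", "SimSession", "simulate", "efficiency_of_policy",
           "optimal_tour"]


@dataclass(frozen=True)
class AgentPolicy:
    """Specification of an exploring agent.

    kind: "unbiased" | "four_bias" | "markov" | "optimal".
    biases: required for four_bias.
    model: a fitted MarkovModel (see :mod:`treemaze.markov`), required
        for kind "markov".
    """

    kind: str
    biases: Optional[BiasSet] = None
    model: object = None

    def __post_init__(self) -> None:
        if self.kind not in ("unbiased", "four_bias", "markov", "optimal"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "four_bias" and self.biases is None:
            raise ValueError("four_bias policy requires a BiasSet")
        if self.kind == "markov" and self.model is None:
            raise ValueError("markov policy requires a fitted model")


@dataclass
class SimSession:
    """A simulated walk: node sequence plus its generating ground truth."""

    seq: NodeSequence
    policy: AgentPolicy
    seed: int | None
    rewards: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate(policy: AgentPolicy, maze: MazeGraph, n_steps: int,
             start: int = 0, seed: int | None = None,
             rng: np.random.Generator | None = None,
             step_duration: float = 1.0,
             t0: float = 0.0) -> SimSession:
    """Run *policy* for *n_steps* node steps starting at *start*.

    Returns a session whose node sequence has ``n_steps + 1`` events at
    *step_duration* spacing.  With a fixed seed the walk is
    bit-reproducible.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    maze._check(start)
    if rng is None:
        rng = np.random.default_rng(seed)
    if policy.kind == "unbiased":
        nodes = _walk_unbiased(maze, n_steps, start, rng)
    elif policy.kind == "four_bias":
        nodes = _walk_four_bias(maze, n_steps, start, rng, policy.biases)
    elif policy.kind == "optimal":
        nodes = _walk_optimal(maze, n_steps, start)
    else:
        nodes = _walk_markov(maze, n_steps, start, rng, policy.model)
    times = t0 + step_duration * np.arange(len(nodes))
    return SimSession(NodeSequence(np.asarray(nodes), times), policy, seed)


# ---------------------------------------------------------------------
# walk kernels
# ---------------------------------------------------------------------

def _walk_unbiased(maze: MazeGraph, n_steps: int, start: int,
                   rng: np.random.Generator) -> List[int]:
    leaf_min = 2 ** maze.n_levels - 1
    u = rng.random(n_steps)
    nodes = [start]
    cur = start
    prev = -1
    for k in range(n_steps):
        if cur >= leaf_min:
            cur = (cur - 1) // 2
        elif cur == 0:
            cur = 1 + (u[k] >= 0.5)
        else:
            r = int(u[k] * 3)
            cur = (cur - 1) // 2 if r == 0 else 2 * cur + r
        nodes.append(cur)
    return nodes


def _walk_four_bias(maze: MazeGraph, n_steps: int, start: int,
                    rng: np.random.Generator, b: BiasSet) -> List[int]:
    psf, psa, pbf, pbs = b.PSF, b.PSA, b.PBF, b.PBS
    leaf_min = 2 ** maze.n_levels - 1
    u1 = rng.random(n_steps)
    u2 = rng.random(n_steps)
    nodes = [start]
    cur = start
    prev = None
    for k in range(n_steps):
        if cur >= leaf_min:                       # end node: forced reversal
            nxt = (cur - 1) // 2
        elif prev is None:                        # walk start: uniform move
            neigh = maze.adjacency[cur]
            nxt = neigh[int(u1[k] * len(neigh))]
        elif cur == 0:
            # root: stem (entrance) unavailable; reverse vs cross
            p_rev = 1.0 - pbf
            p_str = pbf * (1.0 - pbs)
            tot = p_rev + p_str
            if tot <= 0:                          # degenerate: always cross
                nxt = 3 - prev                    # other child of root (1<->2)
            else:
                nxt = prev if u1[k] < p_rev / tot else 3 - prev
        elif prev == (cur - 1) // 2:              # arrived from the stem
            if u1[k] >= psf:
                nxt = prev
            else:
                came_left = cur % 2 == 1
                alt = u2[k] < psa
                go_left = (not came_left) if alt else came_left
                nxt = 2 * cur + (1 if go_left else 2)
        else:                                     # arrived from the bar
            if u1[k] >= pbf:
                nxt = prev
            elif u2[k] < pbs:
                nxt = (cur - 1) // 2
            else:
                nxt = 2 * cur + 1 if prev == 2 * cur + 2 else 2 * cur + 2
        prev, cur = cur, int(nxt)
        nodes.append(cur)
    return nodes


def optimal_tour(maze: MazeGraph, start: int = 0) -> List[int]:
    """Depth-first Euler tour from *start* visiting each end node once."""
    if start != 0:
        raise ValueError("optimal tour starts at the central junction")
    tour: List[int] = []

    def visit(node: int) -> None:
        tour.append(node)
        for child in maze.children(node):
            visit(child)
            tour.append(node)

    visit(0)
    return tour


def _walk_optimal(maze: MazeGraph, n_steps: int, start: int) -> List[int]:
    tour = optimal_tour(maze, start)
    walk = list(tour)
    # repeat the tour (dropping the duplicated root) until long enough
    while len(walk) < n_steps + 1:
        walk.extend(tour[1:])
    return walk[: n_steps + 1]


def _walk_markov(maze: MazeGraph, n_steps: int, start: int,
                 rng: np.random.Generator, model) -> List[int]:
    leaf_min = 2 ** maze.n_levels - 1
    nodes = [start]
    cur = start
    for _ in range(n_steps):
        if cur >= leaf_min:
            cur = (cur - 1) // 2
        else:
            probs = model.predict(tuple(nodes[-model.max_depth:]))
            a = rng.choice(3, p=probs)
            if a == 2:
                if cur == 0:   # confined: renormalize onto the children
                    p = probs[:2]
                    a = rng.choice(2, p=p / p.sum()) if p.sum() > 0 else \
                        rng.integers(2)
                    cur = 2 * cur + 1 + int(a)
                else:
                    cur = (cur - 1) // 2
            else:
                cur = 2 * cur + 1 + int(a)
        nodes.append(int(cur))
    return nodes


# ---------------------------------------------------------------------
# policy efficiency
# ---------------------------------------------------------------------

def efficiency_of_policy(policy: AgentPolicy, maze: MazeGraph,
                         n_steps: int = 100_000, replicates: int = 100,
                         seed: int | None = None) -> dict:
    """Exploration efficiency E of a policy over replicate simulations.

    Each replicate runs an independent walk, builds its end-node
    discovery curve and reads off E = 32/N32.  Returns per-replicate
    values with mean and SD.
    """
    from .exploration import discovery_curve, endnode_visit_clips, n32_efficiency

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    Es = []
    for child in ss.spawn(replicates):
        rng = np.random.default_rng(child)
        sess = simulate(policy, maze, n_steps, rng=rng)
        clips = endnode_visit_clips(sess.seq, maze)
        curve = discovery_curve(clips, stop_past=0.55 * 64)
        Es.append(n32_efficiency(curve))
    Es = np.asarray(Es)
    return {"E": Es, "mean": float(Es.mean()),
            "sd": float(Es.std(ddof=1)) if len(Es) > 1 else 0.0}
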