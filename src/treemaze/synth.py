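"""Synthetic session generator with embedded ground truth.

Emulates the data-generating process of an overnight labyrinth session:
alternating cage and maze residencies (cage-to-maze hazard elevated
right after return and declining to a steady level within about a
minute; maze exit at a constant hazard), exploratory walking driven by
an agent policy, goal-directed runs to the water port with a 90 s
reward timeout, terminal home runs, and abrupt policy switches at
configured times.  Every generated artifact carries its recipe, seed,
and a ground-truth log (mode intervals, rewards, switch times) against
which the analysis modules can be validated.

Goal-directed runs follow the unique shortest path with an optional
per-junction lapse probability; this is a convenient generative device
for graded "perfect path" fractions, not a claim about the animals'
algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .biases import BiasSet
from .maze import MazeGraph, shortest_path
from .reduction import CAGE, KeypointTrack, NodeSequence

__all__ = ["PolicyProfile", "SessionRecipe", "SyntheticSession",
           "generate_session", "render_track"]


@dataclass(frozen=True)
class PolicyProfile:
    """Behavioral parameters active over one schedule interval."""

    explore_biases: Optional[BiasSet] = None   # None = unbiased walk
    p_start_drink: float = 0.0        # bout opens with a water run
    p_drink_then_explore: float = 0.9  # else the animal leaves
    long_run_rate: float = 0.0        # 1/s hazard of a direct run to water
    lapse: float = 0.0                # wrong-turn prob on goal-directed runs


@dataclass(frozen=True)
class SessionRecipe:
    """Study conditions for one synthetic 7-h session.

    Defaults mirror the recorded sessions: about half the time in the
    maze (mean bout about five minutes against comparable cage breaks),
    ~16,000 node steps per night at 0.7 s per step, constant maze-exit
    hazard, cage-entry hazard declining fourfold over the first minute,
    and a 90 s reward timeout on the port.
    """

    duration: float = 25_200.0
    schedule: Tuple[Tuple[float, PolicyProfile], ...] = (
        (0.0, PolicyProfile()),)
    cage_rate: float = 1.0 / 400.0         # steady cage->maze hazard (1/s)
    cage_decline_factor: float = 4.0
    cage_decline_tau: float = 20.0         # seconds
    maze_exit_rate: float = 1.0 / 300.0    # constant maze->cage hazard
    step_duration: float = 0.7             # seconds per node step
    drink_dwell: float = 2.0               # seconds at the port
    cage_min: float = 3.0                  # tunnel transit floor (s)
    water_leaf: Optional[int] = None       # None = unrewarded session
    reward_timeout: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.schedule]
        if not times or times[0] != 0.0 or sorted(times) != times:
            raise ValueError("schedule must start at t=0 and be sorted")
        if times[-1] > self.duration:
            raise ValueError("schedule times must lie within the session")

    def profile_at(self, t: float) -> PolicyProfile:
        active = self.schedule[0][1]
        for t0, prof in self.schedule:
            if t0 <= t:
                active = prof
        return active


@dataclass
class SyntheticSession:
    seq: NodeSequence
    recipe: SessionRecipe
    rewards: np.ndarray
    mode_intervals: List[Tuple[str, float, float]] = field(repr=False)
    long_run_starts: List[float] = field(default_factory=list, repr=False)

    def truth_mode_fraction(self, mode: str) -> float:
        tot = sum(t1 - t0 for _, t0, t1 in self.mode_intervals)
        own = sum(t1 - t0 for m, t0, t1 in self.mode_intervals if m == mode)
        return own / tot if tot > 0 else float("nan")


def _sample_cage_residency(recipe: SessionRecipe,
                           rng: np.random.Generator) -> float:
    """Inverse-CDF sample from the declining cage hazard
    r(tau) = r_inf * (1 + (F-1) * exp(-tau/tau0))."""
    r, F, tau0 = recipe.cage_rate, recipe.cage_decline_factor, \
        recipe.cage_decline_tau
    target = rng.exponential(1.0)

    def cum_hazard(tau: float) -> float:
        return r * (tau + (F - 1.0) * tau0 * (1.0 - np.exp(-tau / tau0)))

    hi = 10.0
    while cum_hazard(hi) < target:
        hi *= 2.0
    draw = float(brentq(lambda x: cum_hazard(x) - target, 0.0, hi))
    # traversing the connecting tunnel takes a few seconds each way
    return max(draw, recipe.cage_min)


class _Walker:
    """Stateful single-step kernels shared by the session generator."""

    def __init__(self, maze: MazeGraph, rng: np.random.Generator) -> None:
        self.maze = maze
        self.rng = rng
        self.leaf_min = 2 ** maze.n_levels - 1
        self.cur = 0
        self.prev: Optional[int] = None

    def reset(self) -> None:
        self.cur = 0
        self.prev = None

    def explore_step(self, biases: Optional[BiasSet]) -> int:
        cur, prev, rng = self.cur, self.prev, self.rng
        if cur >= self.leaf_min:
            nxt = (cur - 1) // 2
        elif biases is None or prev is None:
            if prev is None:
                neigh = self.maze.adjacency[cur]
                nxt = neigh[rng.integers(len(neigh))]
            else:
                neigh = self.maze.adjacency[cur] if cur else (1, 2)
                nxt = neigh[rng.integers(len(neigh))]
        elif cur == 0:
            p_rev = 1.0 - biases.PBF
            p_str = biases.PBF * (1.0 - biases.PBS)
            z = p_rev + p_str
            if z <= 0 or rng.random() >= p_rev / z:
                nxt = 3 - prev
            else:
                nxt = prev
        elif prev == (cur - 1) // 2:
            if rng.random() >= biases.PSF:
                nxt = prev
            else:
                came_left = cur % 2 == 1
                alt = rng.random() < biases.PSA
                go_left = (not came_left) if alt else came_left
                nxt = 2 * cur + (1 if go_left else 2)
        else:
            if rng.random() >= biases.PBF:
                nxt = prev
            elif rng.random() < biases.PBS:
                nxt = (cur - 1) // 2
            else:
                nxt = 2 * cur + 1 if prev == 2 * cur + 2 else 2 * cur + 2
        self.prev, self.cur = self.cur, int(nxt)
        return self.cur

    def goal_steps(self, target: int, lapse: float) -> List[int]:
        """Walk to *target*, re-planning after each (possibly lapsed)
        step; a lapse takes one uniformly wrong neighbor."""
        out: List[int] = []
        guard = 0
        while self.cur != target and guard < 10_000:
            guard += 1
            path = shortest_path(self.maze, self.cur, target)
            nxt = path[1]
            if lapse > 0 and self.maze.is_junction(self.cur) \
                    and self.rng.random() < lapse:
                wrong = [n for n in self.maze.adjacency[self.cur] if n != nxt]
                if wrong:
                    nxt = wrong[self.rng.integers(len(wrong))]
            self.prev, self.cur = self.cur, int(nxt)
            out.append(self.cur)
        return out


def generate_session(maze: MazeGraph,
                     recipe: SessionRecipe) -> SyntheticSession:
    """Simulate one full session; byte-identical for a fixed seed."""
    rng = np.random.default_rng(recipe.seed)
    dt = recipe.step_duration
    nodes: List[int] = [CAGE]
    times: List[float] = [0.0]
    rewards: List[float] = []
    mode_iv: List[Tuple[str, float, float]] = []
    long_runs: List[float] = []
    last_reward = -np.inf
    walker = _Walker(maze, rng)
    rewarded = recipe.water_leaf is not None

    t = 0.0
    while True:
        t += _sample_cage_residency(recipe, rng)
        if t >= recipe.duration:
            break
        bout_end = t + rng.exponential(1.0 / recipe.maze_exit_rate)
        walker.reset()
        nodes.append(0)
        times.append(t)

        def emit(path: List[int]) -> None:
            nonlocal t
            for n in path:
                t += dt
                nodes.append(n)
                times.append(t)

        def drink_run(t0: float, lapse: float) -> None:
            nonlocal t, last_reward
            emit(walker.goal_steps(recipe.water_leaf, lapse))
            if t - last_reward >= recipe.reward_timeout:
                rewards.append(t)
                last_reward = t
            t += recipe.drink_dwell  # dwell at the port before the next step

        prof = recipe.profile_at(t)
        leaving = False
        if rewarded and rng.random() < prof.p_start_drink:
            t0 = t
            drink_run(t0, prof.lapse)
            mode_iv.append(("drink", t0, t + dt))
            leaving = rng.random() >= prof.p_drink_then_explore
            if not leaving:
                # the exit clock gates exploration only; re-arm it
                # (memoryless) so a drink cannot consume the bout
                bout_end = t + rng.exponential(1.0 / recipe.maze_exit_rate)
        expl_t0 = t
        while not leaving and t < bout_end:
            prof = recipe.profile_at(t)
            walker.explore_step(prof.explore_biases)
            t += dt
            nodes.append(walker.cur)
            times.append(t)
            if rewarded and walker.cur == recipe.water_leaf:
                # chance arrival at the port during exploration: the
                # animal drinks there like after a deliberate run
                if t - dt > expl_t0:
                    mode_iv.append(("explore", expl_t0, t - dt))
                t0 = t - dt
                drink_run(t0, 0.0)
                mode_iv.append(("drink", t0, t + dt))
                leaving = rng.random() >= prof.p_drink_then_explore
                if not leaving:
                    bout_end = t + rng.exponential(1.0 / recipe.maze_exit_rate)
                expl_t0 = t
            elif (rewarded and prof.long_run_rate > 0
                    and rng.random() < prof.long_run_rate * dt):
                # goal-directed run to water from mid-maze
                if t > expl_t0:
                    mode_iv.append(("explore", expl_t0, t))
                long_runs.append(t)
                t0 = t
                drink_run(t0, prof.lapse)
                mode_iv.append(("drink", t0, t + dt))
                leaving = rng.random() >= prof.p_drink_then_explore
                if not leaving:
                    bout_end = t + rng.exponential(1.0 / recipe.maze_exit_rate)
                expl_t0 = t
        if not leaving and t > expl_t0:
            mode_iv.append(("explore", expl_t0, t))
        # home run to the exit, then back to the cage
        t0 = t
        if walker.cur != 0:
            emit(walker.goal_steps(0, 0.0))
        mode_iv.append(("leave", t0, max(t, t0 + 1e-9)))
        nodes.append(CAGE)
        times.append(t)
        if t >= recipe.duration:
            break

    # clamp truth intervals so they never overlap (drink runs extend one
    # step past the port, into the start of the following segment)
    mode_iv.sort(key=lambda iv: iv[1])
    clamped: List[Tuple[str, float, float]] = []
    for m, t0, t1 in mode_iv:
        if clamped and t0 < clamped[-1][2]:
            t0 = clamped[-1][2]
        if t1 > t0:
            clamped.append((m, t0, t1))
    seq = NodeSequence(np.array(nodes), np.array(times))
    return SyntheticSession(seq, recipe, np.array(rewards), clamped,
                            long_runs)


# ---------------------------------------------------------------------
# continuous track synthesis
# ---------------------------------------------------------------------

def render_track(session: SyntheticSession, maze: MazeGraph,
                 frame_rate: float = 30.0, jitter: float = 0.0,
                 rng: np.random.Generator | None = None) -> KeypointTrack:
    """Continuous nose track through corridor cell centers.

    Positions are interpolated linearly between consecutive node cells
    (corridors are straight), sampled at *frame_rate*, with optional
    Gaussian positional jitter in cell widths.  At moderate jitter the
    reduction round trip `to_node_sequence(render_track(s))` reproduces
    the generating node sequence exactly; large jitter (around 0.6 cell
    widths) breaks it, which the robustness tests exercise.
    """
    if rng is None:
        rng = np.random.default_rng(session.recipe.seed + 1)
    coords = maze.cell_coords
    ft: List[np.ndarray] = []
    fx: List[np.ndarray] = []
    fy: List[np.ndarray] = []
    nodes, times = session.seq.nodes, session.seq.times
    inside = nodes != CAGE
    i = 0
    n = len(nodes)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        # brief pause at the entrance junction after the tunnel
        hold = (np.arange(5) - 5) / frame_rate
        ft.append(times[i] + hold)
        x0, y0 = coords[int(nodes[i])]
        fx.append(np.full(5, float(x0)))
        fy.append(np.full(5, float(y0)))
        for k in range(i, j - 1):
            t0, t1 = times[k], times[k + 1]
            x0, y0 = coords[int(nodes[k])]
            x1, y1 = coords[int(nodes[k + 1])]
            m = max(int(np.ceil((t1 - t0) * frame_rate)), 2)
            tt = np.linspace(t0, t1, m, endpoint=False)
            # the nose pauses briefly at each node before moving on
            pause = min(4.0 / frame_rate, 0.4 * (t1 - t0))
            frac = np.clip((tt - t0 - pause) / (t1 - t0 - pause), 0.0, 1.0)
            ft.append(tt)
            fx.append(x0 + frac * (x1 - x0))
            fy.append(y0 + frac * (y1 - y0))
        if j - 1 >= i:   # hold the final node of the bout briefly
            hold = np.arange(5) / frame_rate
            ft.append(times[j - 1] + hold)
            x, y = coords[int(nodes[j - 1])]
            fx.append(np.full(5, float(x)))
            fy.append(np.full(5, float(y)))
        i = j
    if not ft:
        return KeypointTrack(np.empty(0), np.empty(0), np.empty(0), frame_rate)
    tt = np.concatenate(ft)
    xx = np.concatenate(fx)
    yy = np.concatenate(fy)
    order = np.argsort(tt, kind="stable")
    tt, xx, yy = tt[order], xx[order], yy[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, xx, yy = tt[keep], xx[keep], yy[keep]
    if jitter > 0:
        xx = xx + rng.normal(0.0, jitter, len(xx))
        yy = yy + rng.normal(0.0, jitter, len(yy))
    return KeypointTrack(tt, xx, yy, frame_rate)
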