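"""Behavioral ethogram: drink / leave / explore occupancy and
transitions for the simulated session."""

import json
from pathlib import Path

from treemaze.biases import BiasSet
from treemaze.maze import build_maze
from treemaze.modes import ethogram, mode_timecourse, segment_modes
from treemaze.synth import PolicyProfile, SessionRecipe, generate_session

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42

maze = build_maze()
profile = PolicyProfile(explore_biases=BiasSet(0.85, 0.55, 0.90, 0.60),
                        p_start_drink=0.5, p_drink_then_explore=0.9,
                        long_run_rate=0.003)
recipe = SessionRecipe(schedule=((0.0, profile),),
                       water_leaf=maze.water_port_leaf, seed=SEED)
session = generate_session(maze, recipe)

segments = segment_modes(session.seq, maze, maze.water_port_leaf)
occ, trans = ethogram(segments)
print("occupancy fractions:",
      {k: round(v, 3) for k, v in occ.items()})
print("transition matrix (rows from, columns to):")
print(trans.round(3))
print(f"generator truth explore fraction: "
      f"{session.truth_mode_fraction('explore'):.3f}")

OUT.mkdir(exist_ok=True)
(OUT / "ethogram.json").write_text(json.dumps({
    "occupancy": occ,
    "transitions": {m: trans.loc[m].to_dict() for m in trans.index},
}, indent=1))
mode_timecourse(segments, bin_width=1800.0).to_csv(
    OUT / "mode_timecourse.csv", index=False)
print(f"wrote {OUT / 'ethogram.json'}")
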