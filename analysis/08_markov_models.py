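"""Predicting junction decisions: fixed- and variable-depth Markov
chains vs the four-bias baseline, scored by held-out cross-entropy in
bits per action (uniform baseline log2 3 = 1.585)."""

from pathlib import Path

from treemaze.agents import AgentPolicy, simulate
from treemaze.biases import BiasSet
from treemaze.markov import compare_models
from treemaze.maze import build_maze

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42

maze = build_maze()
# a session-length walk (about one night of steps)
sess = simulate(AgentPolicy("four_bias",
                            biases=BiasSet(0.85, 0.55, 0.90, 0.60)),
                maze, 16_000, seed=SEED)
table = compare_models(sess.seq, maze, ks=(1, 2, 3, 4),
                       m_values=(10, 30, 100), pooling=True)
print(table.round(4).to_string(index=False))
best = table.loc[table.bits.idxmin()]
print(f"best model: {best.model} at {best.bits:.3f} bits/action "
      f"(mean history length {best.mean_history:.1f})")

OUT.mkdir(exist_ok=True)
table.to_csv(OUT / "markov_models.csv", index=False)
print(f"wrote {OUT / 'markov_models.csv'}")
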