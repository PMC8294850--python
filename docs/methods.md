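# Methods

## The maze and its coordinate conventions

The labyrinth is a full binary tree of T-junctions.  With L junction
levels (default 6) there are 2^L − 1 junctions and 2^L end nodes; node
ids follow heap order with the central junction as node 0 and the
children of junction i at 2i+1 (left branch) and 2i+2 (right branch).
The entrance corridor is not a node: paths "from the entrance" start at
node 0, which makes the perfect run to the water port six steps (seven
nodes) long.  Junction levels are counted 0..5 internally; reporting
code may relabel to the 1..7 convention in which end nodes sit at
level 7 (`level_to_reporting`).

Every node is placed on a square grid (one corridor width per cell,
1.5 inch physically) by an H-tree construction driven by egocentric
turns: each child lies at the parent's position plus the level's
corridor length (4, 4, 2, 2, 1, 1 cells) along the direction obtained
by turning left or right from the heading of travel into the parent.
Two consequences matter:

- the 64 end nodes tile a regular 8×8 lattice, whose 28-cell perimeter
  and central 4×4 block define the outer / middle / inner rings used by
  the node-preference analysis;
- flipping the first turn of a leaf's turn sequence while keeping the
  rest maps the layout onto its 180° rotation, so the "image node" of
  the water port (the destination of a single first-junction mistake)
  is exactly the diametrically opposite end node, 12 steps away.
  Together with the mirror map (all turns flipped) these generate a
  four-element symmetry group acting freely on the leaves; the three
  non-identity images of a target are its control nodes.

The embedding is used only for ring classification and for
synthesizing tracks; all graph logic is heap arithmetic.  The water
port's leaf is a configuration parameter; the default is an outer-ring
leaf adjacent to a corner (an arbitrary documented choice — its
identity does not affect any statistic except through the ring
exclusions, where the port and its neighbor are excluded from the
outer-ring average).

## Track reduction

The nose track (time, x, y in grid units) is reduced to node events in
three steps: (1) a centered moving average of 0.15 s smooths
frame-level tracking jitter, applied only within contiguous stretches
(never across gaps longer than 2 s, which mark time out of view);
(2) each frame is assigned its nearest grid cell (midline rule);
(3) a node event is registered at the first frame lying inside a node
cell other than the current one by at least 0.2 cell widths beyond the
midline.  The hysteresis margin prevents slow midline crossings from
flickering; returning to the current node cell without visiting
another node cell is never a new event; a gap longer than 2 s resets
the state, so re-entering the maze registers the entrance junction
afresh.  Consecutive events that are not graph-adjacent ("teleports",
e.g. tracking dropouts) raise a warning and are either left for
downstream validation ("split", the default — decisions are never
fabricated silently) or repaired by inserting the unique tree path
("interpolate").

Bouts are maximal in-maze runs; each starts and ends at node 0.  A
direct path is a node run without reversals (a reversal at position i
means s(i+1) = s(i−1)); the maximal reversal-free suffix ending at a
target defines visits "on a direct path", and the junction count of
such a path must strictly exceed 6 to qualify as a "long" path to the
port.  Turning errors on a run follow from the tree having no loops:
every wrong step must be backtracked, so errors = (length − direct
length)/2, and an odd difference is a data-integrity error.

End-node visit sequences (for discovery curves) apply a two-step
flicker rule: a repeat visit of the same end node counts only after
the animal has moved at least two steps away.  Since a leaf's only
neighbor is its parent, this reduces to ignoring leaf↔parent bounces.
Without this rule the unbiased random walk's efficiency is dragged to
about 0.15 by bounce repeats; with it the walk scores 0.223 ± 0.009,
matching the expected 0.23.  Leaf occupancy distributions, in
contrast, use plain first-entry counting.

## Mode segmentation

Drink = the maximal reversal-free run ending at the water port, plus
the dwell at the port until the first step away; leave = the terminal
home run of the bout; explore = the remainder.  Detected
retrospectively, these tile each bout exactly.  When a home run begins
at the port itself the drink keeps priority and the leave starts at
the port departure.  For unrewarded sessions only leave and explore
exist.  Transitions out of leave are read from the first mode of the
next bout.  Note the definition is retrospective while the synthetic
generator's ground-truth labels are prospective, so the approach path
of a chance port visit counts as drink in the analysis but as explore
in the truth log; recovered explore fractions therefore sit a few
percent below the generator's nominal value, and tests allow for that.

## Transition rates

Residency durations in cage or maze determine the cumulative hazard
through R(t) = −ln(1 − F̂(t)).  F̂ is the product-limit
(Kaplan–Meier) estimate so the final, session-censored residency can
be included without biasing the tail.  The instantaneous rate is the
derivative of R after Gaussian smoothing (bandwidth a parameter,
default 5 s; the estimator behind the published curves is not fully
specified, and kernel-on-R is our choice).  Where F̂ reaches 1 the
hazard is clipped with a warning.

## Exploration efficiency

d(n) is the mean number of distinct end nodes over all windows of n
consecutive end-node visits, pooled with unit weight over all windows
in all exploration clips; windows never span clip boundaries, and
clips shorter than n contribute nothing at that n.  The implementation
uses a last-occurrence decomposition (element i is new in window
[t, t+n) iff its previous occurrence precedes t), giving exact pooled
averages in O(V) per window size.  N32 is found by linear
interpolation of d through 32 and E = 32/N32; a curve that never
reaches half coverage raises an explicit error rather than returning
NaN.  The summary fit uses

    d(n) ≈ 64 (1 − 1/(1+z) + b z³/(1+b)),   z = n/a,

an empirical form in which a sets the visits to roughly half coverage
(E = 32/a) and a small b captures late acceleration; it is fitted by
unweighted least squares over the full n range.  Split-half efficiency
recomputes E separately on the first and second halves of in-maze
time.

## Turning biases

Each step is an action a ∈ {in-left, in-right, out-left, out-right}
("in" = away from the entrance; left/right = the branch's relation to
its parent junction).  At every junction passage the arriving and
departing actions (a0, a1) are tallied — consecutive events only, with
bout/clip boundaries breaking pairs — into conditional probabilities
p(a1|a0), from which

    PSF = stem-forward,  PSA = alternate | stem-forward,
    PBF = bar-forward,   PBS = branch into stem | bar-forward

are composed (see `estimate_biases` for the exact sums).  Passages
through the central junction are excluded: within the maze it has no
stem corridor, so its actions do not fit the coding (its exits belong
to leave mode in any case).  An unbiased walk gives (2/3, 1/2, 2/3,
1/2); estimates recover generating biases within ±0.01 at 10^5
passages.

## Agents

Unbiased walk: uniform over available corridors (three at a junction,
two at the confined root, forced reversal at leaves).  Four-bias walk:
arriving from the stem, reverse with probability 1−PSF, otherwise
alternate vs repeat the previous turn by PSA; arriving from the bar,
reverse with 1−PBF, otherwise take the stem with PBS else cross.  At
the confined root the stem (entrance) is unavailable and its
probability mass is renormalized over reversal and crossing.
Alternation state is simply the arrival branch, so no extra memory is
needed.  The Markov agent samples fitted conditional action
distributions; the optimal explorer is the depth-first Euler tour,
which visits each of the 64 end nodes exactly once.  Walks are
bit-reproducible under a fixed seed.  Simulated walkers are confined
to the maze, matching the explore-mode restriction of the analyses.

## Changepoint models

Event trains (e.g. long paths to the port, timed on the in-maze clock
with cage time excised) are modeled as inhomogeneous Poisson processes
with ln L = Σ ln r(tᵢ) − ∫₀ᵀ r.  The sigmoid rate is

    r(t) = ri + (rf − ri) (1 + erf((t − ts)/w)) / 2,

which starts at ri and saturates at rf (note the 1+erf form; the bare
erf does not have that limit behavior).  Its integral is evaluated in
closed form via the erf antiderivative.  `fit_sigmoid` maximizes ln L
by Nelder–Mead from a multi-start grid (ts at event-time deciles,
w ∈ {10, 100, 1000} s, rates log-parameterized).  `fit_step` profiles
the step model on a 10 s ts grid with closed-form rate MLEs (n₁/ts,
n₂/(T−ts)) and reports the mean and SD of ts under the normalized
likelihood profile.

The raw joint ML of (ts, w) is degenerate: w → 0 with ts inside a
fortuitous inter-event gap always gains a little likelihood, so the
fitted width over-diagnoses suddenness on genuinely gradual data.
The sudden/gradual decision therefore uses `width_evidence`: the
ts-marginalized (uniform over the window, rates profiled per
candidate ts) likelihood of a step is compared with that of a
reference-width sigmoid, the reference being the geometric midpoint
√(300 · T/2) of the gradual range.  Marginalization charges the step
model's sharper ts peak its proper Occam factor.  A change is
"sudden" when the step side wins and the step-time SD is below 900 s
("dropped" above), and "gradual" otherwise; the 300 s width and 900 s
SD thresholds are the study's conventions.  At the canonical train
shape (ri = 0.002/s, rf = 0.02/s, T = 10⁴ s) this classifier is
correct for roughly nine in ten trains of either regime — close to
the known-parameter likelihood-ratio bound of about 96% — and the
step time itself is recovered to well under 200 s.

## Decision models

Junction decisions (explore mode, T-junctions only; end-node
reversals are forced and excluded) are predicted from the history of
the k most recent nodes.  Probabilities use Laplace smoothing,
p(a|h) = (n(h,a)+1)/(Σn+3), so no test action ever has zero
probability.  The variable-depth model keeps histories of length up
to 6 only while their training count reaches a threshold m (default
10, swept in `compare_models`), retention being suffix-closed, and
predicts from the longest retained suffix.  Pooling maps each history
node to its (level, branch-type) label, merging junctions related by
the maze's symmetry; the root keeps its own label.  Evaluation is
five-fold cross-validation on fixed-length chunks (default 500
decisions) dealt round-robin to folds so each fold samples the whole
session; reported cross-entropy is the decision-weighted mean of
−log₂ p over held-out folds.  The four-bias baseline converts a
BiasSet plus the arrival direction into action probabilities (with a
10⁻⁶ floor).  A hook for external compressors as entropy bounds is
deliberately not provided.

## Synthetic sessions

The generator emulates the study's data-generating process, not mouse
cognition: alternating residencies (cage→maze hazard declining
fourfold over the first minute, r(τ) = r∞(1 + 3e^(−τ/20 s)), floored
at a 3 s tunnel transit; maze→cage at a constant hazard that gates
exploration only and is re-armed, memorylessly, after each drink),
explore stepping by any agent policy, bouts opening with a water run
with probability p_start_drink, drinks followed by more exploration
with probability 0.9, goal-directed direct runs to the port launched
at a configurable hazard (the lever for simulating abrupt policy
switches), rewards on a 90 s timeout, and a terminal home run.
Goal-directed runs follow the unique shortest path with an optional
per-junction lapse probability — a generative device for graded
perfect-path fractions, not a model of the animals' algorithm.
Default scales (0.7 s per step, mean bout ≈ 5 min against comparable
cage breaks) yield about 16,000 node steps per night with roughly
half the time in the maze, matching the recorded sessions.

`render_track` lays the node sequence out as a continuous nose track
through corridor cell centers at a chosen frame rate, with a brief
pause at each node (the nose stalls at decision points) and Gaussian
positional jitter.  The reduction round trip is exact at jitter up to
about 0.2 cell widths and is deliberately broken by 0.6, which the
robustness tests exercise.

What the generator does not emulate: speed modulation, grooming and
naps, learning dynamics within a policy (switches are abrupt by
construction), sensory-cue use, or any within-junction kinematics.
Passing recovery tests on these sessions therefore validates the
estimators' correctness on data with known structure, not the
behavioral claims themselves on real recordings.

## Problem sizes

Defaults used by the test-suite and drivers: 10⁵-step walks (about
2×10⁴ end-node visits) for efficiency estimates, 1.4–1.5×10⁵ junction
passages for bias and entropy recovery, 100 replicate trains for
changepoint statistics, and single 7-h synthetic sessions elsewhere.
These sizes put Monte-Carlo error comfortably below each test's
tolerance.
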