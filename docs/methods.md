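# Methods

## The task environment

The environment is a rectangular grid maze (default 5×5) in which every
wall between two rooms carries a shared open/closed door and the outer
boundary is closed. A *state* is a (row, column, orientation) triple, so a
5×5 maze has 100 states. The agent observes only the *scene* — the
open/closed status of the doors to its left, front and right — encoded as a
3-bit label (4·left + 2·forward + 1·right, open = 1). Since the all-closed
scene is excluded by construction (no dead ends), seven scene types can
occur. Because many states share a scene, the task is a POMDP: identifying
one's state requires integrating scenes and actions over time.

Mazes are sampled by drawing each interior door i.i.d. Bernoulli(p_open =
0.55), repairing dead ends and disconnected components by opening extra
doors, and rejecting any maze in which some scene identifies a unique state
(partial observability requires every realized scene to be shared by at
least two states). An optional constraint additionally requires all seven
scene types to occur, which the default task maze uses so that the
downstream rare-label logic operates on a seven-type label distribution. A
fixed maze can also be loaded from JSON so that a whole cohort shares one
layout.

The game protocol alternates blocks of 1–5 *action trials* (observe the
scene, choose an egocentric move; a closed door is a no-op that redisplays
the same scene) with one *prediction trial*: a delay during which the
upcoming scene must be predicted covertly, a 4-level confidence report, and
a choice among four scene options that always include the true upcoming
scene. Distractors are drawn from the scenes reachable by applying the
chosen action in any state whose scene matches the previous trial's scene
(padded with other realized scenes when that pool is small). Feedback on
the next action trial always shows the true scene. A game ends when the
agent first arrives at a never-visited state after completing at least five
prediction trials (a grid-based variant of the termination rule is
available behind a config flag). Misses (probability 0.007) and
computer-substituted timeout actions (probability 0.028, a random passable
door) are injected at the empirical rates of such events.

## The behavioral model

The model tracks the navigator's cognitive state as a belief over
hypotheses (maze state h, binary state-confidence c, operant mode m, and a
subjective set V of visited grid cells). Two policies are switched by the
confidence bit:

* **forward-dominant** (c = 0, information-maximizing): forward if open;
  right if the front door is closed and both side doors are open; the single
  open door otherwise. The optimal action is chosen with probability α and
  each remaining passable action with (1−α)/N_nopt.
* **efficient exploration** (c = 1): all passable doors into unvisited
  cells are optimal; if none, the passable actions that begin a shortest
  open-door path (grid-level BFS) to the nearest unexplored cell are
  optimal; if every cell is visited, all passable actions are. Optimal
  actions share β, non-optimal share 1−β; a single passable door forces
  probability 1, and when every passable action is optimal the distribution
  is uniform over them.

After each action the predicted scene (deterministic push of h through the
transition) is compared with the observation. A match is an *update*: the
state advances deterministically, V grows, and confidence may rise (low→high
with probability p_lh; high stays high). A mismatch is a *backtrack*: the
state is re-estimated uniformly over the set H of states consistent with
the most recent n steps — n (scene, action) pairs plus the current scene,
including the observed success/failure of every move, which is treated as
observable because a failed move redisplays the same scene — and confidence
may drop (high→low with probability p_hl; low stays low). Moving into an
already-visited cell despite a scene match is an *action backtrack*
(confidence transition as in backtrack, but the confirmed state advance is
kept; a config switch allows re-sampling instead), unless every passable
door led to a visited cell, in which case the step counts as a plain update.
θ = (α, β, p_lh, p_hl, n) is the subject-level parameter vector.

Filtering propagates a weighted hypothesis collection through these rules:
each hypothesis is weighted by the likelihood of the observed action under
its confidence-appropriate policy, branched over backtrack targets and
confidence transitions, merged on identical (h, c, m, V) keys, and
renormalized. The predictive probability of each action before
renormalization is the per-action evidence factor; their product over a game
is the game's evidence. Model read-outs used downstream: the set of most
probable actions (all ties), the marginal distribution of upcoming scene
labels given the chosen action, and a binary state-confidence ĉ that is
high only when the largest joint mass P(c = 1, h) among the most probable
states strictly exceeds the total low-confidence mass (ties read low).

Bookkeeping choices the data cannot decide, each behind a config switch,
with defaults as follows. The hypothesis key includes V because both the
exploration policy and the action-backtrack exception depend on it;
hypotheses below weight 1e−8 are pruned (renormalizing). After a backtrack
re-estimation V is rebuilt from the grids traversed by the window-consistent
trajectories ending at the re-estimated state (the window is exactly what
the model treats as reliable); `keep` and `clear` variants are available.
If no surviving hypothesis assigns the observed action positive probability,
the evidence factor is floored at ε = 1e−10 and the belief is left
unchanged (counted and reported). Prediction trials contribute no evidence:
the likelihood is a product over action selections only.

Exactness of the incremental implementation (merging included) is certified
against an independent brute-force enumeration of all (h, c, V)
trajectories on 3×3 fixtures: posteriors and per-action evidence factors
agree to 1e−10. At prediction trials, read-outs condition on the
already-chosen action (the belief is reweighted by its likelihood before
the scene marginal and ĉ are computed), since the subject's report follows
their own action.

## Fitting and model comparison

Parameters are estimated per subject by type-II maximum likelihood:
minimizing the negative log evidence (NLE), the −log product of per-action
predictive probabilities over all games. The filter's branching structure
is independent of the continuous parameters, so each game is compiled once
per n into index arrays whose per-hypothesis likelihoods are linear in α or
β; NLE evaluation is then a fast vectorized pass that reproduces the
unpruned filter exactly (verified to ~1e−13). The surface is smooth on the
bounded box, so the inner search uses multi-start L-BFGS-B on [0.01, 0.99]
(bounds avoid log 0; the box edges are not attainable parameter claims),
with an exhaustive outer grid over n (default 1–5; the recovery study uses
1–3 since the reference n is 2) and the previous grid point's optimum
carried as a warm start. Model variants — `switching` (free α, β, p_lh,
p_hl, n), `forward_only` (α, n), `efficient_only` (β, n) — share the
compiled structure: the single-strategy variants pin the initial confidence
bit and freeze its transitions, which also yields the exact reduction
identity NLE(switching, p_lh = 0) = NLE(forward_only). AIC = 2k + 2·NLE
counts n as free by default (flag available), and model selection flags the
AIC winner.

A caveat found in simulation: with a well-performing agent (the reference
θ), scene mismatches while confidence is high are rare, so the evidence is
nearly flat in p_hl (1–3 nats across the whole admissible range on 30-game
subjects). p_hl point estimates are therefore intrinsically high-variance
at this data scale regardless of optimizer; α, β, p_lh and n recover well.

## Synthetic subjects

The generative agent is the model run forward with a *single sampled*
hypothesis: the initial state estimate is drawn uniformly from the states
consistent with the first scene, actions are sampled from the
confidence-appropriate policy at the current estimate, and backtracks
re-draw the estimate uniformly from the window-consistent set. Its
predicted scene is mapped onto the four options (uniform fallback among the
options if the predicted scene is not displayed — the true scene always is,
so a correct internal prediction is always expressible).

Reports and reaction times are explicit noise models *outside* the
navigation model, present only so downstream analyses receive realistically
structured inputs: the reported side (1–2 vs 3–4) matches the latent
confidence bit with probability `report_fidelity` (default 0.85 — reports
track the latent bit clearly but imperfectly, so report-conditioned and
latent-conditioned analyses can dissociate); the level within a side is
drawn with P(extreme) = 0.4. RT = 1.8 s − 0.25·[high side] − 0.15·[correct] +
N(0, 0.4²), truncated at 0.2 s — magnitudes chosen to sit well inside the
4.5-s response window with effect sizes comparable to the RT shifts the
task literature reports. A sidecar table records the latent h, c and mode
at every trial for ground-truth evaluations.

What the generator does not emulate: human memory imperfection of the maze
layout, learning or fatigue across sessions, level-resolved (4-point)
confidence calibration, and any coupling between RT and the neural
patterns. Passing behavioral tests therefore show that the analysis code
recovers the directions and magnitudes this generative process produces,
not that humans behave like the generator.

## Behavioral statistics

Subjects whose prediction accuracy is not above the 0.25 chance level by a
one-sided one-proportion z-test at p < 0.01 are excluded (missed trials
dropped first). Cohort analyses: per-subject high-vs-low-confidence
accuracy with a one-sided Wilcoxon signed-rank test across subjects
(subjects with a single side reported but dropped from the pairing);
Pearson correlation of accuracy, confidence level and the model's
high-state-confidence fraction with the prediction-trial index, indices
capped at the 95th percentile of per-game prediction counts; streak curves
where each trial's predictor is the length of the immediately preceding
run of correct (or incorrect) predictions, runs resetting at game
boundaries and the run-ending trial not counting toward its own predictor;
scene-choice RTs z-scored within (subject, session) — sessions with fewer
than two RTs or zero variance dropped with a warning — summarized by
confidence side × correctness with one-sided rank-sum comparisons; and the
percent agreement between the model's ĉ side and the reported side on
prediction trials. All tests are one-sided in the direction of the stated
hypothesis and no multiple-comparison correction is applied to the
two-group comparisons.

For the trend correlations the analysis unit is the individual trial
(pooled across subjects) by default. The per-(subject, index)-mean variant
is available (`unit="subject_index_mean"`), but it gives every cell equal
weight no matter how few games support it; under the termination rule, late
indices exist mostly in games where the agent had failed to localize, so
those sparse, selection-biased cells mask the trend. Pooling weights trials
equally and leaves the selection effect visible but not dominant.

## Synthetic activity patterns

For every scored prediction trial the generator emits a 9-period ×
n_features pattern: envelope[t] · amplitude · prototype(chosen scene) +
session drift + Gaussian noise, followed by per-feature z-normalization
within session (emulating run-wise detrending/normalization). Prototypes
are unit-norm random vectors on an informative subset (default 60 of 600
features) with pairwise correlations kept below 0.3. The envelope ramps
from 0.25 to a peak of 1.0 at period 6 and eases off, mirroring a
delay-locked hemodynamic rise. The central manipulable property is that
trial-to-trial noise depends on the reported confidence side
(σ_high = 0.5, σ_low = 1.0 by default), so scene decodability rises with
confidence; an amplitude-modulation mode is provided instead of the noise
mode because accuracy differences cannot distinguish the two mechanisms.
Incorrect trials carry the *chosen* scene's prototype (scale configurable).
The default amplitude of 2.0 keeps peak-period six-class accuracy well
above chance but far from ceiling, leaving headroom for the confidence
conditions to separate. With amplitude 0 the patterns carry no
label information, which is the calibration null used in testing. Scans
are not simulated volume-by-volume: the generator emits per-period features
directly, while `period_features` (mean of four consecutive 1-s volumes
starting t seconds after delay onset) remains implemented for scan-level
input.

## Decoding

Scene decoding uses the chosen-scene labels with the globally rarest label
removed (ties: lowest label), leaving six classes; confidence and
state-confidence decoding are binary. The classifier is a bundle of
L1-penalized logistic one-vs-rest classifiers (liblinear; fixed penalty
C = 1.0 by default) — a sparsity-inducing probabilistic linear classifier
whose prediction is the class with maximum probability, ties to the lowest
label; the number of features with any nonzero weight is reported.
Cross-validation is leave-one-session-out (plain decoding) or
leave-one-game-out (conditional decoding); in each fold the training set is
randomly undersampled to the minority class size, the classifier retrained,
and the untouched test fold scored — repeated (default 100×, scaled down in
tests) and averaged. The test fold never participates in undersampling,
feature selection, or training. Conditional decoders restrict both training
and testing to one condition (correct/incorrect, reported-confidence side,
model-state-confidence side); subjects with fewer than three training
samples of any scene label in any fold (or an empty condition subset) are
excluded with a machine-readable reason. Condition contrasts use one-sided
rank-sum tests on per-subject accuracies at a given period.

The two-step permutation test builds a group-level null: (i) per subject,
the decoding analysis is repeated with target labels permuted within
sessions (defaults N_sbj = 150, scaled to 30 in tests); (ii–iii) a null
sample is the across-subject mean of one value drawn per subject from its
pool (permutations plus the original), repeated N_group times (default
1000, scaled 200); the original per-subject accuracies are compared with
the null by a one-sided rank-sum test. Undersampling repeats re-enter
training from scratch on every repeat (no reuse of feature selection across
repeats, the leakage-safe reading).

## Pipeline and reproducibility

`run_end_to_end` chains maze → cohort simulation → exclusion → behavioral
statistics → model fitting and AIC selection → filter traces → pattern
generation → plain, conditional and permutation decoding into one JSON+CSV
bundle. One global seed fans out to fixed per-stage substreams, so any
stage reruns identically in isolation; two runs of the same config produce
identical bundles (modulo wall-time entries). Every simulated quantity and
every statistic in the bundle is recomputed at run time.

## Problem sizes used in the test suite

The suite certifies filter exactness on 3×3 fixtures with 6-step games;
parameter recovery and model selection on 20 subjects × 30 games at
θ = (0.9, 0.85, 0.4, 0.5, n = 2) with a 1–3 grid over n and 4 optimizer
starts; behavioral directions on a 15-subject cohort at the default 38 games; decoder
calibration on amplitude-0 patterns (binomial-band check, and 100 null
runs of the 30/200-scaled permutation test on 4-subject binary-target
datasets); and confidence-modulated decodability at the peak period with
5 undersampling repeats. These sizes are the package's reference study
conditions for synthetic work; all of them are configurable.

## Known limitations

The model assumes a perfectly known maze map, graded confidence collapsed
to one bit, and no learning within or across sessions. p_hl is weakly
identified at realistic data scales (see Fitting). The generator's
report/RT models are deliberately simple; conclusions about real data
require the real data. Searchlight analyses, hemodynamic convolution and
real fMRI preprocessing are out of scope.
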