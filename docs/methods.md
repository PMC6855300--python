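# Methods

## Setting and model

A game session is a fixed-duration recording (default 90 s) subsampled to a
frame grid (default 5 frames/s; frame *i* sits at `i / fps` seconds). The
session's meta information partitions the timeline into *prompt regions* —
ordered, non-overlapping intervals, each with a target emotion drawn from a
closed seven-class vocabulary (the six Ekman classes that survive merging
anger with contempt, plus neutral). Frames are abstract timestamped records;
no video decoding or face detection happens anywhere in the package.

The extraction cascade treats the prompt emotion as weak supervision and
sharpens it in three stages:

1. **Boundary selection.** A frame belongs to the region containing its
   timestamp under the convention `[t_start, t_end)`. The written
   formulation of the selection closes both ends of the interval; we use
   half-open intervals deliberately so a frame on a shared boundary belongs
   to exactly one region (the prompt newly on screen). At 5 fps this moves
   at most one frame per region boundary.
2. **Sub-bound trimming.** The leading `α` seconds of a region (the child's
   interpretation lag) and trailing `β` seconds (relaxation, or the face
   leaving the frame during the phone tilt that advances the prompt) are
   cropped: frames with `t_start + α ≤ t < t_end − β` survive. A trim that
   empties a region is legal, not an error.
3. **Minimum confidence.** A frame must have classifier confidence for the
   region's emotion strictly greater than `λ`. `λ = 0` disables the filter
   entirely — including for frames with no score at all — because a
   score-0 or scoreless frame should only be excluded once the user has
   opted into confidence filtering. For `λ > 0`, unscored frames are
   dropped. Scores from several classifiers may first be fused per frame by
   min, max, or unweighted average over the providers that returned a
   vector for that frame; requiring all providers would discard usable
   frames whenever a single provider misses a face.

All densities are computed over frames that *have* a ground-truth label:
unlabeled frames (no face, too blurry) carry no evidence about filter
quality and are excluded from both numerator and denominator.

## The greedy searches and the tradeoff ratio

Both searches optimize one emotion class at a time, pooled over all
sessions, because interpretation lag plausibly varies with prompt
complexity. The boundary search starts at `(α, β) = (0, 0)`; each iteration
scores the two single-axis widenings by

    k = density gain (pp) / frame loss (%)

and accepts the larger-k candidate while `k ≥ 1` (ties widen `α`), stopping
when both candidates fall below 1 or caps are reached. The `λ` search runs
afterwards at the fixed trim, raising `λ` in fixed increments under the
same rule. Step sizes default to 0.2 s (one frame period) for `α`/`β` and
0.01 for `λ`, so all returned parameters land on those grids; caps default
to 2.4 s and 0.5, beyond the range where trims remain sensible — they
prevent pathological full-region trims on degenerate inputs.

Two readings of k are implemented and switchable:

* `baseline_mode` — the reference state is the **previous accepted state**
  (default) or the initial one. With an initial-state reference the search
  keeps accepting long after a step stops paying for itself, because the
  accumulated gain dominates any new loss; the previous-state reference
  stops exactly when the marginal step fails, which is what a
  terminating-condition reading of `k < 1` requires.
* `loss_denominator` — frame loss is measured over **matching (relevant)
  frames** (default) or over all retained frames. Counting all retained
  frames makes the ratio degenerate: removing *only* mismatched frames then
  yields `k = candidate density`, so no step is ever accepted below perfect
  purity. Counting matching frames makes the removal of pure noise free
  (`k = +∞`) and prices a step by the relevant frames it sacrifices.

The defaults are the combination under which the search recovers known
generator parameters (see below) and under which observed per-class optima
of the kind the method is meant to produce are reachable at realistic
densities. The pure function `tradeoff_ratio(base, cand)` defaults to the
all-retained-frames loss, since in isolation "frame loss" most naturally
means total frames; the optimizers pass their own default explicitly.

An exhaustive grid oracle (`exhaustive_grid_oracle`) brute-forces density
and retention at every grid point. The test suite replays every greedy
accepted step against it, confirming `k ≥ 1` per step and `k < 1` at
termination — the greedy path is exactly the sequence of states the oracle
says it is.

Degenerate inputs: an emotion with no region, a region set with no
ground-truth frames, and a `λ` search with no scored frames are errors; a
class that is already pure (or hopeless) returns zero trims because no
candidate can post a density gain.

## Ground truth and reliability

Consensus labels come from exactly two raters (the design the method was
validated with): a frame is *valid* when both raters assigned a label, and
enters the consensus only when the labels agree. Percent agreement is
`100 · trace / total` of the rater-vs-rater confusion matrix over valid
frames; Cohen's κ is `(p_o − p_e) / (1 − p_e)` with the usual marginal
chance correction (κ = 1 by convention when a single identical label was
used throughout). Both statistics are invariant to label ordering, and κ is
cross-checked against scikit-learn's implementation in the tests. Display
rounding is half-up to one decimal; internal values are never rounded.

## The synthetic generator

`SimulationConfig` emulates the data-generating process the cascade
assumes:

* regions tile `[0, duration]` with i.i.d. uniform durations (default
  3–10 s, ~12 prompts per 90 s session; the minimum is set so that no
  class's lag + decay can swallow a whole region), emotions sampled by
  weight (default uniform over the seven classes);
* during the onset lag `L_c` the child still shows the *previous* region's
  emotion with probability 0.5, else neutral (first region: neutral) —
  the face transitions from a typically neutral or leftover expression;
* during the trailing decay `R_c` the face is neutral;
* in the interior the target emotion appears with probability
  `p_express = 0.8`, else a confusion-weighted off-target label
  (neutral-heavy by default, weight 3 vs 1);
* any frame is unlabelable with `p_invalid = 0.12` — the fraction of
  frames the study's raters could not label (165 of 1350);
* per-class defaults for `L_c`/`R_c` are the per-class optima observed in
  the study's sessions (0–2.2 s), so default sessions exhibit realistic
  class-dependent lag structure.

Classifier scores are Dirichlet draws with concentration `1 + c` on the
true label and 1 elsewhere, so the true label's expected score
`(1 + c)/(7 + c)` strictly dominates every other label's `1/(7 + c)` for
any `c > 0` (the calibration threshold is 0); `c = ∞` yields exact one-hot
vectors, and unlabelable frames get exchangeable vectors. The three default
providers are deliberately miscalibrated relative to one another — sharp
(`c = 6`, 5% miss), moderate (`c = 3`, 10% miss, scores written on a 0–100
dialect), diffuse (`c = 1.5`, 15% miss) — to exercise fusion and dialect
normalization. One global seed feeds independent per-stream generators
(`SeedSequence` spawn keys per session and per provider), so adding a
provider never perturbs session structure and every bundle is bit-for-bit
reproducible.

What the generator does **not** model: correlated rater errors (synthetic
annotations are a perfect rater pair, so synthetic κ is 1 by construction),
within-region autocorrelation of expression beyond the three windows,
subject-level variation, prompt-difficulty effects, or classifier errors
correlated across providers. Passing tests on synthetic data therefore
demonstrate the *mechanics* of the cascade — selection identities,
monotonicity, greedy-path legality, parameter recovery under the stated
noise — not field performance on real children's video, which depends on
how well real lag/decay/expression behavior matches these assumptions.

## Problem sizes used in the checks

The oracle-equivalence checks run five seeded four-session bundles against
a 13 × 13 trim grid and a 51-point λ grid. Parameter recovery uses ten
replicates of twenty sessions with a uniform 0.6 s lag and 1.0 s decay and
`p_express = 0.97`, requiring recovery within one 0.2 s step in at least
90% of replicates; recovery is evaluated on a non-neutral class because for
the neutral class the lag and decay windows themselves look neutral, making
the trims unidentifiable (visible in the worked example, where neutral
keeps zero trims). The acceptance script's synthetic study uses twenty
default-condition sessions (~9,000 region frames). With a single
default-condition provider the λ search often returns 0 — dropping that
provider's 5% missed frames costs more matching frames than low-score
mismatches it removes — while ensemble-fused scores, where simultaneous
misses are rare, support positive λ; this mirrors the intended robustness
argument for fusion.

## Numerical conventions

Interval membership uses an absolute slack of 1e-9 s (five orders below a
frame period) so grid timestamps like 0.6 = 3 × 0.2 compare exactly;
accepted trims and λ values are re-rounded to their step grid to avoid
drift. Merged provider categories (anger + contempt) sum and cap at 1.0,
treating scores as probabilities of a union event. Unknown provider score
keys warn and are ignored (provider APIs grow categories over time);
unknown *rater* or *meta* vocabulary is a hard error, since ground truth
must stay within the closed label set.
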