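# Methods

This note documents the models, conventions and numerical choices
behind `fidgetpose`, in the spirit of a statistical package's methods
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and data model

The unit of analysis is a **snippet**: 250 frames (5 s at 50 fps) of a
25-joint 2D skeleton in the BODY_25 layout (0 = Nose, 1 = Neck,
8 = MidHip, …, 24 = RHeel), each joint carrying an image-pixel (x, y)
and a tracker confidence in [0, 1]. A joint with confidence below 0.05
is treated as missing (the threshold is configurable; trackers report
near-zero confidence for occluded joints, and exact semantics of the
confidence score vary between tracker versions). Coordinates are
0-based pixels with y growing downward. Each snippet belongs to one
participant and carries one of the labels FM+ (fidgety movements
present), FM− (absent), not-assessable, or unlabeled.

Inputs at other frame rates are resampled to 50 fps by per-coordinate
linear interpolation. Missingness is never interpolated across: an
output frame bracketed by a frame in which a joint is missing leaves
that joint missing. Sequences are cut into consecutive non-overlapping
250-frame snippets; a trailing remainder is dropped and logged.

## Normalization

Per snippet: every frame is translated so the mid-hip joint is at the
origin, and all coordinates are divided by the snippet-median trunk
length (neck ↔ mid-hip distance over frames where both are present).
The scale is **per snippet**, not per frame, deliberately: per-frame
scaling would divide out part of the within-snippet motion amplitude,
which is the classification signal. Missing joints are set to exactly
(0, 0) *after* the transform, so zero encodes "missing" rather than a
location; the mid-hip itself is (0, 0) by construction whenever it is
used as the anchor, an accepted collision documented here. When the
anchor is missing in a frame the snippet-median anchor position is
used; when the trunk joints are never jointly present the scale falls
back to the snippet-median bounding-box diagonal of the confident
points; a snippet without at least two confident points in any frame is
rejected as unusable.

This normalization is exactly invariant to isotropic scaling plus
translation of the raw pixels (the camera model of the synthetic
generator). It is *not* invariant to rotation; rotational variation is
out of scope, matching a fixed overhead-camera recording geometry.

## Feature vectors

Window geometry: windows start at frames 0, N_slide, 2·N_slide, …, and
a window covers N_stack frames; trailing partial windows are dropped,
giving `floor((T − N_stack)/N_slide) + 1` windows when T ≥ N_stack.
The vector layout is frame-major, joint-major, (x, y) within a joint —
an arbitrary but fixed order recorded in checkpoint sidecars so saved
models remain portable. Defaults N_stack = 52 and N_slide = 12 are the
tuned optima; they give 17 windows of 2600 values per snippet, each
spanning 1.04 s. Windows never cross snippet boundaries. Each window
inherits its snippet's label for training; windows are classified
independently at inference.

## Classifier

Nine shallow dense architectures are provided, with 1–3 hidden layers
of 50/100/200 units. The first hidden layer uses ReLU; later hidden
layers use PReLU with one learned slope per layer initialized at 0.25
(its originating convention); 20% inverted dropout acts between hidden
layers in the multi-layer architectures, during training passes only;
the output is a single sigmoid unit. The loss is binary cross-entropy —
the canonical pairing with a sigmoid output (the loss choice is
recorded in checkpoint metadata). Optimization is Adam with
bias-corrected moments, α = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8,
mini-batches of 3968 windows (tuned value), per-epoch seeded shuffling.
Weights are He-initialized from a seeded generator; biases start at 0.
Everything is plain numpy; training and inference are deterministic
given the seeds.

"Convergence" is operationalized as early stopping: training stops when
the validation loss has not improved for `patience` epochs (default 20,
maximum 500 epochs, both configurable), and the parameters from the
best validation epoch are returned. Without a validation set, training
runs to `max_epochs`. A practical numerical note: the stacked-position
features carry a large constant offset (the base posture repeated 52
times), so full-batch Adam at α = 0.001 spends its first few hundred
steps traversing a plateau before the loss drops. Runs on small
synthetic cohorts therefore use generous epoch budgets (250–800 epochs)
and a patience of 60–100; with mini-batches much smaller than the
training set, or real-scale data, fewer epochs suffice. Default
patience 20 is appropriate when an epoch contains many updates.

Snippet classification is a uniform majority vote over the window
probabilities thresholded at 0.5: the class with strictly more votes
wins. With 17 windows a tie is impossible; for even window counts an
exact tie resolves to FM− — absence of fidgety movements is the
clinically conservative flag — and is logged. The tie rule and
threshold are configurable.

## Dataset splitting

Snippets of one participant must land in exactly one set per fold
(identity leakage across train/test inflates scores). Balancing snippet
fractions per set *and per class* with participant-atomic items is a
multi-way knapsack problem, solved by a genetic algorithm over
integer chromosomes (one gene per participant = set index): tournament
selection (size 3), uniform crossover (p = 0.9), per-gene mutation
(p = 1/n_participants), elitism 2, population 200, 300 generations —
standard GA practice, all exposed via `GAParams`. Fitness is the sum of
squared deviations between achieved and target snippet fractions over
every (set, class) cell. The canonical protocol carves out ~25% of
snippets as a validation set, then builds five independent train (~2/3
of the remainder) / test (~1/3) splits; folds are independent GA runs
with distinct seeds, so participants may recur across folds but never
across sets within a fold. If a target fraction is missed by more than
5 percentage points the best-found plan is returned with a warning.

## Hyperparameter sweeps

One parameter at a time — batch size, then N_stack, then N_slide —
is swept over a grid while the others stay fixed, each candidate scored
by training to convergence and measuring snippet-level TPR and FPR on a
participant-disjoint validation set. The selected value minimizes the
distance to the perfect ROC corner, d = √((1 − TPR)² + FPR²), with
ties broken toward the smaller value. Default grids (batch ∈ {256 …
8192}, N_stack ∈ {13, 26, 52, 104}, N_slide ∈ {6, 12, 25, 50}) are
reconstructions that include the tuned optima; the sweep architecture
defaults to the two-hidden-layer network 5.

## Evaluation

FM+ is the positive class. From confusion counts (kept as reals so fold
means are representable): sensitivity(FM+) = TP/(TP+FN),
sensitivity(FM−) = specificity(FM+) = TN/(TN+FP), precision per class,
accuracy, per-class F1, TPR/FPR. A zero denominator yields NaN (an
explicit undefined marker) rather than an exception, so fold
aggregation can skip undefined cells. Cross-validation reports
per-fold metrics and their across-fold mean and SD (the per-fold
TP/FP/FN/TN means are also reported, from which the ratio-of-mean-counts
reading can be derived; on the checked worked examples the two readings
agree at 2 decimals). Architecture comparison uses a two-sided t-test
on per-fold accuracies — Welch (unequal variances) by default as the
safer choice, Student's pooled variant by flag. Display rounding is
half-up at 2 decimals.

Rater machinery: Cohen's κ = (p_o − p_e)/(1 − p_e) restricted to the
FM+/FM− classes (pairs containing other labels are dropped and
counted); if both raters are constant and identical, κ is defined as 1.
The consensus filter excludes a snippet if *either* rater marked it
not-assessable (checked first), then if the raters disagree; only
unanimously labelled FM+/FM− snippets survive.

## Synthetic cohorts

The generator exists because the underlying clinical videos are
confidential; it emulates just enough structure to exercise every
pipeline stage. A fixed supine template (trunk length 1, limbs flexed)
is perturbed by band-limited oscillations: per joint, a sum of two
random-phase sinusoids with frequencies drawn from the class's band,
pointing along a direction that re-randomizes as a Poisson process,
plus Ornstein–Uhlenbeck jitter (timescale 0.2 s) supplying the
"variable acceleration" character; a shared component mixed in
proportion to `inter_joint_correlation` couples the joints; an
exponential on/off bout process gates activity at the class's duty
cycle. Distal joints swing more than the trunk via a fixed per-joint
amplitude profile.

Class defaults (conventions, not clinical measurements):

| parameter | FM+-like | FM−-like |
|---|---|---|
| amplitude (trunk lengths) | 0.04 | 0.15 |
| frequency band (Hz) | 1–3 | 0.2–0.7 |
| direction changes (/s/joint) | 2.0 | 0.2 |
| inter-joint correlation | 0.15 | 0.9 |
| duty cycle | 0.8 | 1.0 |

Per participant, a camera transform (uniform scale 80–320 px per trunk
length, offset 0–500 px) is constant across snippets; per frame-joint,
i.i.d. dropout (default 2%) zeroes the joint; retained confidences are
Uniform(0.5, 1). Labels are per-snippet Bernoulli draws at the cohort's
FM+ share (default 53.6%, 45 participants × 40 snippets). Seed streams
are structured per (cohort seed, participant, snippet), so cohorts
differing only in camera ranges contain identical motion, labels and
dropout — the basis of the feature-invariance tests.

What the generator does **not** model: articulated limb kinematics
(joints move as perturbed points, not a linked chain), tracker failure
modes beyond i.i.d. dropout (no identity swaps, no correlated
occlusions), rotation or perspective, writhing-specific waveforms, or
any quantitative FM kinematics — none are published as numbers. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline's
machinery is correct and that the classifier can recover a known
class structure from stacked positions; they are not evidence of
clinical performance on real infants.

## Problem sizes in tests and the acceptance script

Synthetic runs use deliberately small cohorts — 6–16 participants with
4–12 snippets each — chosen as the smallest sizes at which the
participant-disjoint protocol is meaningful and the classes are
recovered reliably; the end-to-end acceptance run uses 16 participants
× 12 snippets (≈ 3,260 windows of 2600 values) with training to at
most 800 full-batch epochs under patience-100 early stopping. GA
property tests run the solver at reduced population/generations through
`GAParams`, which cannot affect the disjointness and conservation
invariants they check.

## Known limitations

* The 0.05 missing-confidence threshold is a convention; the original
  tracker semantics ("not correctly identified → zero-filled") are
  reproduced but the exact cutoff is a guess, hence configurable.
* Zero-filling after normalization conflates "missing" with the anchor
  position; harmless for dense networks reading fixed slots, documented
  for anyone swapping in another model class.
* Rotation of the camera is not normalized away.
* Fold means of ratio metrics vs ratios of mean counts differ in
  principle; both views are derivable from the report.
* The GA returns the best assignment found, not a certified optimum;
  on small instances it matches exhaustive search (tested), on large
  ones only the random-restart bound is guaranteed.
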