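# Methods

`ssokd` builds compact image+tabular classifiers in two stages: knowledge
distillation from a large "teacher" fusion network into a small "student",
followed by discrete swarm optimization of the student's head
hyperparameters. This note records the models, the defaults and why they
are what they are, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## The fusion classifier

Each sample is a grayscale lesion ROI plus a 44-feature tabular vector.
The classifier has two branches:

* **Image branch**: convolutional feature extractor → global average
  pooling → dense(`cnn_neurons`) → ReLU → dropout(`cnn_dropout`).
* **Tabular branch**: dense(`dnn_neurons`) → ReLU → dropout(`dnn_dropout`).

The branch outputs are scaled by the fusion ratio — image features by
`image_weight` (written w below), tabular features by 1 − w — then
concatenated and passed through dense(`fused_neurons`) → ReLU →
dropout(`fused_dropout`) → a two-logit head. The softmax of the two logits
gives P(malignant); hard labels threshold at 0.5, with a probability of
exactly 0.5 classified positive. Two logits rather than a single sigmoid
unit are used because the distillation losses compare class-logit vectors
under a temperature; for binary cross-entropy training the two forms are
equivalent.

Scalar multiplication of each branch's feature vector before concatenation
is the simplest mechanism consistent with a "fusion ratio between image and
tabular features" and preserves dimensionality; the ratio reaches the loss
only through the learned weights of the fused layer, so w = 0 makes
predictions exactly invariant to the image input (asserted in tests by
permuting images at fixed tabular features).

Seven integers encode the head architecture for the optimizer: three
neuron counts in [1, 512], three dropout percents in [1, 99] and the
image-fusion percent in [1, 99]; decoding divides percents by 100.

### Backbones

Four desk-scale extractors ship in the registry (NHWC, 3×3 valid
convolutions, 2×2 max pooling, global average pooling):

| name | blocks | channels | features |
|------|--------|----------|----------|
| `tiny-small` | 2 | 4, 8 | 8 |
| `tiny` | 2 | 8, 16 | 16 |
| `tiny-deep` | 3 | 8, 16, 24 | 24 |
| `tiny-wide` | 3 | 16, 32, 48 | 48 |

The wide/deep variants play the teacher role, the small ones the student.
Pretrained ImageNet backbones would plug into the same registry surface but
are deliberately off the test path. Note the three-block extractors need
inputs of at least 18×18. All layers, losses and the Adam optimizer are
implemented in NumPy with explicit forward/backward passes; gradient
correctness is checked against central finite differences in the test
suite.

### Training

Adam at learning rate 1e-3, batch size 8, cross-entropy loss, early
stopping on validation loss with patience 4, plateau learning-rate
reduction (factor 0.2, patience 2, floor 1e-4), and restoration of the
best-validation-loss weights at the end. All initialization, shuffling and
dropout randomness derives from a single seed, so runs are bit-reproducible.

## Knowledge distillation

The student minimizes `L = α·L_soft + (1−α)·L_hard`, where `L_hard` is
cross-entropy against the one-hot label and `L_soft` is cross-entropy
between the teacher's and student's temperature-softened distributions
(logits divided by T before the softmax). No 1/T² gradient rescaling is
applied to the soft term, so α is interpretable as the literal mixing
weight. The gradient of the batch-mean loss w.r.t. the student logits is
`α·(q_T − p_T)/T + (1−α)·(q_1 − c)`, implemented in closed form.

Defaults: **α = 0.9, T = 5**. The high soft-loss weight reflects the regime
the method targets — a teacher clearly stronger than the student — where
most of the transferable signal is in the teacher's soft targets; at
α = 0.5 the effect on the synthetic task was within test-set quantization
noise. Both values are exposed in `KDConfig`; α = 0 recovers plain
hard-label training exactly (asserted in tests: with the same seed, the
α→0 student equals the baseline student).

**Comparability test.** Teacher and student are retrained over n seed
replicates (default 5); the paired per-seed test-accuracy lists feed a
two-tailed paired t-test of equal means. The student is "comparable" when
p ≥ α/2 = 0.025. Zero variance of the paired differences is reported as a
degenerate-test error rather than silently passed. The replicate structure
(re-training with paired seeds, rather than bootstrapping over test items)
is this package's documented choice.

**Selection.** Among comparable students the one with the highest mean
post-distillation accuracy is selected; ties break toward fewer parameters
(the point of the exercise is lightweighting). If no student is comparable
the highest-accuracy one is selected with a warning.

## Simplified Swarm Optimization

Particles are integer vectors. Per update, every variable independently
becomes the global best, the personal best, itself, or a fresh uniform
random value within bounds, according to where a uniform draw ρ falls in
the cumulative partition (0, Cg, Cp, Cw, 1) — in that order: gbest, pbest,
current, random. One ρ is drawn per variable per update; all variables are
updated before the fitness is evaluated (full-variable update). Positions
are never rejected; memory lives only in pbest/gbest, which are replaced
on strict improvement, making the gbest trace monotone non-decreasing.
gbest starts at 0.0 (fitness is an accuracy, so 0 is a safe floor); if no
initial particle exceeds it, the first particle is recorded as the
incumbent so the result is always well-defined.

Random replacement draws a uniform integer over the variable's bounds.
Stage-2 fitness is the **validation** accuracy of the decoded model with
the student's feature extractor frozen (features are precomputed once, so
each evaluation trains only the dense heads); the test split is touched
exactly once, at final reporting. Fitness evaluations are cached per
solution — the evaluation is deterministic given the solution, so the
cache is exact, and repeated gbest copies cost nothing.

### Capability on the toy landscape

The built-in toy landscape is separable with a unique known maximizer:
`0.5·mean(x_j = t_j) + 0.5·(1 − mean |x_j − t_j|/width_j)`. The match term
rewards locking individual variables (which pbest/gbest copying
propagates); the distance term provides a gradient from anywhere. On
[1, 8]⁷ with a 310-evaluation budget (10 particles, 30 generations) the
optimizer reaches the exact optimum in roughly 85% of runs at
(Cg, Cp, Cw) = (0.4, 0.75, 0.8) — the best of a broad parameter scan — and
in roughly 65% at more exploratory settings. Exact assembly of all seven
coordinates is the bottleneck: positions are never rejected, so a correct
random hit survives only if the whole updated solution improves that
particle's personal best. This capability figure is measured, not assumed;
the test suite asserts majority-of-seeds convergence and a consistent
advantage over pure random search at equal budget, and the known gap to a
higher reliability bar is deliberate and documented rather than patched by
easing the problem.

### Interval-design harness

`intervals_from_probabilities` converts an action-probability allocation
into cumulative bounds; `level_experiment` runs repeated optimizations per
parameter level with disjoint seeds and emits the per-level best/mean plus
raw groups for a one-way ANOVA (hand-computed sums of squares; p from the
F distribution; cross-checked against `scipy.stats.f_oneway`).

## Preprocessing

* **White-border crop**: from each edge inward, contiguous rows/columns
  whose fraction of pixels at ≥ 95% of the *valid intensity range* exceeds
  0.90 are removed. Anchoring the threshold to the valid range (not the
  per-image maximum) makes the crop idempotent. Cropping everything raises
  a degenerate-input error.
* **Non-local means** via scikit-image (`patch 7`, search window 21,
  filter strength h = 0.8 × estimated noise sigma when unset). Constant
  images are fixed points.
* **CLAHE** via scikit-image over an 8×8 tile grid; the clip limit uses the
  OpenCV convention and is divided by 256 bins for scikit-image. Constant
  images are returned unchanged (there is no contrast to equalize).
* **Resize + standardize**: resize to the target shape (default 75×75×3;
  the desk-scale workflow uses 32×32×1), replicate grayscale across
  channels, scale to [0, 1], then z-score with dataset-level moments fitted
  on the training split only and reused for validation/test (leakage
  guard; two-pass contract).
* **Tabular encoding**: fixed 44-column layout — three ordinals (breast
  density, BI-RADS, subtlety) then 21 shape indicators and 20 margin
  indicators, alphabetical within blocks with UNKNOWN last. Missing
  shape/margin values map to UNKNOWN; each indicator block sums to exactly
  1 per row. Pathology merges to binary with benign-without-callback
  counted as benign.

## Splitting and augmentation

Per class, `floor(0.8·n)` samples go to training; the remainders are dealt
one at a time to validation or test by largest remaining global deficit
(ties to test), processed in label order. For a 912+784 dataset this
reproduces 1356/170/170 with validation 91+79 and test 92+78. Within each
class the order is shuffled by seed over a content-based key, so the split
is invariant to input ordering. Augmentation quadruples the training split
only: original, horizontal flip, vertical flip, and one random k·90°
rotation with k uniform on {1, 2, 3}.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* of a curated
mammography mass collection: a 0.54:0.46 benign:malignant ratio; two image
classes differing in lesion geometry (benign = one smooth isotropic
Gaussian blob; malignant = 3–6 anisotropic, randomly oriented blobs whose
superposition creates an irregular margin); optional saturated white-border
artifacts; additive Gaussian pixel noise (default sd 0.25 on a [0, 1]
scale, chosen so desk-scale models land in the 75–100% accuracy band
rather than saturating — mirroring the difficulty regime of real ROI
classification); ordinal severity fields (BI-RADS, subtlety) whose
distributions are tilted by a log-odds gradient toward higher categories
for malignant cases; fixed label-independent shape/margin category
distributions with missingness at 4/1696 and 60/1696; and per-sample RNG
streams derived from (seed, index) for bitwise reproducibility and
single-sample regeneration.

It does **not** emulate mammographic texture, acquisition physics, scanner
or view effects, inter-field correlations (e.g. shape–margin dependence),
or patient-level structure. Passing tests therefore demonstrate that the
machinery — preprocessing, distillation, optimization, selection — behaves
as specified on data with the right gross statistics; they say nothing
about clinical performance.

## The directional experiments

Two protocols state the package's end-to-end claims in falsifiable form;
both run once per seed and count per-seed outcomes.

* **Distillation benefit** (`kd_benefit_experiment`): n = 1000 samples,
  no augmentation, 10 epochs, with 25% of *training and validation* labels
  flipped (annotation noise; test labels stay clean). Teacher: `tiny-wide`
  with (64, 20, 64, 20, 64, 20, 50) heads. Student: `tiny-small` with the
  (10, 20, 40, 20, 100, 20, 50) baseline heads — deliberately
  capacity-limited, since a student that can match the teacher on its own
  leaves distillation nothing to transfer. The distilled student is
  compared with an identically seeded hard-label student. Measured: strict
  wins in ~18/20 seeds, mean test-accuracy gain ≈ +3 to +6 points.
* **Stage-2 benefit** (`stage2_benefit_experiment`): n = 600, clean
  labels, distill a `tiny` student, freeze its extractor, swarm-optimize
  the seven head variables (4 particles, 4 generations, validation-accuracy
  fitness), compare final test accuracy against the stage-1 student. A tie
  counts as a success: the optimizer must do no harm. Measured: 18/20
  seeds. Annotation noise is deliberately absent here — with noisy
  validation labels, model selection decorrelates from clean-test accuracy
  and the comparison measures label noise, not the optimizer.

Problem sizes (n = 1000/600, 10 epochs, 10 seeds) are the package's chosen
study conditions: large enough that test-split accuracy resolves 1-point
differences, small enough to run on one CPU in minutes.

## Numerical and degenerate-input choices

* Dropout is inverted (scaled at train time), so inference is a pure
  forward pass.
* Softmax uses max-subtraction; cross-entropies clip probabilities at
  1e-300 before the log.
* Max-pool gradients split evenly across tied maxima, conserving gradient
  mass.
* Images write to 16-bit PNG; round-trips are exact to 1/65535.
* Precision/recall with a zero denominator surface as an explicit
  undefined flag (`None`), never as 0, so aggregates cannot silently
  average in zeros.
* Compression rate is `100·(1 − student/teacher)` parameters, rounded to
  two decimals; a student larger than its teacher yields a negative rate
  with a warning rather than an error (at desk scale, SSO-chosen heads can
  outweigh a tiny teacher).
* The ANOVA reconstruction path accepts printed (rounded) sums of squares;
  reconstructed p-values can differ from a published table in the third
  decimal for exactly that reason.

## Known limitations

* The NumPy networks are CPU-only and unbatched across workers; they are
  sized for method validation, not throughput.
* Exact toy-optimum convergence reliability is ~0.85 per seed at the
  310-evaluation budget (see above), a property of full-variable SSO with
  uniform random replacement rather than of this implementation.
* The comparability t-test inherits the usual small-sample caveats at the
  default 5 replicates; it is a screening rule, not a calibrated
  equivalence test.
* DICOM input and pretrained backbones are out of scope; the registry and
  manifest formats are the intended extension points.
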