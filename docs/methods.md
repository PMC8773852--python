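# Methods

This note documents the models, numerical choices and limitations of the
package, in the order data flows through it.

## Synthetic 12-lead generator

Every stage is testable offline because the generator produces controllable
signals with known ground truth.  A beat is modelled as a sum of Gaussian
bumps (P and T waves) and a narrow biphasic spike (QRS: a positive R bump at
the apex plus a negative S bump 28 ms later), sampled on a 256-point window at
250 Hz with the R apex at index 127.  Per-lead amplitudes follow conventional
QRS polarities (aVR, V1, V2 predominantly negative), so leads are
distinguishable after z-scoring.  Continuous records repeat the cycle at the
requested heart rate and add a slow sinusoidal baseline wander plus white
noise; the planted R-apex indices are stored as ground truth.

Class signatures: each MI subcategory perturbs the morphology only on the
leads of its anatomical territory — anterior V3/V4 (AMI), antero-septal
V1–V4 (ASMI), antero-lateral V3/V4 + I/aVL/V5/V6 (ALMI), inferior II/III/aVF
(IMI), infero-lateral II/III/aVF + lateral (ILMI).  The perturbation kinds are
ST elevation (a smooth plateau 40–160 ms after the R apex), Q deepening (a dip
just before the apex) and T inversion (the upright T pushed below baseline);
kinds are assigned per class so that classes with overlapping territories
remain distinguishable by morphology.  Default magnitude is 0.3 × the
per-lead QRS amplitude — strong enough for small-sample attention-recovery
experiments, configurable.  OMI, a catch-all for under-represented infarct
locations, gets a half-magnitude perturbation on a random 2-lead subset drawn
per seed.  Patients are dealt round-robin to classes and each patient carries
exactly one class, so patient-wise splits are class-pure by construction.

What the generator does **not** emulate: rhythm variability and arrhythmia,
beat-to-beat morphology drift, within-class patient heterogeneity (all
patients of a class share one template), electrode artifacts, and the
continuum of real infarct presentations.  Passing tests therefore demonstrate
that the machinery is correct and that the attention/search mechanisms recover
planted structure — not that real-database accuracy would reach similar
levels.  In particular, because same-class patients are statistically
identical, inter-patient splits here check the *structural* guarantee, not
robustness to patient shift.

## Preprocessing

Records are downsampled to 250 Hz with a polyphase antialiasing filter
(output length `round(T·250/fs)`; only downsampling is supported).  Each lead
is then filtered with an 8-level Daubechies-6 wavelet decomposition: the
level-8 approximation band (< ~0.5 Hz — baseline wander, including any DC
offset) and the level-1 detail band (> ~62.5 Hz — high-frequency noise) are
zeroed before reconstruction.  The wavelet family is fixed; the decomposition
depth and the detection lead are configuration-exposed since reasonable
alternatives exist.

R-peaks are detected on lead II (the conventional rhythm lead) by a built-in
energy detector: 5–20 Hz band-pass, derivative, squaring, 150 ms
moving-window integration, a fixed-fraction threshold (30 % of the maximum)
with a 300 ms refractory distance, then apex refinement as the band-passed
extremum within ±100 ms.  Any detector with the `(signal, fs) -> sorted
indices` contract can be substituted.  A flat signal yields an empty list,
not an error.

Segmentation keeps the inclusive window `[r−127, r+128]` (256 samples);
windows crossing a record boundary are dropped rather than padded, because
padding would distort the subsequent z-score.  Z-scoring is per lead,
`z = (x − µ)/δ` with the population standard deviation; a lead with
δ ≤ 1e−8 raises a degenerate-beat error naming the lead.  Indexing is
0-based throughout.

## Branch networks

Each lead has its own residual 1-D CNN of exactly 17 convolutional *basic
units* (convolution → batch normalization → ReLU).  The concrete topology —
the published description fixes only the unit count — is: unit 1 a kernel-7
stem; units 2..17 as 8 residual blocks of two kernel-3 units, the shortcut
joining the block input to the second unit's output before its ReLU;
temporal stride 2 at units 5, 9 and 13; full-scale channel widths
[32×4, 64×4, 128×4, 256×5].  Shortcuts are parameter-free (temporal
subsampling plus zero-padded or truncated channels) so that a census of
convolutional layers in any built branch is exactly 17.  All of this is
overridable through the width plan.

Branches are trained **separately**, one per lead, as 7-way classifiers over
the six MI subcategories plus HC — a feature-learning strategy, not the final
diagnosis — with a softmax head (the alternative, seven sigmoids, is not
used).  The loss is the weighted cross-entropy
`−Σ_i ω_i [y_i log p_i + (1−y_i) log(1−p_i)]` (written here with the leading
minus so it is minimized; probabilities clipped at 1e−7), with
inverse-frequency weights `ω_i = N/(c·N_i)` so rare classes are not ignored.
Optimization is SGD with momentum 0.9, initial learning rate 0.1 divided by
10 every 10 epochs, batch 128, 30 epochs (the full-scale profile, kept as a
named configuration).

The **desk profile** — width 16 for all units, learning rate 0.05, batch 32,
5 epochs — is the package default for laptop-scale runs, the examples and the
test suite.  It was sized as the smallest schedule at which the branch
features make the synthetic 7-class task linearly separable at the top level;
below it (e.g. 3 epochs at width 8) the 7-way branches underfit and
downstream heads cannot fit even their training fold.

After training, a **feature bank** caches the globally averaged activation of
every lead at every even level plus the top level (9 levels), for every beat.
One forward pass per lead serves all levels.  The GA then never retrains a
branch: each fitness evaluation only trains a small LSE head on cached
features.

All layers (convolution via sliding windows, batch normalization, pooling,
linear) carry explicit analytic backward passes; a numeric gradient check on
a small branch is part of the test suite.

## LSE head

The squeeze stage is two-level: branch features are already time-pooled per
level, and the per-lead squeeze `u_i` is the mean of that pooled vector —
this is what makes `u` 12-dimensional, as the gate weights
`W1 ∈ R^(12/r)×12`, `W2 ∈ R^12×(12/r)` require.  Excitation
`e = sigmoid(W2 relu(W1 u))` is computed per beat (input-dependent
attention), with reduction factor r = 1 by default; biases are included and
zero-initialized.  Scaling is `o_i = e_i·y_i`, and a final fully-connected
layer produces softmax class probabilities or a sigmoid positive-class
probability in binary mode.  Training uses Adam (learning rate 0.01, batch
32, 30 epochs) on the same weighted cross-entropy; `epochs = 0` returns the
freshly initialized model, which is the ablation baseline's starting point.

Forcing `e = 1` makes the head exactly a concatenation + fully-connected
classifier — the conventional MBN summarizer — and is used for ablation
comparisons; in that mode the gate weights receive no gradient.

Mean excitations over a beat set report per-lead attention.  On the synthetic
inferior-MI task this recovers the planted leads in the large majority of
seeded runs, *provided the branches are trained*: with random (untrained)
branch features the gates saturate arbitrarily and recovery fails — the
attention analysis is only meaningful on top of learned features.  At desk
scale the recovery criterion is met in 4 of 5 seeds; occasional failures at
this scale are expected noise.

## Architecture search

Genomes, operators and the loop are exactly the protocol summarized in the
README.  Numerical and procedural choices where the protocol leaves latitude:

* Accuracy enters the fitness on the [0, 1] scale; on the percent scale the
  β term would dominate the F1 term, inverting the stated priority of
  performance over complexity.
* Offspring count is `pop_size − n_parents` (= 90), generated by ⌈90/2⌉
  crossovers of uniformly drawn distinct parent pairs; one surplus child is
  discarded when the count is odd.
* Mutation applies to offspring only, never to the retained parents, so the
  population's best fitness is non-decreasing (asserted on every run).  A
  reset that lands on the element's current value still counts as one of the
  k mutated elements.
* Selection ties break by smaller depth sum, then insertion order.
* The evaluated initial population counts as generation 1 toward the
  10-generation cap; the early stop fires when the maximum fitness is
  unchanged (within 1e−12) for 2 consecutive generations.
* Fitness evaluations are memoized per genome; an evaluator exception floors
  that individual's fitness at −∞ with a logged warning.
* The LSE-training evaluator carves a patient-wise 80/20 fit/validation split
  from the training fold once, shared by all genomes; per-genome seeds derive
  from a CRC of the genome so evaluation is deterministic given genome and
  run seed.  F1 is macro-averaged for multiclass tasks and positive-class for
  binary ones.

A caveat observed in controlled experiments: once the parent pool converges,
crossover produces mostly duplicate offspring (memoized, so cheap, but
uninformative), and exploration rests on the reset-to-extremes mutation.  On
smooth landscapes with mid-valued optima the protocol therefore beats an
equal-scale 1000-sample random search in roughly nine out of ten seeded runs,
not always — the comparison test asserts the win *rate*, estimated over 80
seeded replicates, rather than a single 5-seed draw.

## Diagnosis pipeline

Detection collapses all MI subcategories to one positive class.
Localization covers the five location subcategories plus HC — OMI
participates in branch training (7-way head) but is excluded from
localization, since it is not a single location — in either of two modes: a
single multiclass head, or a group of one-vs-rest binary heads whose
prediction is the class with maximum positive probability, ties broken by the
fixed class order [HC, AMI, ASMI, ALMI, IMI, ILMI].  In the binary-group mode
the GA runs once per class, giving one genome per class.

Metrics are one-vs-rest Sen, Spe, Ppv and Acc in percent and
F1 = 2·TP/(2·TP+FP+FN) (equivalently the harmonic mean of Sen and Ppv) on
the fractional scale; the mean row is the unweighted average over classes,
overall accuracy is the confusion-matrix trace over the total.  A class with
no positive samples is reported as missing and excluded from means with a
warning.  Accuracy is beat-level, pooled across folds via the elementwise sum
of fold confusion matrices.

Cross validation partitions *patients*, stratified by class so every class
appears in every fold; the no-overlap guarantee is asserted structurally on
every split.  Architecture transfer freezes the branch weights (checksummed
before and after), rebuilds the feature bank on the target dataset, reuses
the learned genomes verbatim and retrains only the LSE heads.

At desk scale the separable detection task saturates, so the ablation
comparison (GA + LSE versus the fixed all-17 concatenation head) typically
ties at the ceiling; the suite asserts non-inferiority at its canonical seed.
At some seeds the depth penalty's preference for shallow genomes can cost a
few points against a saturated baseline — the ordering claim is robust only
on tasks hard enough that the baseline is off the ceiling.

## Problem sizes

Examples and tests run at desk scale by choice: ~200-beat datasets (29 beats
per class, 21 patients), width-16 branches for 5 epochs, GA populations of
20 with up to 5 generations in the end-to-end runs (the operator-level tests
keep the full population of 100).  The full-scale profiles (widths 32–256,
30 epochs, population 100) are preserved as named configurations and their
constants are pinned by tests.

## Known limitations

* No GPU path and no deep-learning framework; the numpy implementation is
  sized for desk-scale experiments, not database-scale training.
* WFDB ingestion is not included; records enter as in-memory arrays or CSV
  matrices (one row per lead).
* The R-peak detector's fixed-fraction threshold is tuned for clean template
  signals; heavily pathological rhythms would need a substituted detector.
* Beat-level diagnosis only; no record-level aggregation of beat predictions.
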