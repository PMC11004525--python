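# Methods

## Problem and data model

The prediction target is binary: whether a COPD patient experiences an
increase in acute exacerbations over the follow-up year (1) or stays stable
(0). Inputs are per-patient feature tables with four annotated column blocks —
CNN-backbone and radiomics features from the inspiratory and the expiratory
CT phase. At full scale a patient has 13,824 CNN features per phase and 1,785
radiomics features per phase (31,218 columns); cohorts are ~200 patients with
roughly a 2:1 stable/exacerbation split. All stages operate on this table
abstraction; image processing (lung segmentation, CNN inference, radiomics
computation) happens upstream of the package.

## Synthetic cohorts

Because such cohorts are private, experiments run on seeded synthetic tables.
The generator draws class-conditional Gaussians with common variance and
independent columns: uninformative columns are N(0, σ²) in both classes;
informative columns get a between-class mean gap of d·σ (Cohen's d;
default d = 1.0, σ = 1.0), split evenly across all four blocks so every
phase-combination experiment has signal in each block. Three designated
risk-factor columns (chosen round-robin across blocks from the planted set)
use a larger gap (default d = 2.0) to mimic a few strongly associated
markers; they live inside the feature matrix, like real risk factors
selected from the same pool. Labels are an exact-count permutation
(70 exacerbation of 200 at desk scale; 70 of 202 at paper scale).

Two presets: *paper scale* (202 × 31,218) for structural checks and *desk
scale* (200 × 640, blocks 256/256/64/64) for everything iterative. What the
generator does **not** emulate: feature correlation (real CNN/radiomics
features are strongly correlated; independence makes selection easier than
reality), batch/scanner effects, heavy tails, and label noise. Passing
recovery tests therefore demonstrates correctness of the machinery, not
expected performance on clinical data.

## Lasso selection

The screen solves the squared-loss Lasso on the binary outcome exactly as
the printed objective (Gaussian working model on 0/1 labels), with a
`loss="logistic"` switch for the statistically conventional alternative.
Columns are standardized internally (constant columns dropped with a
warning), so selection is invariant to positive rescaling of any input
column. The penalty grid is 100 log-spaced values from λ_max (the smallest
penalty with an empty model) down to 10⁻⁴·λ_max; ten-fold CV (shuffled,
seeded) picks the minimizer of mean held-out error — the plain CV-min rule,
no 1-SE. If CV-min lands on an empty model (typical on signal-free data) the
largest penalty attaining at least `min_features` (default 1) nonzero
coefficients is used instead, so downstream graph construction is always
defined; the fallback sees training rows only and introduces no leakage.

Selection is fitted **inside each training fold** by default. Fitting on all
rows before cross-validation (a leakage risk, but the original study design)
is available via `paper_mode`/`--paper-mode` and `train_rows=None`.

## GLM risk factors

Each selected column is fit in a univariate binomial GLM with logit link;
columns are ranked by the absolute Wald statistic |β̂/SE| and the top k = 3
are the risk factors (ties break toward the lower column index, for
determinism). A multivariable GLM with ~10² predictors and ~70 events would
be unstable, hence marginal fits. Under perfect or quasi-separation the MLE
diverges; such columns are flagged and refit with a ridge-penalized Newton
logistic (L2 on the slope only, penalty 1.0), taking z from the penalized
Fisher information — a finite, large rank statistic that places perfect
predictors first. One caveat of Wald ranking: |z| saturates and can even
decrease for very strong effects (the Hauck–Donner effect), so the margin
between a d = 2 and a d = 1 column at n = 200 is smaller than the effect
gap suggests; recovery of planted risk columns is therefore a
high-probability event across seeds, not a certainty per seed.

## The graph predictor

**Episodes.** One episode is a graph of N = 2m+1 nodes: m support patients
per class (default m = 10, N = 21) and one query. Support sets are drawn by
a single random permutation of the pool — the first m rows of each class in
permutation order — and the training query is a uniform draw from the
remaining rows. This label-blind scheme keeps the sampled graph invariant
under a global swap of the two class labels, which makes the trainer's
label-symmetry property exact (see below). Since queries then follow the
cohort's class ratio, the episodic loss is weighted by inverse query-class
frequency, so both classes contribute equally in expectation.

**Node features.** V = [selected features ∥ k risk-factor columns ∥ class
channel]. The risk-factor columns are duplicated from the selected matrix
and appended as flagged channels. The class channel is the one-hot support
label, (½, ½) for the query; support labels must reach the predictor for
few-shot classification to be possible at all, and concatenating them as
node channels follows standard practice for few-shot graph networks.
Features are standardized with training statistics stored in the model.

**Edges.** Two ingredients per episode:

* constraint matrix E: per risk factor f, D_f[i,j] = |r_if − r_jf| and
  S_f = 1 − D_f/max(D_f) (all-ones when the factor is constant);
  E = Σ_f w_f S_f with nonnegative weights, equal by default. With weights
  summing to one, E is symmetric with unit diagonal, entries in [0, 1].
* learned weights W: a per-pair MLP on the absolute feature differences
  |x_i − x_j| (selected-feature channels only), widths F→64→1 with tanh
  hidden and sigmoid output. Absolute differences (rather than signed) make
  W symmetric by construction. Applying the same MLP to every (i,j) cell is
  equivalent to stacked 1×1 convolutions over the N×N grid.

The adjacency is A = rownorm((W∘E with zeroed diagonal) + I): nonnegative,
self-loops added, rows summing to one — a stable aggregation operator.

**Layers.** H = tanh(FC₁(A·V)); then the *auto-metric* step recomputes W
(a second edge MLP) from pairwise differences of H, reuses E, forms A′, and
logits = FC₂(A′·H); softmax over two classes. Exactly two
aggregation+FC layers.

**Training.** Cross-entropy on the query node only (support labels are
inputs, not targets), Adam (lr 10⁻³, default 2000 episodes), parameters
persisting across episodes. Everything is numpy with hand-derived
backpropagation; a finite-difference gradient check (1e-4 relative) is part
of the test suite. Initialization is uniform fan-in, except the final
classifier layer and the class-channel input rows, which start at zero.
Together with label-blind episode sampling this makes the initial parameter
state invariant under the class-swap permutation, so retraining with all
labels swapped provably yields the mirrored model and exactly swapped output
columns — a strong end-to-end consistency check.

**Prediction.** For each query row, `repeats` (default 10) episodes are
built with resampled support sets from the stored training pool, the query
node's softmax outputs are averaged, and the class is the argmax (ties at
0.5 go to class 0, the conservative majority call).

## Evaluation harness

Stratified 5-fold cross-validation (per-fold class counts within 1 of
proportional), shared folds across all predictors at a given seed, models
re-initialized per fold. Metrics: accuracy; precision and F1 macro-averaged
over the two classes (the averaging convention is a package choice — the
classes are imbalanced and macro treats them symmetrically); AUC as the
rank-based Mann–Whitney statistic with ties counted ½ (NaN with a warning
when the test fold is single-class — cannot occur with stratified folds of
this cohort). Baselines at fixed, documented hyperparameters: random forest
(200 trees), MLP (one 64-unit hidden layer), LDA (SVD solver), RBF-SVM with
Platt-scaled probabilities; scale-sensitive models get train-fitted
standardization. Paired two-sided t-tests over per-fold metrics compare
predictors.

## Numerical and design choices

* λ grid bounds and the CV-min rule as above; Lasso coordinate descent via
  scikit-learn with a fixed iteration cap.
* All randomness flows through `numpy.random.Generator` seeded per stage;
  identical seeds reproduce tables, selections, episodes and parameters
  bit-for-bit.
* Degenerate inputs: single-class labels, all-constant matrices, k out of
  range, too-small support classes and unknown variant names raise typed
  errors naming the offending field; non-finite training loss aborts with a
  diagnostic rather than continuing.
* Problem sizes in tests and the acceptance script use the desk-scale preset
  (200 × 640) with 100–1000 training episodes; at these sizes the full
  pipeline runs in seconds per fold while leaving the paper-scale layout to
  structural checks.

## Known limitations

* Independence of synthetic features flatters selection; no claim about
  clinical performance follows from the synthetic benchmarks.
* The edge-network depth/width and the risk-difference→similarity transform
  are package choices where the upstream literature leaves the architecture
  under-specified; they are deliberately the simplest symmetric options.
* Wald-based risk ranking inherits the Hauck–Donner saturation noted above.
* The optional imaging adapter (NIfTI volumes + lung masks through external
  PyRadiomics/Med3D extractors) is documented as a CSV schema contract only;
  the exact radiomics configuration that yields 1,785 features per phase
  (wavelet + Laplacian-of-Gaussian filter banks, bin width, sigmas) is
  user-provided and not validated here.
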