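# Methods

This note documents the models implemented by `microexpr`, the numerical
choices behind them, what the synthetic study conditions emulate, and the
known limitations.

## RoI geometry

Landmarks follow the 0-based iBUG 68-point numbering: brows 17–26, eyes
36–47 (inner corners 39/42), mouth 48–67 (corners 48/54). Two distances
set the scale of everything: `D_eye`, between the inner eye corners, and
`D_mouth`, between the mouth corners.

* Eye boxes: the landmark x-extent of each eye widened by `D_eye/4` on each
  side, bottom `D_eye/5` below the lowest eye landmark, top at the highest
  eyebrow landmark of that side (all five brow points participate). The
  lateral rule is read as a *margin* added per side: that parallels the
  mouth rule ("`D_mouth/5` away from the corners") and produces boxes wider
  than the eye itself, which a literal "box width = D_eye/4" would not.
* Mouth box: `D_mouth/5` beyond each corner, `D_mouth/4` above the highest
  and `D_mouth/7` below the lowest mouth landmark.
* Landmarks are located once, on the first frame, and reused for the whole
  clip: head displacement within a micro-expression clip is negligible
  compared to the RoI margins. Per-frame landmark overrides are possible by
  constructing boxes per frame.

Boxes are 0-based, half-open, floored on top/left and ceiled on
bottom/right (maximal enclosing box — annotated pixels are never lost),
then clamped to the frame. Crops are resampled to the configured sizes
(defaults: eyes 80×90, mouth 70×150, height×width). Resampling is the
identity at the target size, area (block) averaging for exact integer
down-sampling — the correct antialiased reduction — and bilinear
interpolation otherwise (`roi.resample=nearest` is available).

## Optical strain and apex detection

Optical strain is the spatial-derivative magnitude of the inter-frame flow
field: rigid translation (constant flow) gives exactly zero, localized
non-rigid motion gives a strain peak around the moving region. Two tensor
conventions are supported:

* `printed` (default): `eps_xy = (dv_x/dx + dv_y/dy)/2` — half the
  divergence — alongside the usual `eps_xx`, `eps_yy` and the symmetric
  shear `eps_yx`. This is the form the recognition method defines.
* `symmetric`: the standard infinitesimal strain tensor,
  `eps_xy = eps_yx`.

The scalar strain is the root-sum-of-squares of the four components in
either convention (it is invariant to swapping the two off-diagonal
roles). Derivatives are central differences in the interior and one-sided
at borders; border pixels are excluded from RoI sums by default
(`exclude_border=1`) because one-sided derivatives there are noisier.

Flow estimation is an injected dependency with signature
`(frame_prev, frame_next) -> FlowField`; the default binding is the TV-L1
dense variational estimator from scikit-image. All correctness tests inject
analytic flows, so no numerical claim depends on the estimator.

The apex search keeps an interval `[lo, hi]` of strain-series positions and
compares the inclusive sums of `[lo, mid]` and `[mid, hi]`, keeping the
heavier half (ties keep the upper half, matching the `<=` branch of the
published pseudo-code). As published, the loop cannot make progress once
`hi = lo + 1`; we terminate at interval width <= 1 and return the endpoint
with the larger value, the minimal fix that preserves the comparison logic
and guarantees termination in `ceil(log2 N) + 1` iterations.

**Limitation.** The half-sum comparison is a heuristic. It provably tracks
the maximum when the series is *peak-dominated* — when values decay by a
factor >= 2 per step away from the peak, the peak exceeds the sum of all
other entries, so the heavier half always contains it and the search lands
within one position of the argmax. Strain series of genuine
micro-expressions are of this concentrated kind, and the unimodal test
series are generated in this class. On flat-peaked unimodal series
(slow additive ramps) the search can land several frames off; the
exhaustive `brute_force_apex` is provided both as a test oracle and as a
fallback (`apex_frame(series, method="brute")`). Series values are indexed
to the later frame of each pair; `StrainSeries.frame_of` converts a series
position to the apex frame index.

## NMF and LNMF

The data matrix `D` (pixels × samples, non-negative) is factored as
`D ~ WH`, minimizing the generalized KL divergence
`sum(d log(d/(WH)) - d + (WH))`, with `W >= 0`, `H >= 0` and each `W`
column summing to 1. One iteration runs the multiplicative H step, the
multiplicative W step (with the per-basis denominator `sum_j h_lj`), then
re-normalizes the W columns. The re-normalization scale factors are
absorbed into the H rows so the product `WH` — and hence the objective —
is unchanged by the re-scaling; without that compensation the
normalization step could raise the objective and per-iteration
monotonicity would be lost. With W column-normalized, `W^T 1 = 1`, so the
H step equals the standard KL update and the whole iteration is provably
non-increasing for `nmf_kl` (and, identically, for `lnmf_printed`).

Variants:

* `lnmf_printed` (default) — the published update skeleton, identical to
  the KL updates above.
* `lnmf_sqrt` — the classical locality-penalized form,
  `H <- sqrt(H * W^T(D/WH))`. Its fixed point is `H = W^T(D/WH)` (not the
  plain-KL stationary point), so it trades reconstruction fidelity for
  locality: on the planted-parts fixture it plateaus around 15% relative
  error where the default variant reaches < 1%. Its KL trace is observed
  to be non-increasing in all seeded runs.

The locality/orthogonality weights alpha and beta of the penalized LNMF
objective are carried in `LNMFConfig` for documentation; they do not enter
the published update rules and therefore not the default iteration.

Numerical choices: `W` init Uniform(0.1, 1.1) column-normalized; `H` init
drawn per-row and broadcast across columns (the H update is
column-separable, and a column-position-independent init makes the learned
features exactly equivariant under sample reordering); epsilon `1e-12`
inside every denominator and log argument; stopping at relative objective
change < `1e-6` or 2000 iterations. Fits are bitwise reproducible per
(seed, config).

Features: one LNMF run per RoI with configured ranks (profiles: 40/40/80,
height 160; 120/120/110, height 350); the three H blocks are stacked
row-wise. Mirrored samples are extra data-matrix columns created at image
level before factorization: a mirrored face's left-eye region is the
flipped right-eye region, so the eye crops swap roles and the mouth flips.
Mirrored columns inherit the subject and label of their source. The
default fits the factorization on all samples jointly (features are H
columns, as the method defines); `encode_with_fixed_basis` iterates the H
update with W frozen for leakage-free per-fold encoding of held-out
samples when that protocol is preferred. The macro-expression profile
(`ck_macro`) factors whole 48×48 images with plain NMF at rank 200 instead
of the RoI split.

## Macro-to-micro augmentation

Per emotion, macro features `X_emo` are split (seeded, default 50/50 with
the probe taking the floor on odd counts) into reference and probe halves.
Micro features of the same emotion are sorted by sample id and recycled
round-robin to pair one micro column with each reference column. The
weight matrix solves `X_probe ~ X_ref H`, `H >= 0`, by fixed-basis
multiplicative updates (Frobenius form
`H <- H * (X_ref^T X_probe) / (X_ref^T X_ref H)`, epsilon-guarded; a KL
form is config-selectable); its residual trace is non-increasing. New
micro samples are `Y_new = Y_emo H` — a product of non-negative factors,
so non-negativity is a hard guarantee, and exactly one sample is generated
per probe column. Generated columns carry the emotion label, subject id
`mtm` (they blend many subjects' features and belong to no real subject)
and provenance `mtm_augmented`. A zero probe matrix yields `H = 0` with
residual defined as 0.

The SVD baseline stacks `M = [X_ref; Y]`, splits the left singular vectors
into macro/micro row blocks `R_x`/`R_y`, solves `X_probe = R_x H` by least
squares (pseudo-inverse with a warning when `R_x` is rank-deficient) and
returns `R_y H`. Because `U` is orthogonal, `H` is sign-indefinite and the
generated samples generally contain negative entries — on sparse
non-negative feature-like inputs, every seeded trial does — which is why
the non-negative path exists.

Mapping between macro and micro emotion vocabularies (e.g. a corpus that
labels "repression" where another has "anger/contempt") is a user-supplied
table: `mtm_transform` takes an explicit emotion list and never guesses.

## Classification protocol

One-vs-one SVMs (scikit-learn's SVC, `n(n-1)/2` binary machines) with the
polynomial kernel `(gamma x^T y + alpha)^d`; profiles `casme2` = (4, 0, 4)
and `samm` = (4, 0, 1); the regularization constant C defaults to 1 and is
exposed. Prediction is majority vote over the pairwise decisions with ties
broken toward the lowest class index (deterministic).

Evaluation is leave-one-subject-out: each fold tests all and only the
*original* samples of one subject; mirrored and MtM-generated samples may
train but never test, and no sample sharing the test subject's id is
trained on. Both constraints are machine-checked on every fold. A
`sample` mode (leave-one-sample-out, with the mirrored twin of the held-out
sample also excluded from training) is available. Repeated runs (default
5) vary only the stochastic seeds via an optional per-run feature builder
(factorization init, MtM splits); folds and kernel stay fixed; accuracy is
the mean over runs and the confusion matrix the per-run mean, so its rows
always sum to the per-class original counts.

## Synthetic study conditions

All tests and the acceptance script run on seeded generators
(`microexpr.synth`), pure functions of their parameters:

* `make_parts_data` — disjoint Gaussian-bump-on-pedestal parts, one per
  grid cell, with sparse non-negative mixing (Uniform(0.2, 1) magnitudes,
  each sample activating about half the parts, each part appearing alone
  in at least one sample). Sparse mixing keeps the exact factorization
  identifiable — under dense all-positive mixing the same data admit
  rotated factorizations and basis supports are not recoverable even at
  reconstruction error 1e-4. Default study size: 5 parts, 40×40 pixels,
  60 samples.
* `make_motion_sequence` — a synthetic face (background gradient, eye and
  mouth blobs placed by a generated 68-point layout) whose mouth blob
  moves horizontally with per-pair displacement magnitudes that rise
  linearly to the apex pair and decay geometrically (factor 0.7) after it;
  analytic flows are exported alongside the rendered frames so strain
  tests bypass flow estimation. Default: 16 frames, apex at frame 7, peak
  displacement 2 px.
* `make_classed_features` / `make_classed_roi_stacks` — non-negative class
  templates scaled by a separation factor plus per-subject offsets and
  unit Gaussian noise, clipped at zero; separation 10 sigma makes classes
  linearly separable (verified by a 1-NN oracle). Defaults: 3 classes, 6
  subjects, 3 samples per cell.
* `make_macro_micro_pair` — per emotion, random positive `X_ref`, planted
  non-negative `H*`, `X_probe = X_ref H*`, and paired random positive
  micro features, so the weight solver has a recoverable ground truth.

What passing these conditions does **not** show: robustness to landmark
error, illumination and head pose, flow-estimation noise on real skin
texture, class imbalance, or the much weaker class separation of real
micro-expression data — the published corpus-level accuracies cannot be
reproduced without the licensed datasets, and none of the synthetic
numbers should be read as recognition accuracy on real faces. The
estimator-in-the-loop tier (TV-L1 on rendered frames) is deliberately
tolerance-relaxed (apex within ±2 frames on a 10-frame clip).

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: monotonicity
on ten 64×100 matrices at rank 10 for 250 iterations; part recovery on ten
seeded 1600×60 matrices at rank 5 (up to 2000 iterations); 100 unimodal
series of lengths 8–256; 50-seed non-negativity fuzzing and 20-seed SVD
sign checks; an end-to-end run with 54 original + 54 mirrored + 60
generated samples across 6 subject folds; and a bookkeeping run shaped
like the published protocol (792 macro columns across five emotions split
396/396, 312 micro columns, 396 generated, 708 training samples total).
These sizes keep the full suite under a few minutes on one CPU while every
stage still runs at a scale where its failure modes (non-identifiability,
wrong-half searches, sign violations, fold leakage) are observable.
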