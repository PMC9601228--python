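# Methods

This note documents the models, procedures and design choices behind
`mammotensor`: what each pipeline stage computes, which parameters matter
and why their defaults are what they are, what the synthetic phantoms do and
do not emulate, and the package's known limitations.

## Problem setting

The task is per-pixel characterization of breast tissue on digital
mammograms into three classes: healthy tissue (0), calcification (1) and
malignant mass (2). Classifying a pixel from its scalar intensity alone
discards spatial context, so each pixel *i* is represented by the square
neighbourhood centered on it: a third-order tensor
X_i ∈ R^{s×s×b}, where *s* is the window edge (the TWS hyper-parameter) and
*b* = 10 the number of image channels. The label t_i ∈ {0,1}^C is one-hot
(C = 3), and the dataset is D = {(X_i, t_i)}_{i=1..N}. A classifier
f(X, θ) outputs class probabilities; predictions take the argmax; training
minimizes mean cross-entropy over the training split.

The motivating constraint is small-sample learning: annotated mammograms
are scarce, so the model must have few trainable parameters, and the
pipeline deliberately constructs *small* training sets to prove the point.

## The Rank-R FNN

The model is a one-hidden-layer feed-forward network with Q hidden neurons
whose input-to-hidden weights are constrained to rank-R canonical polyadic
(CP) form. Neuron q's weight tensor is

    W(q) = Σ_{k=1..R}  w1_k(q) ∘ w2_k(q) ∘ w3_k(q),

with w1, w2 ∈ R^s on the two spatial axes, w3 ∈ R^b on the channel axis,
and ∘ the vector outer product. The hidden activation is
u_q = g(⟨W(q), X⟩), the output layer is a softmax over logits
z_c = ⟨v(c), u⟩. The factorization cuts the first layer from Q·s²·b scalars
to Q·R·(2s + b): at the default working point (s = 21, b = 10, Q = 25,
R = 4) that is 5,275 versus 110,325 trainable scalars (ratio 0.048), and at
the larger configuration (s = 35, Q = 50, R = 8) 32,150 versus 612,650.

Numerical and design choices, where the formulation leaves them open:

- **Axis convention.** Inputs are stored height × width × channels; the
  factor roles are fixed as w1 → height, w2 → width, w3 → channels. Any
  consistent convention is equivalent up to relabeling of learned factors.
- **Hidden nonlinearity g.** ReLU by default; sigmoid via
  `TrainConfig(activation="sigmoid")`. The choice is config-exposed because
  nothing in the model pins it down.
- **No biases.** The factorized layer and output layer carry no bias terms
  by default, matching the model equations exactly.
- **Q and R defaults (25, 4).** Small values keep the parameter budget in
  the low thousands, which is the regime the model is designed for. Both
  are exposed everywhere (config, CLI `--config`, `ModelDims`).
- **Initialization.** Factor entries ~ N(0, 1/√(R(2s+b))), output weights
  ~ N(0, 1/√Q): variance-preserving at the working dimensions.
- **Optimizer.** Adam with step 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-8;
  full-batch when the training set has ≤ 1024 samples, else mini-batches of
  128, reshuffled each epoch by the run's seeded generator. Training runs
  70 epochs with held-out evaluation every 10 by default.
- **Gradients** are derived manually (chain rule through softmax, g, and
  the factorized contraction) and validated against central finite
  differences (max relative discrepancy ~2.5e-7 on a dense parameter scan
  of a small model; the test gate is 1e-5).
- **Factorized evaluation.** `hidden_preactivation` contracts X against
  w3, then w2, then w1 per rank term and never materializes W(q)
  (O(R(s²b + s² + s)) per neuron). The *batched* training path instead
  materializes the K = Q·R rank-1 tensors into one (s²b × K) matrix per
  step — K·s²·b multiplies, negligible — so the whole batch runs as a
  single BLAS matmul. The two routes agree to floating-point roundoff
  (~6e-15 relative, tested to 1e-8), and the parameter count is unaffected:
  only factors are stored and updated.
- **Divergence.** If the loss goes non-finite the trainer returns the last
  finite checkpoint and flags the history; in the repeated-experiment
  driver a diverged repetition is recorded but does not abort the batch.
- **Ties** in the argmax prediction break toward the lowest class index.

## Pre-processing pipeline

**Peripheral crop.** The tissue mask is intensity > 0.05 (on [0,1]),
largest 8-connected component, holes filled; the crop is the tissue
bounding box expanded by an 8 px margin and clipped. Threshold and margin
are package choices (nothing external fixes them) and are arguments. When
an annotation mask is supplied, the pipeline verifies the crop never
discards lesion pixels.

**Filter bank.** Nine training-free filters stack with the raw image into
a 10-channel object. The named filter families (Sobel with thresholds,
Canny, Gaussian difference, gamma correction, histogram normalization,
Gabor) do not by themselves enumerate nine channels, so the default
assignment is: Sobel magnitude; Sobel binarized at 0.1 and at 0.3; Canny
(σ = 1); difference of Gaussians (σ = 1, 3); gamma 0.5; histogram
equalization; Gabor magnitude at 0° and 90° (frequency 0.2 cycles/px).
Every parameter lives in the `FilterSpec` list, so any other nine-channel
assignment is one config edit. Channels that stray outside [0,1] are
min–max rescaled; channels already in range are left untouched so
identity-like transforms stay exact — rescaling is rank-preserving either
way.

**Patch extraction.** 64 × 64 windows are scanned row-major with a stride
(default 32 px). A window is kept iff its breast-tissue coverage strictly
exceeds 90% and, when the image carries any lesion annotation, it
intersects at least one lesion pixel; scanning stops at `max_patches`
(default 10 per image — a package choice). Acceptance is tested against a
brute-force loop oracle on random masks.

**Tensorization.** Every `tss`-th pixel (both axes) whose centered
tws × tws window fits inside the patch is a dominant pixel producing one
sample labeled by that pixel's class. Windows never cross patch borders (no
padding — padding semantics would fabricate context and dilute labels). TWS
is expected odd so the center is exact; an even TWS uses the top-left pixel
of the central 2×2 block.

**SPC and the split.** The samples-per-class cap applies per patch and per
class *at extraction* (min(SPC, available) drawn uniformly without
replacement); the pooled dataset is then split 30% training / 70% testing.
The split is stratified by class (largest-remainder apportionment of the
round-half-up train total), the training order is permuted by the same
seeded generator, and a class with fewer than two samples goes entirely to
training with a warning. Stratification is a package choice on top of the
bare 30/70 rule: at these dataset sizes an unstratified draw can leave a
rare class unrepresented in one half.

**Repetitions.** Each experiment repeats 10 times with seeds derived from
the master seed. A repetition re-draws the per-patch tensor selection and
the 30/70 split; the extracted patches stay fixed. Aggregates are
mean ± Student-t 95% half-width over the per-repetition metrics (n−1
degrees of freedom) — appropriate at n = 10.

**Metrics.** Accuracy = trace/total of the confusion matrix (rows = truth).
F1 is macro-averaged: per-class 2PR/(P+R) with the 0/0 case defined as 0,
unweighted mean over classes. Macro was chosen over micro because the
evaluation emphasizes per-class confusion structure and micro-F1 collapses
to accuracy in single-label problems; micro is available via the same
confusion matrix.

## Synthetic phantoms

The phantom generator exists so the entire pipeline and model are testable
without clinical data. Each phantom is a half-elliptical "breast" against a
dark background (attached to the left edge like a chest wall), filled with
smoothed-Gaussian parenchyma-like texture (correlation length 6 px,
amplitude 0.08 around base intensity 0.45), with:

- **masses** — flat-topped Gaussian blobs, radius 6–12 px, labeled class 2
  where the profile is at or above half its peak. The peak is 2× the
  configured contrast (0.25), so the *mean* elevation of labeled pixels is
  ≈1.44× contrast and the audit "mass pixels exceed surrounding tissue by
  at least the configured contrast" holds with margin;
- **calcifications** — clusters (spread 8 px) of 8 speckles of 1–3 px at
  +0.45 contrast, labeled class 1;
- additive pixel noise (σ = 0.05) and clipping to [0,1].

Structures are rejection-placed (100 attempts, then an error) inside the
breast with a 16 px interior margin, and kept mutually disjoint so
component counts are well defined. Cohorts allocate lesions
deterministically: the first round(fraction·n) images get masses, the last
round(fraction·n) get calcification clusters (default mix: one third each,
one third healthy). Per-image seeds derive from the master seed.

Contrasts were set so the task is neither trivial nor impossible: the
noise standard deviation (0.05) makes single-pixel classification
ambiguous, while a 21 px window sees enough structure to separate the
classes. What the phantoms do **not** emulate: pectoral muscle, skin line
and nipple, vasculature and ductal structure, scanner artifacts, BIRADS
density variation, spiculated or irregular mass margins, and the
benign/malignant distinction within each lesion family. Passing the
end-to-end test therefore shows the pipeline and model are correct and
learnable under realistic geometry and noise — not that clinical-grade
scores transfer to real mammograms.

## Reference experiment and problem sizes

The package's reference run (`run_default_experiment`, also what
`scripts/acceptance.py` executes) uses a 12-image cohort at 192 × 192 px,
≤10 patches/image, TWS = 21, SPC = 60, TSS = 2, Q = 25, R = 4, 70 epochs,
10 repetitions. This yields roughly 90–120 patches and a few thousand
tensors per repetition (≈30% train). At these sizes the full run completes
in a few minutes on one CPU; the cohort size and image resolution are the
package's desk-scale working point, chosen to keep the three classes all
represented while remaining firmly in the small-sample regime.

Typical results at this working point: held-out accuracy ≈0.98–0.99 with a
95% half-width under 0.01, macro-F1 ≈0.75–0.90. Macro-F1 varies noticeably
across cohort seeds because calcification is by far the rarest class (tiny
speckles yield few dominant pixels, so a repetition's training draw can
contain only a handful of calcification tensors); repetitions that miss the
class entirely drag the macro average even when accuracy is unaffected.
This mirrors the real clinical difficulty of the class and is reported, not
hidden.

## Known limitations

- The synthetic gap above: no claim is made about clinical performance.
- The per-patch SPC cap interacts with patch overlap: overlapping patches
  can contribute near-duplicate tensors to training and testing halves
  (windows from different patches may share pixels). The split is by
  tensor, not by source image; image-level holdout would be the stricter
  protocol and is straightforward to add on top of `split_dataset`.
- Training is plain NumPy on one CPU; it is sized for desk-scale
  experiments, not for full-resolution clinical images (a full-field
  mammogram would need tiled processing and far more patches).
- The comparison deep-learning baselines evaluated alongside this model in
  the literature are out of scope; the package evaluates the tensor-based
  model only.
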