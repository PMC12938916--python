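# Methods

## Problem setting

Six-class skin-lesion classification from paired smartphone dermoscopic
images and clinical metadata, under the two asymmetries that dominate real
clinical corpora: class imbalance (a rare malignant class below 10 % of
samples) and information asymmetry between a high-dimensional image and a
low-dimensional tabular record.  The class order is fixed alphabetically —
ACK, BCC, MEL, NEV, SCC, SEK — so the static focal weights
[1, 1, 2, 1, 2, 1] land on MEL and SCC, the rare malignant classes.

## Metadata encoding (21 attributes → 81 dimensions)

Three numeric attributes (age, two lesion diameters) are min-max scaled to
[0, 1] over declared physiological ranges (age 0–100 y, diameters 0–50 mm);
eighteen categorical attributes are one-hot encoded, each with an explicit
trailing "unknown" dimension, so a missing categorical value is itself a
valid one-hot state rather than an all-zero span.  The layout totals exactly
81 dimensions and the first 18 encode age, sex and anatomical region — the
block that minimal-metadata synthesis fills deterministically, sampling the
remaining 63 dimensions from reference marginals.  Missing numerics are
imputed with medians computed on the training split only and then frozen,
to avoid leakage.  The exact published encoding of this attribute family is
not public; this schema is a documented, versioned stand-in (serialises to
a YAML-compatible dict) and real CSVs can be remapped through it.

## Network

* **Backbone.**  `resnet50` geometry (224 px → 2048×7×7, realised as a
  strided convolutional stack with the layer4 output geometry; pretrained
  weights are out of scope and any initialisation is accepted) or `tiny`
  (3 stride-2 conv blocks, 32 px → 64×4×4) whose dims propagate through all
  configs so end-to-end tests run in seconds.
* **Recalibration.**  z = GAP(F); e_M = Dropout(ReLU(BN(W_M M + b_M))) with
  embedding width d (512 full-scale, 16–32 tiny); gates
  α = σ(W₂ ReLU(W₁[z; e_M] + b₁) + b₂) with hidden width C′ (256
  full-scale); F′ = α ⊙ F.
* **Modulation + fusion.**  γ, β from e_M by affine maps (initialised near
  the identity: γ ≈ 1, β ≈ 0, for stable early training);
  F″ = γ ⊙ F′ + β.  Spatial positions are tokens (row-major flattening,
  N = H·W); Q, K, V are square per-token projections; the metadata key
  K_M = W_KM e_M is broadcast-added to every key row before the dot
  product; softmax is over key positions with scale √C; a residual
  connection gives F_fused = F″ + A.  This resolution of the attention's
  dimensional layout (tokens = spatial positions, K_M added to K row-wise,
  single head, no positional encoding) is the standard reading that makes
  every projection dimensionally consistent.
* **Head.**  GAP over F_fused → dropout → linear → 6 logits.

## Uncertainty and loss

Monte-Carlo dropout keeps every dropout site live in evaluation mode while
batch-norm statistics stay frozen, so dropout is the only stochasticity.
T passes (default 10 full-scale, 3 in the tiny profile — the uncertainty
pass multiplies forward cost by ≈ T) give per-class softmax variances;
population variance (divisor T) by default, sample variance available.
The weight w = 1/(1 + exp(−λσ²)) with λ = 0.1 is computed per sample for
the sample's true class and multiplies the static focal weight α_y.
Because softmax variances are bounded by 0.25, w lives exactly in
[0.5, 1/(1 + e^{−0.025})] ≈ [0.5, 0.50625]; λ is configuration, never
silently rescaled, and the band is asserted in the tests.  The loss is
−α_y · w · (1 − S_y)^γ · log S_y with γ = 2 (γ = 0 recovers weighted
cross-entropy; S_y is clamped at 1e-8 before the log).

Training: SGD, momentum 0.9, weight decay 1e-3, batch 8, cosine-annealed
learning rate lr(t) = lr₀(1 + cos(πt/T_max))/2 with lr_min = 0 and clamping
past T_max; full-scale recipe lr₀ = 1e-3 over 150 epochs, tiny profile
lr₀ = 1e-2 over 5–10 epochs.  Gradients are clipped to global norm 5 —
without it the attention stage occasionally diverges at the tiny profile's
higher learning rate.  The best checkpoint is selected by validation
balanced accuracy, ties broken by accuracy; channel-gate snapshots (mean α
per channel over up to 64 validation samples) are persisted every 10 epochs
(every epoch in tiny runs), and attribution artifacts are saved once
validation BACC > 0.82 or ACC > 0.86.

## Attribution

Integrated gradients with a midpoint Riemann sum (lower bias than the
left-endpoint rule at equal step count), 50 steps by default.  The image
path holds metadata fixed and integrates from a zero image in the
normalised space; the metadata path integrates from the neutral encoding
(all categoricals "unknown", numerics mid-range) because an all-zero vector
is not a valid point of the one-hot space.  The attributed score is the
softmax output by default (the uncertainty machinery is on softmax scale);
pre-softmax logit attribution is an option and is what the closed-form
linear-model tests use.  Completeness residuals |ΣIG − (S_c(x) − S_c(x′))|
are recorded on every result.  Per-pixel attributions are summed over the
three colour channels; heatmaps are min-max normalised to [0, 1] with the
constant-map convention 0.5 everywhere; heatmaps are absolute-valued by
default with signed maps available.  The unified ranking orders all
pixels + 81 metadata dimensions by |attribution| with deterministic
(modality, index) tie-breaking.

## Faithfulness evaluation

Insertion/deletion follow the standard protocol: from the baseline (or the
full input), features — pixels with their three channels moving together,
plus metadata dimensions in unified mode — are flipped in ranking order at
a grid of 20 interior fractions plus endpoints; the metric is the
trapezoidal area under the score-vs-fraction curve.  Replaced pixels take
the baseline value (no blurring).  The faithfulness drop is defined here as
the ratio of the score drop from deleting the top-q attributed fraction to
the mean drop over R random q-fractions (values > 1 mean attributed regions
are more critical than chance); this ratio form and the default q = 0.2 are
this package's reconstruction of the protocol, labelled as such.  A
Grad-CAM-resolution comparison ranking scores every pixel by the mean
|attribution| of its 7×7-coarse cell.

## Synthetic data

The generator emulates the structure, not the appearance, of a
PAD-UFES-20-scale corpus: default 2298 samples with per-class proportions
(730, 845, 52, 244, 192, 235)/2298 — SCC ≈ 8.4 % and MEL rarest — and a
largest-remainder rule so counts always sum to the requested total.
Lesions are rendered as rotated ellipses with class-dependent eccentricity
(asymmetry), low-order Fourier perturbation of the boundary radius (border
irregularity) and class-dependent hue on a skin-toned background; melanoma
is dark and highly asymmetric, nevi regular and brown, BCC/SCC pink-red
with ragged borders.  A linear probe on raw pixels beats chance balanced
accuracy, so fusion modules have learnable image signal.

Metadata follows class-conditional laws (age/diameter normals, region
preferences, symptom/history Bernoullis, phototype categoricals) mixed with
the population marginal through `metadata_signal_strength` s: each
attribute follows the class law with probability s, and the laws themselves
sharpen as s rises (probability vectors exponentiated with k = 1 + 3s,
continuous standard deviations scaled by 1 − 0.7s), so s = 0 is exactly
class-independent and s = 1 near-deterministic.  Default s = 0.8 with 5 %
missingness to exercise imputation.  Two RNG streams (images, metadata)
derive from one seed so metadata can be regenerated without re-rendering.

What passing tests on this generator do **not** show: robustness to real
dermoscopic texture, hair/ruler artefacts, camera and lighting variation,
or real metadata missingness patterns — the generator's class-conditional
structure is a caricature built to give every mechanism measurable signal.

Stratified splitting shuffles with a fixed seed, then apportions: the train
size is floor(n·f_train); the remainder splits between validation and test
in proportion to their fractions with validation receiving any odd sample;
per-class quotas follow largest-remainder apportionment.  At n = 2298 with
fractions (0.667, 0.1665, 0.1665) this reproduces the published
(1532, 383, 383) partition — the naive per-partition rounding of those
fractions does not, so the train-first rule is this package's
reconstruction.

## Metrics

Balanced accuracy (mean per-class recall), accuracy, per-class
precision/recall/F1, one-vs-rest specificity and class-wise accuracy, and
macro AUC via the rank statistic with midrank tie handling.  Everything is
computed at full precision; report output rounds half-up to one decimal.
Undefined denominators yield NaN flags, never silent zeros; classes absent
from an evaluation set are excluded from mean-recall/AUC with a warning.
Independent cross-checks against brute-force loops and scikit-learn's
implementations run in the test suite.

## Numerical and engineering choices

* No deep-learning framework is used: a ~350-line reverse-mode autodiff
  engine over numpy (broadcast arithmetic, matmul, im2col convolution,
  activations, reductions, shape ops) powers all training and all input
  gradients; it is finite-difference-verified in the tests.
* float64 throughout; softmax is max-shifted for stability; non-finite
  attention scores raise with a max-logit diagnostic rather than
  propagating NaNs.
* Batch-norm in evaluation mode before any statistics exist is a state
  error; the training loop warms the statistics with one no-grad pass so
  the first uncertainty estimate is well-defined.
* Checkpoints are flat `.npz` state dicts plus a JSON sidecar carrying the
  resolved config and its hash; evaluation refuses mismatched checkpoints.

## Scaled-down experiment design

Desk-scale runs use the tiny profile: 16–32 px images, embedding width 16,
attention hidden width 8, T = 2–3, 8–10 epochs, lr₀ = 0.01, n = 240–360
samples, 5 seeds per directional comparison (20 for the ranking-resolution
comparison).  These sizes keep the full acceptance recomputation around a
minute on one CPU while leaving each directional effect (minority-class
recall under uncertainty-weighted focal loss vs cross-entropy; multimodal
fusion vs image-only; fine vs 7×7-coarse attribution ranking under
insertion AUC) visible in the seed-mean.  Directional conclusions are
asserted on seed-means, not per-seed, and magnitudes at this scale are not
comparable to full-scale results.

## Known limitations

* The `resnet50` tag reproduces layer4 geometry, not the literal 50-layer
  residual topology, and no pretrained weights are available in-package.
* Single-head attention only; no positional encodings.
* The faithfulness-drop formula and the metadata IG baseline are
  reconstructions (documented above) rather than published definitions.
* Pure-numpy training is CPU-bound: the full-scale 224-px/150-epoch recipe
  is supported by the code paths but impractical without hardware
  acceleration; the package's empirical claims are made at the tiny
  profile.
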