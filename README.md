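# dermafuse

Multimodal skin-lesion classification for clinical six-class dermoscopy
(ACK, BCC, MEL, NEV, SCC, SEK — actinic keratosis, basal cell carcinoma,
melanoma, nevus, squamous cell carcinoma, seborrheic keratosis), built for
the small, severely imbalanced smartphone-image datasets found in
teledermatology: a few thousand images, a rare malignant class holding under
10 % of the samples, and 21 clinical attributes per lesion encoded as an
81-dimensional metadata vector.

The package is aimed at researchers studying image+metadata fusion and
attribution faithfulness on such data.  It ships its own synthetic-data
generator (procedurally rendered lesions with class-conditional asymmetry,
border irregularity and colour, plus class-correlated metadata), so every
component can be trained, evaluated and explained end to end without any
external dataset.

## Model

A convolutional backbone produces a feature map **F** ∈ ℝ^{C×H×W}
(ResNet50-layer4 geometry, C = 2048, H = W = 7, by default; a tiny
3-block variant for desk-scale work).  Three mechanisms sit on top:

1. **Metadata-conditioned channel recalibration.**  Global average pooling
   gives a channel descriptor z_c = (1/HW) Σ_{i,j} F_c(i,j); the metadata
   vector M ∈ ℝ^81 is embedded as e_M = Dropout(ReLU(BN(W_M·M + b_M)));
   an MLP over [z; e_M] with sigmoid output emits per-channel gates
   α ∈ (0,1)^C and F′_c = α_c · F_c (squeeze-excite conditioned on the
   clinical context).

2. **FiLM modulation + cross-attention fusion.**  The embedding predicts a
   channel-wise affine transform γ, β = W·e_M + b, F″_c = γ_c F′_c + β_c;
   the H·W spatial positions are then treated as tokens, projected to
   Q, K, V, a metadata key K_M = W_KM·e_M is added to every key row, and
   single-head scaled dot-product attention
   A = softmax(Q(K + 1·K_Mᵀ)ᵀ/√C)·V feeds a residual fusion
   F_fused = F″ + A.

3. **Uncertainty-weighted focal loss.**  Per batch, T Monte-Carlo-dropout
   passes (batch-norm frozen, dropout live, p = 0.5) estimate the softmax
   variance σ²(S_c) of the true class; the weight w = 1/(1 + exp(−λσ²)),
   λ = 0.1, multiplies the focal loss
   −α_y · w · (1 − S_y)^γ · log S_y with γ = 2 and static class weights
   α = [1, 1, 2, 1, 2, 1] (melanoma and SCC up-weighted).  Training uses
   SGD (momentum 0.9, weight decay 1e-3) under cosine-annealed lr.

Interpretability is dual-modality **integrated gradients**: midpoint-rule
path integrals from a zero-image / neutral-metadata baseline give per-pixel
and per-metadata-dimension attributions with an explicit completeness
residual, a unified ranking across all pixels + 81 metadata dimensions, and
insertion/deletion-AUC + faithfulness-drop evaluation of that ranking.

All network forward/backward passes run on a compact numpy reverse-mode
autodiff engine included in the package (`dermafuse.autodiff`), verified
against finite differences in the test suite.

## Worked example

```bash
ARGS='--set simulate.total_n=240 --set simulate.image_size=32 \
      --set simulate.class_proportions=[0.25,0.25,0.1,0.2,0.1,0.1] \
      --set simulate.metadata_signal_strength=1.0 \
      --set train.epochs=10 --set train.lr0=0.01 --set model.mc_passes=2'

dermafuse $ARGS simulate --out data        # 240 synthetic lesions + CSV
dermafuse $ARGS train    --data data --out run
dermafuse $ARGS evaluate --data data --checkpoint run/checkpoint.npz --out eval
dermafuse $ARGS explain  --data data --checkpoint run/checkpoint.npz \
          --out explain --sample-id syn_00000.png --steps 16
```

The run above prints

```
wrote 240 samples to data
best val BACC 78.3 at epoch 9
{"bacc": 90.0, "acc": 92.5, "macro_auc": 99.0}
wrote attribution artifacts for 1 sample(s)
```

i.e. on the held-out stratified test split the trained tiny model reaches
90.0 % balanced accuracy (mean per-class recall), 92.5 % plain accuracy and
99.0 % macro one-vs-rest AUC; `eval/metrics.json` adds per-class precision,
sensitivity, specificity, F1, class-wise accuracy and AUC, and `explain/`
holds the attribution heatmap PNG, per-pixel and per-metadata-dimension
attribution CSVs and the unified ranking.

The same pipeline is available as a scikit-learn-style estimator:

```python
from dermafuse import LesionClassifier
clf = LesionClassifier(epochs=10, lr0=0.01).fit((images, metadata), y)
proba = clf.predict_proba((images_test, metadata_test))
```

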