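# Methods

## Problem setting

`haaunet` segments brain-tumor sub-regions from multi-modal 2D MRI slices
(four channels in fixed order: T1, T1Gd, T2, T2-FLAIR) into the BraTS-style
label set {0 background, 1 necrotic core (NCR), 2 peritumoral edema (ED),
3 enhancing tumor (ET)}, with the nested composite views WT = NCR∪ED∪ET,
TC = NCR∪ET, ET used for evaluation. Around the segmenter sit a
brightness-preserving preprocessing stage, mask-level morphological
descriptors, mutual-information feature selection, standard segmentation
metrics, and a Cox proportional-hazards survival head on
segmentation-derived covariates.

The network and its training loop run on a small reverse-mode automatic
differentiation engine written on numpy (im2col convolutions, separable
min/max filters, bilinear upsampling). Gradient correctness is enforced by
finite-difference tests at float64 on every structured operator and through
the assembled network.

## Preprocessing

**Bi-histogram equalization (BBHE).** The 256-bin histogram of an 8-bit
slice is split at the image mean m; the sub-histogram at or below m is
equalized onto [0, m] by its own CDF, the one above m onto (m, 255].
Pixels are routed to the sub-LUT of their own side of the mean, so the
mapping never crosses m even where integer rounding disagrees with the
split; ties at exactly m belong to the low half. Constant images (one
degenerate sub-histogram) pass through unchanged. Because each half keeps
its own output range, global brightness is preserved up to discretization
(≤ 2 grey levels on 8-bit images; this bound is exercised on random
128×128 images). Multi-channel slices are rescaled per modality to
[0, 255] and equalized independently; the subsequent z-scoring (population
mean 0 / variance 1, optionally over a brain mask) makes the absolute
scale irrelevant. A 3×3 flat grayscale closing between the two steps
removes small dark artifacts; it is extensive and idempotent.

## Network

The segmenter is a 4-level encoder–decoder. Each encoder level applies
Conv3×3 → ReLU → adaptive attention block (AAB), with 2×2 max-pooling
between levels and a second Conv3×3 as the bottleneck; the decoder
mirrors it with bilinear 2× upsampling, a fusion convolution over the
concatenated skip, and a decoder-side AAB per level, ending in a 1×1
convolution and per-pixel softmax.

**AAB.** Each block fuses three streams of its input F:

    AAB(F) = α·(F ⊙ A_spatial) + β·(F ⊙ A_channel) + γ·(F + CAMFM(F)),

with (α, β, γ) the softmax of per-level learnable logits — a convex
combination, so the branch weights are relative contributions and cannot
trade off against convolution scale. Disabled branches (ablation flags)
are removed from the softmax; with all three disabled the block is an
identity and the network reduces exactly to a plain U-Net (verified by
parameter-count equality against an independent accounting).

**SCHAM.** The spatial map is sigmoid(Conv7×7(concat(channel-max,
channel-mean))); the channel map is sigmoid(FC₂(ReLU(FC₁(GAP(F))))) with
squeeze width max(1, c/r), r = 16 by default (the floor keeps tiny test
networks valid). Skip connections pass encoder features through the
residual refinement F + Dropout(F ⊙ A_spatial ⊙ A_channel, p = 0.2)
before decoder fusion. Each level computes its attention maps once: the
AAB streams and the skip refinement share one SCHAM instance. The
residual form (rather than pure multiplicative recalibration) is used
throughout; it keeps gradients flowing when attention saturates.

**CAMFM (in-network).** A segmented region does not exist mid-network, so
the in-network morphological stream uses differentiable grayscale
morphology: six operator residuals per channel (opening and closing
residuals at 3×3, morphological gradients at 3×3 and 5×5, top-hat and
bottom-hat at 5×5), all built from separable min/max filters. Each
response is standardized per sample (zero mean, unit variance across
h×w×c, ε = 1e-6, so constant inputs map to exactly zero) and the six are
combined with softmax weights from a context head (GAP → dense → 6
logits). Weights are per level, consistent with the per-level AAB logits.

**Mask-level descriptors.** The six named descriptors are computed with
their standard radiomics definitions: solidity (area / convex-hull area),
compactness (perimeter²/4πA), circularity (its reciprocal), GLCM contrast
and homogeneity (distance 1, four directions, 8 grey levels, restricted to
the region by dropping pairs that touch outside pixels), and boundary
strength (mean Sobel magnitude on 4-connected boundary pixels, normalized
by the region's intensity range). Perimeter uses the Freeman chain-code
estimate, which recovers ≈ 2πr on rasterized disks so a disk's
circularity is ≈ 1; the naive count of boundary edge segments would give
the Manhattan perimeter (≈ 8r) and bias circularity to ≈ 0.62. As a
consequence, compactness can dip a few percent below 1 on rasterized
disks — the isoperimetric lower bound of 1 holds only in the continuum.
A single-pixel region uses the unit pixel boundary (perimeter 4). A
constant-intensity region has contrast 0, homogeneity 1, and boundary
descriptor 0 (the intensity range is floored at ε).

## Losses

The training objective is L = 0.5·L_Dice + 0.3·L_CE + 0.2·L_boundary with
an attention penalty λ Σ‖A − 0.5‖²_F, λ = 0.001 (0.5 is the midpoint of
the sigmoid range; a normalized-distribution reference was rejected
because sigmoid maps are not distributions). Dice is soft, macro-averaged
over the three foreground classes with ε-smoothing (both-empty → 0);
cross-entropy clamps probabilities at 1e-7.

The boundary loss is defined on hard boundary point sets: the mean squared
Euclidean distance from each predicted-boundary pixel to its nearest
ground-truth-boundary pixel, computed by a distance transform; an empty
predicted boundary scores the squared image diagonal. This point-set
quantity is not usefully differentiable (its value depends only on set
membership, so a straight-through gradient is identically zero); the
training graph therefore uses the standard distance-transform surrogate
Σ p_fg ⊙ φ², with φ the distance to the GT class boundary normalized by
the image diagonal and classes absent from a slice penalized at the
maximum 1. Reported validation losses always use the exact point-set
definition.

## Metrics

DSC and IoU use the both-empty-→ 1 convention and satisfy
IoU = DSC/(2−DSC) identically. HD95 is the maximum of the two directed
95th-percentile nearest-neighbour distances between boundary point sets,
scaled by pixel spacing — the field-standard reading of the "95th
percentile symmetric surface distance" (the alternative half-sum-of-means
formula is not a percentile statistic and is not implemented).
Confusion-matrix rates report nan, never 0, on empty denominators. Timing
summaries (mean inference time, FPS = n/Σt) are informational only.

## Mutual-information selection

MI is the plug-in estimate over empirical joint frequencies (natural log
internally, bits at the interface; 0·log 0 ≡ 0). Continuous features are
discretized into 16 equal-width bins over their observed range (quantile
bins available, which makes selection invariant to monotone transforms).
Features occupying a single bin get MI = 0 and can never displace an
informative feature. The default keep fraction is 0.8. Selection is
applied to mask-level descriptor/deep-feature tables (a per-sample
selection inside the network cannot be trained through).

## Survival

The Cox model h(t|X) = h₀(t)exp(βᵀX) is fitted by Newton–Raphson on the
Breslow partial likelihood (step-halving, convergence at gradient
max-norm < 1e-6, flagged fit at 100 iterations; standard errors from the
inverse observed information; Breslow baseline hazard exported for
plotting). Harrell's C-index counts concordant comparable pairs with 0.5
for risk ties and is undefined (nan) without comparable pairs.

The proportional-hazards check correlates Schoenfeld residuals with a
transform of event time using the exact score test for the alternative
β(t) = β + θ·g(t), with per-event risk-set variances — the statistic
u = Σ g̃ₖrₖ with variance Σ g̃ₖ²Vₖ − (Σ g̃ₖVₖ)(ΣVₖ)⁻¹(Σ g̃ₖVₖ) and g̃ the
centered transform. The default transform is 1 − KM(t⁻). The classical
approximation that replaces every Vₖ by the average Ī/d was measured to
be severely conservative at cohort sizes around 100 (empirical type-I
error ≈ 0–2% at nominal 5%, reproduced independently by lifelines); the
exact form calibrates to ≈ 3–4% and is the one modern R `survival`
implements.

Survival covariates per subject: WT/TC/ET areas (pixel count × spacing²),
the six descriptors of the WT region, and optionally a global-average-
pooled bottleneck feature vector from the segmentation encoder.

## Synthetic phantoms

The phantom generator emulates the label structure and modality contrast
the pipeline assumes, not MRI physics. Geometry is three concentric disks
(ET ⊂ TC ⊂ WT by construction) with an optional elliptical warp
(row-axis stretch 0.85–1.15 in the randomized generator) so the shape
descriptors are exercised off the circular ideal. Default class means on
the 8-bit scale put background at 60, enhancing tumor at 200 on T1Gd with
necrosis dark at 40, and edema at 140 on FLAIR — the contrast pattern a
channel-attention mechanism is expected to discover. Additive Gaussian
noise defaults to σ = 15, below half the smallest class-mean gap, so the
modality-contrast contract remains testable. Generators are pure
functions of their spec (bit-identical for identical seeds).

Survival cohorts draw event times from an exponential proportional-hazards
model with independent exponential censoring, so event fractions and
moments have closed forms used directly in tests; a helper solves for the
censoring rate that yields a target censoring fraction under a balanced
binary covariate (0.34 ≈ 20% censoring at β = ln 2).

What the phantoms deliberately lack: bias fields, partial-volume effects,
3D continuity, anatomical background structure, inter-site intensity
variation. Passing the end-to-end test therefore shows the architecture,
losses and training loop can learn a multi-class contrast-and-geometry
segmentation problem — not that the model reaches clinical accuracy on
real BraTS data.

## Training and problem sizes

Training uses Adam with per-epoch exponential learning-rate decay
(lr·γ^epoch, γ = 0.95) and early stopping on a held-out validation split,
restoring the best-validation parameters. Default hyperparameters follow
the reference recipe (batch 16, lr 1e-4, 200 epochs, patience 30,
dropout 0.2, loss weights 0.5/0.3/0.2, λ = 0.001). All randomness —
initialization, batch shuffling, dropout, phantom generation — flows from
explicit seeds, so histories are exactly reproducible.

The package's own desk-scale configuration, used by the acceptance script
and the end-to-end tests, is a 64×64 input with encoder channels
(8, 16, 32, 64), trained for 15 epochs on 60 phantoms with batch 4 and
lr 3e-3 (the small-model regime: fewer, noisier gradients per epoch favor
a larger step than the full-scale recipe), evaluated on 20 held-out
phantoms. On this setup the full attention model reaches WT Dice ≈ 0.95
and is compared against the seed-matched plain-U-Net ablation. The
reference architecture's printed size (28.3 M parameters, 156.7 GFLOPs at
224×224) is under-determined by the published description, so the
analytic profiler reports the parameters and MACs of the configuration
actually built, per component (encoder, spatial attention, channel
attention, CAMFM, decoder).

## Numerical choices and edge cases

- ε-conventions: Dice smoothing 1e-7 (both-empty → loss 0, score 1);
  probability clamp 1e-7; standardization ε 1e-6 (constant maps → 0).
- Softmax/log-softmax use max-subtraction; sigmoid clips logits at ±60.
- Max-pool gradients route to the first argmax on exact ties (plateaus
  are common after morphology; any subgradient is valid).
- The 70/15/15 train/validation/test split helper is deterministic in the
  seed; the estimator's internal early-stopping split defaults to 30%.
- Network weights and activations are float32; gradient-check tests build
  float64 models. Checkpoints round-trip predictions bit-exactly.

## Known limitations

2D only; single-resolution bilinear decoder (transposed convolution not
implemented); no batch normalization (the reference recipe lists it, but
at desk scale batches of 4 make batch statistics more harmful than
helpful, and the phantom task trains cleanly without it); the plain
attention-vs-ablation comparison on near-saturated phantom tasks has a
thin margin and is a direction check, not an effect-size claim; Breslow
ties handling only; the grading classifier around the tumor-grade
accuracy tables is out of scope (only its metrics are provided).
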