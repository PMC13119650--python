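# haaunet

Hybrid adaptive-attention U-Net for multi-modal brain-tumor MRI analysis:
segmentation of BraTS-style tumor sub-regions, morphological shape
descriptors, mutual-information feature selection, standard evaluation
metrics, and a Cox proportional-hazards survival head — with a synthetic
phantom generator so the entire pipeline runs and is tested without any
external data.

## Who this is for

Researchers in medical image analysis who want a transparent, fully tested
reference implementation of an attention U-Net variant that couples deep
features with explicit tumor morphology, and a reproducible desk-scale
harness for its surrounding pipeline (preprocessing, metrics, feature
selection, survival modelling). Everything runs on numpy/scipy — the
network and its reverse-mode gradient engine are part of the package — so
there is no GPU or deep-learning-framework dependency.

## The model

Inputs are 4-channel 2D slices (T1, T1Gd, T2, T2-FLAIR) with labels
{background, NCR, ED, ET}; evaluation uses the nested composite regions
WT = NCR∪ED∪ET, TC = NCR∪ET, ET. The segmenter is a 4-level
encoder–decoder in which every level carries an **adaptive attention
block**

    AAB(x) = α·F_spatial(x) + β·F_channel(x) + γ·F_morphological(x),

a convex combination (softmax-normalized per level) of

- a **spatial attention** stream — sigmoid(Conv7×7 over the channel-max
  and channel-mean maps),
- a **channel attention** stream — squeeze-and-excite with reduction
  ratio r = 16,
- a **morphological stream** — six differentiable grayscale-morphology
  operator responses (opening/closing residuals, gradients, top/bottom-hat)
  standardized and mixed by context-adaptive weights (CAMFM).

Skip connections are refined by the spatial-channel hybrid attention
module, F + Dropout(F ⊙ A_spatial ⊙ A_channel), before decoder fusion.
Training minimizes 0.5·Dice + 0.3·cross-entropy + 0.2·boundary plus an
attention-uniformity penalty (λ = 0.001) with Adam, exponential LR decay
(γ = 0.95) and early stopping. Preprocessing is brightness-preserving
bi-histogram equalization (histogram split at the mean, each half
equalized into its own range), a 3×3 grayscale closing, and per-modality
z-scoring. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from haaunet import (HAAUNetSegmenter, BBHEPreprocessor, make_phantom_dataset,
                     evaluate_regions, extract_descriptors, composite_views,
                     generate_survival_cohort, SurvivalCohortSpec, cox_fit,
                     c_index, schoenfeld_check)

# --- segmentation on synthetic phantoms -------------------------------
Xtr, ytr = make_phantom_dataset(60, image_size=64, seed=0)
Xte, yte = make_phantom_dataset(20, image_size=64, seed=1)
pp = BBHEPreprocessor()
model = HAAUNetSegmenter(image_size=64, encoder_channels=(8, 16, 32, 64),
                         batch_size=4, learning_rate=3e-3, max_epochs=15,
                         val_fraction=0.2, seed=0)
model.fit(pp.fit_transform(Xtr), ytr)
pred = model.predict(pp.transform(Xte))
scores = [evaluate_regions(pred[i], yte[i]) for i in range(20)]
for region in ("WT", "TC", "ET"):
    print(f"{region} Dice {np.mean([s[region]['dice'] for s in scores]):.3f}")

# --- morphological descriptors of one whole-tumor region --------------
wt = composite_views(yte[0])["WT"]
d = extract_descriptors(wt, Xte[0][:, :, 1])
print(f"solidity {d.solidity:.3f}  circularity {d.circularity:.3f}  "
      f"contrast {d.contrast:.3f}")

# --- Cox survival head on a simulated cohort --------------------------
recs = generate_survival_cohort(SurvivalCohortSpec(
    n_subjects=500, beta_true=(np.log(2),), censor_rate=0.34, seed=1))
fit = cox_fit(recs)
risk = np.array([fit.beta @ r.covariates for r in recs])
print(f"beta_hat {fit.beta[0]:.3f} (true ln2 = 0.693, SE {fit.se[0]:.3f})")
print(f"C-index {c_index(risk, recs):.3f}   "
      f"PH p-value {schoenfeld_check(fit, recs)[0]:.2f}")
```

Output (a few minutes on one CPU core):

```
WT Dice 0.951
TC Dice 0.728
ET Dice 0.744
solidity 0.965  circularity 0.942  contrast 2.190
beta_hat 0.680 (true ln2 = 0.693, SE 0.103)
C-index 0.587   PH p-value 0.48
```

The three Dice rows score the trained tiny network's whole-tumor, tumor-core
and enhancing-tumor masks on 20 held-out phantoms (15 epochs is deliberately
short; the small tumor-core classes are the last to converge and their Dice
keeps rising with more epochs). The descriptor line shows
the whole-tumor region of a held-out phantom is nearly convex and circular
(it is a noisy warped disk) with moderate co-occurrence contrast on T1Gd.
The survival block recovers the simulated log-hazard ratio ln 2 within one
standard error, yields the concordance expected for a single binary
covariate at this effect size, and the Schoenfeld test correctly finds no
proportional-hazards violation (p > 0.05).

## Command line

`haaunet` exposes the pipeline as verbs: `phantoms`, `preprocess`, `train`,
`predict`, `evaluate`, `features`, `select`, `survival fit|cindex`,
`attention`, `profile`. For example:

```bash
haaunet phantoms --n 10 --size 64 --seed 0 --out cases/
haaunet train --n-phantoms 80 --epochs 15 --seed 0 --checkpoint model.npz
haaunet predict --checkpoint model.npz --case cases/case_0000 --out seg.nii.gz
haaunet profile --size 224 --channels 64,128,256,512
```

Real BraTS-style cases (one NIfTI per modality with `_t1/_t1ce/_t2/_flair`
suffixes plus `_seg` labels) load through the same `load_case` path the
phantom writer uses.

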