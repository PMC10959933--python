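# fovecast

Predicting the 6-month postoperative appearance of the macula after
full-thickness macular hole (FTMH) surgery, directly from the preoperative
OCT volume scan.

FTMH surgery (vitrectomy with ILM peeling or an inverted ILM flap) closes
the hole in most eyes, but surgeons and patients cannot see in advance what
the healed fovea will look like — whether the outer retinal bands recover,
how thick the fovea will be. `fovecast` implements a generative pipeline
that answers this with an image: given a preoperative B-scan, it produces a
predicted postoperative B-scan, and then measures how well such predictions
agree with ground truth.

The pipeline has four stages:

1. **Registration** — the retinal pigment epithelium (RPE) is extracted
   from both the preoperative and postoperative cubes as a height map
   h(y, x); the preoperative cube is rigidly aligned onto the postoperative
   RPE by closed-form least squares (orthogonal Procrustes / Kabsch on the
   grid-corresponded point clouds in physical µm). The RPE is the right
   landmark because surgery does not disturb it.
2. **Preprocessing** — each B-scan is cropped to a 448-pixel square centred
   on its intensity centre of mass (5250.0 µm × 1164.8 µm at native
   sampling), Lanczos-downscaled to 224 × 224, restricted to the 200 slices
   centred on the fovea, and labelled with a condition c ∈ {0,1,2,3}
   encoding the slice's distance band from the fovea. Training pairs are
   augmented six-fold (original, horizontal flip, +4° and +8° rotations
   about the COM, ±15-pixel lateral shifts); a weighted sampler equalises
   the condition distribution.
3. **Conditional VAE** — encoder: four 3×3 stride-1 convolution blocks with
   channel doubling, each with batch normalisation, leaky-ReLU, dropout and
   2×2 max pooling (224 → 14), then five fully connected layers producing
   µ and log σ²; sampler: z = µ + σ ⊙ ε; decoder: the mirror network with
   nearest-neighbour unpooling and a sigmoid output. The loss is
   BCE + λ·(1 − MS-SSIM) + β(t)·KLD for the first 400 epochs, switching to
   a perceptual feature distance afterwards; β ramps linearly from 0 to 1
   (KLD warm-up). The epoch with the smallest validation loss supplies the
   final weights; inference is deterministic (z = µ).
4. **Evaluation** — the predicted (AI) and ground-truth (GT) central slices
   are binarised into neurosensory-retina masks and compared
   (accuracy/precision/recall/F1); foveolar height (FH), mean foveal
   thickness (MFT, ±500 µm) and nasal/temporal parafoveal thickness
   (MNPT/MTPT, 500–1500 µm) are profiled; cohort agreement is summarised by
   Bland–Altman 95 % limits of agreement on percentage differences
   (acceptable when both limits are within ±30 %); and the continuity of
   the external limiting membrane (ELM) and ellipsoid zone (EZ) is
   classified.

Because clinical OCT volumes of surgical cohorts are protected patient
data, the package ships a **synthetic phantom generator**: layered retinal
cubes with ten distinguishable bands, a foveal pit, a full-thickness crater
in the preoperative member, optional residual ELM/EZ defects in the
postoperative member, a known rigid misalignment, and additive noise. Every
stage is developed and verified against phantom ground truth.

The network itself runs on a compact reverse-mode automatic-differentiation
engine (`fovecast.nn`, pure numpy) with finite-difference-verified
gradients; MS-SSIM is implemented as a differentiable graph operation, and
the perceptual loss is a fixed, seeded random-convolution feature distance
(deterministic, no pretrained weights).

## Worked example

```python
import numpy as np
from fovecast.cli import run_pipeline

res = run_pipeline(n_cases=8, seed=0, window=4,
                   vae_overrides=dict(max_epochs=6, recon_switch_epoch=6,
                                      kld_warmup_epochs=3))
print("splits", res["split_counts"])
print("pairs", res["n_train_pairs"], res["n_validation_pairs"])
print("registration residual (um), worst:",
      round(max(res["registration_rms_after_um"]), 2))
print("validation loss:", [round(h["val_loss"], 3) for h in res["history"]])
print("held-out F1, trained vs untrained:",
      round(np.mean(res["f1_trained"]), 3),
      round(np.mean(res["f1_baseline"]), 3))
```

prints (seed 0):

```
splits {'train': 6, 'validation': 1, 'test': 1}
pairs 144 4
registration residual (um), worst: 2.4
validation loss: [81.614, 4.48, 2.108, 1.607, 1.188, 0.937]
held-out F1, trained vs untrained: 0.683 0.549
```

Six of eight phantom cases train the model (4:1:1 split, 6 slices per case,
six-fold augmentation → 144 pairs). Registration leaves the pre/post RPE
surfaces within half an axial pixel (2.4 µm at the 5.2 µm smoke pitch).
The validation loss (reconstruction + KLD at full weight) falls by two
orders of magnitude across epochs as the posterior regularises and the
reconstructions sharpen, and the trained predictor segments the
postoperative neurosensory retina markedly better than the
untrained-weights baseline (F1 0.68 vs 0.55 after this deliberately tiny
six-epoch run; the 20-case smoke study in `scripts/acceptance.py` trains
longer and separates further, reaching F1 ≈ 0.8 vs ≈ 0.45).

A shell interface wraps the same stages:

```bash
fovecast simulate --n-cases 6 --out cohort/ --seed 1
fovecast register --pre cohort/case0000_pre.tiff --post cohort/case0000_post.tiff \
    --out cohort/case0000_registered.tiff --report cohort/case0000_registration.json
fovecast prepare --cohort cohort/ --out dataset/ --window 200
fovecast train --manifest dataset/manifest.csv --out run/
fovecast evaluate --cohort cohort/ --model run/ --out results/
fovecast report --results results/
```

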