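# parotidseg

Parotid-gland segmentation and planning-CT → CBCT contour propagation for
adaptive head-and-neck radiotherapy.

The parotid glands are radiosensitive organs at risk: irradiating them
causes xerostomia, and they shrink measurably over a course of
radiotherapy, so clinics need to know *when the plan no longer matches the
anatomy*.  This package implements that decision-support loop at desk
scale:

1. **Segmentation** — an attention-gated 3D U-Net (encoder filters
   16/32/64/128, 256-filter bottleneck, gates on every skip connection)
   delineates the left/right parotids on preprocessed CT (common spacing
   3.0 × 0.87 × 0.87 mm, HU window (−160, 240) mapped to [0, 1]).
   Training uses 96³ patches (80% gland-centred / 20% background), the
   combined loss `CE + (1 − soft-DSC)`, Adam, and best-validation-DSC
   checkpointing; evaluation reports DSC, HD95 (mm), precision and recall
   on the united parotid mask.
2. **Registration** — histogram matching, rigid + affine mutual-information
   alignment (32-bin MI, 4-level pyramid, regular-step gradient descent),
   then symmetric-forces demons (σ = 3 voxels for pCT→CBCT1, σ = 2 with
   600 iterations for CBCT1→CBCT5), with masks warped nearest-neighbour.
3. **Replanning assessment** — gland volumes on week 1 and week 5 and the
   signed percentage change `100·(v5 − v1)/v1`, scored against reference
   changes with MAE, RMSE and Pearson correlation.

Everything — including the network's forward/backward passes and both
registration algorithms — runs on numpy/scipy; no GPU or deep-learning
framework is required.  A synthetic head-phantom generator (known analytic
gland volumes, CBCT-like degradation, exactly known deformation fields and
shrink factors) makes the whole pipeline testable without any clinical
data.

## Worked example

```python
import numpy as np
from parotidseg import (
    DeformationSpec, PhantomConfig, apply_known_deformation, gland_volume,
    make_head_phantom, propagate_masks, simulate_cbct, unite_parotids,
    volumetric_pct_diff,
)

cfg = PhantomConfig(shape=(56, 56, 56), spacing=(1.5, 1.5, 1.5),
                    gland_center_frac=(0.5, 0.5, 0.28),
                    gland_semi_axes_mm=(10.0, 12.0, 9.0), seed=5)
pct, masks = make_head_phantom(cfg)          # planning CT + parotid labels
cbct1 = simulate_cbct(pct, seed=6)           # week-1 CBCT

shrink = DeformationSpec(type="gland_shrink", shrink=0.90,
                         gland_centers_mm=cfg.gland_centers_mm(),
                         gland_semi_axes_mm=cfg.gland_semi_axes_mm)
week5, _, _, _ = apply_known_deformation(pct, masks, shrink)
cbct5 = simulate_cbct(week5, seed=7)         # week-5 CBCT, glands at 0.9^3 volume

m1, m5, reports = propagate_masks(pct, cbct1, cbct5, masks, seed=0)
v1, v5 = gland_volume(unite_parotids(m1)), gland_volume(unite_parotids(m5))
print(f"week-1 {v1:.2f} mL, week-5 {v5:.2f} mL, change {volumetric_pct_diff(v1, v5):.1f}%")
```

prints (phantom, seed-dependent at the third digit):

```
week-1 9.06 mL, week-5 6.73 mL, change -25.7%
```

The analytic truth for a 0.90 isotropic shrink is `0.9³ − 1 = −27.1%`; the
measured −25.7% shows the intensity-driven pipeline recovering most — not
all — of a low-contrast (15 HU) gland change through CBCT-like noise, which
is exactly the behaviour the volumetric-agreement tests quantify cohort-wide
(MAE < 8 percentage points, Pearson r > 0.7 on ten phantom patients).

A CLI mirrors the library: `parotidseg simulate | preprocess | train |
predict | evaluate | register | assess` (see `parotidseg --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's end-to-end phantom workflow from scratch: it builds
the attention U-Net and checks a forward pass, generates a phantom patient
(planning CT, masks, week-1/week-5 CBCTs with a known gland shrink),
propagates the masks through both registration stages, and prints the
measured against the analytic volume change, writing the results JSON to
`--out`.

## Layout

- `src/parotidseg/grid.py`, `io.py`, `preprocess.py` — containers, NIfTI I/O,
  resampling and HU windowing
- `src/parotidseg/nn/` — numpy attention U-Net (layers, network, Adam)
- `src/parotidseg/training.py` — patches, loss, folds, train loop
- `src/parotidseg/evaluate.py` — sliding-window inference, DSC/HD95/P/R
- `src/parotidseg/registration.py` — histogram matching, MI affine, demons
- `src/parotidseg/replanning.py` — mask propagation and volume-change scoring
- `src/parotidseg/phantom.py` — synthetic head phantoms with analytic truth
- `docs/methods.md` — model, parameters, design choices, limitations
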