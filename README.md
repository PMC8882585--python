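# pterymeter

Quantifying pterygium progression from anterior-segment eye photographs.

A pterygium is a fibrovascular overgrowth of the conjunctiva that invades
the peripheral cornea; once its head has advanced more than about 3 mm onto
the cornea, surgical resection is indicated. `pterymeter` implements a
three-stage measurement system for staging that progression from an
ordinary external eye photograph:

1. **Cornea segmentation** — a U-Net predicts the cornea region; because
   the cornea is anatomically elliptical, the jagged network boundary is
   regularized by a direct least-squares ellipse fit (smallest algebraic
   distance, Halir–Flusser formulation) and re-rasterized.
2. **Pterygium segmentation** — an attention-gated U-Net++ predicts the
   pterygium within the cornea.  One additive attention gate sits before
   every up-sampling step of every nested decoder node; the coarser feature
   map about to be up-sampled acts as the gating signal that re-weights the
   concatenated skip features, suppressing background activations.
3. **Morphometry** — with cornea mask `C` and pterygium mask `P` at a
   common 512×512 working resolution, the residual cornea is the pixel-wise
   XOR `C ⊕ P`.  From the cornea's longest horizontal chord we take the
   center and the transverse radius `RD` (px); `MD` (px) is the minimum
   Euclidean distance from that center to the residual boundary.  The
   invasion width and area follow from the assumed transverse corneal
   diameter `d` (default 11.5 mm; anatomically 10.7–12.58 mm, and the true
   diameter can be supplied per eye):

   ```
   WP   = (d / 2) · (1 − MD / RD)                [mm]
   Area = π (d / 2)² · (A_P / A_C)               [mm²]
   ```

   Staging: class 0 (normal) when WP = 0, class 1 (observe) when
   0 < WP < 3 mm, class 2 (surgery) when WP ≥ 3 mm.

The package also ships the full evaluation battery used to validate such a
system against clinician ratings — Dice / mean-IoU / pixel accuracy,
Pearson χ² with the contingency coefficient `C = √(χ²/(n+χ²))`, Cohen's
kappa, binary diagnostic metrics, ROC/AUC with the Youden-optimal cutoff,
and Bland–Altman limits of agreement — plus a synthetic phantom generator
that renders eye images with pixel-exact masks and closed-form truth
measurements, so every stage is testable without clinical data.

The networks, their losses and the RMSprop/Adam optimizers run on a compact
numpy reverse-mode autodiff engine included in `pterymeter.nn`; everything
trains and runs on a single CPU at the package's working resolutions.

## Worked example

```python
import numpy as np
from pterymeter import (EyePhantomParams, generate_phantom, measure,
                        CrossTab, chi_square_with_C, cohen_kappa)

# A circular cornea of radius 200 px with a pterygium invading half the
# transverse radius from the nasal side:
params = EyePhantomParams(image_height=512, image_width=512,
                          cornea_center=(256, 256),
                          semi_axis_a=200, semi_axis_b=200,
                          pterygium_side="right", invasion_fraction=0.5)
sample = generate_phantom(params, seed=1)
print(sample.truth.wp_mm)            # 2.875  (closed form: 5.75 × 0.5)

r = measure(sample.cornea_mask, sample.pterygium_mask)
print(round(r.wp_mm, 3), r.status)   # 2.904 1

# Agreement between automated staging and clinician ratings over 239 eyes:
tab = CrossTab(np.array([[121, 0, 0], [0, 68, 8], [0, 4, 38]]))
chi = chi_square_with_C(tab)
print(round(chi.chi2, 3), chi.df, round(chi.C, 3))   # 386.233 4 0.786
print(round(cohen_kappa(tab).kappa, 3))              # 0.918
```

The measured 2.904 mm differs from the analytic 2.875 mm only by boundary
rasterization (≈0.03 mm here); status 1 means "pterygium to be observed".
The crosstab statistics say automated staging and visual inspection are
strongly associated (C = 0.786 against a 3×3 maximum of 0.8165) and highly
consistent (κ = 0.918 > 0.8).

## Command line

```sh
pterymeter generate --out data --n-normal 5 --n-pterygium 5 --seed 1
pterymeter measure  --dataset data --out results
pterymeter evaluate --pred results/measurements.csv \
                    --ref data/manifest.csv --out results/report.json
pterymeter train    --dataset data --stage pterygium --out ckpt.npz
pterymeter segment  --checkpoint ckpt.npz --image data/images/sample_0005.png \
                    --out mask.png
```

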