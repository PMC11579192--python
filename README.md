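# esfcm

Enhanced spatial fuzzy C-means (esFCM) segmentation of 3D T1-weighted brain
MRI into cerebrospinal fluid (CSF), gray matter (GM) and white matter (WM),
with simultaneous polynomial bias-field correction.

Plain fuzzy C-means clusters voxels by intensity alone and degrades quickly
under noise and scanner inhomogeneity. `esfcm` adds two refinements:

- **Spatial membership energy** — each iteration, the membership
  μ_ij = 1 / Σ_c (D_ij/D_cj)^(2/(m−1)) (with D_ij = |Î_j − V_i|) is
  multiplied pointwise by the mean of the previous iteration's memberships
  over the voxel's 6 face-connected neighbours and renormalised, smoothing
  label noise without an explicit regulariser.
- **SSIM-weighted bias correction** — the smooth additive bias field is
  modelled as a quadratic polynomial of the voxel coordinates and fit by
  weighted least squares, β̂ = (AᵀWA)⁻¹AᵀW(I − L), to the residual between
  the image I and its FCM reconstruction L_j = Σ_i V_i μ_ij. The weights W
  come from a structural-similarity (SSIM) map between the gradient
  magnitudes of I and L; the mean SSIM serves as a cost that selects the
  best-filtered image Î = I − Aβ̂.

The package also ships the evaluation metrics (Dice, exact Hausdorff
distance in mm, accuracy) and a synthetic three-tissue phantom generator
with plantable noise (0/20/40%) and bias (0/5/10%) degradations, so the
whole pipeline is testable without any external data. It is aimed at
researchers who need a transparent, fully scriptable tissue segmentation
baseline. See `docs/methods.md` for the model details and limitations.

## Worked example

```python
import numpy as np
from esfcm import (FCMConfig, PhantomSpec, evaluate_segmentation,
                   generate_phantom, run_esfcm)

# a 64^3 phantom at 20% noise / 5% bias, and its ground truth
ph = generate_phantom(PhantomSpec(noise_pct=20.0, bias_pct=5.0, seed=0))

result = run_esfcm(ph.image, FCMConfig())          # full esFCM
plain = run_esfcm(ph.image, FCMConfig(             # degenerate plain FCM
    enable_spatial=False, enable_bias_correction=False))

for name, res in [("esFCM", result), ("FCM", plain)]:
    t = evaluate_segmentation(ph.labels, res.labels,
                              evaluation_mask=ph.image.mask)
    d = t[t["class"].isin(["CSF", "GM", "WM"])]["dice"].round(3).tolist()
    print(name, d, "centers", np.round(res.sorted_centers, 1))
```

prints

```
esFCM [0.822, 0.749, 0.843] centers [ 38.8 112.1 190.6]
FCM [0.778, 0.653, 0.769] centers [ 26.3 104.3 196.3]
```

Per-tissue Dice (CSF, GM, WM) against the phantom truth: the spatial energy
and bias correction recover roughly 5–10 Dice points over plain FCM at this
noise level, and the recovered centers sit nearer the true class means
(50/120/200). On the noiseless phantom both configurations reach Dice 1.0
for every tissue.

The same workflow is available from the shell:

```sh
esfcm phantom --out ph --noise 20 --bias 5 --seed 0     # synthesize
esfcm segment --input ph/phantom_n20_b5.nii.gz \
              --mask ph/phantom_n20_b5_labels.nii.gz --out seg
esfcm evaluate --gt ph/phantom_n20_b5_labels.nii.gz \
               --seg seg/labels.nii.gz --out metrics.csv
```

`segment` writes the label map, per-tissue probability maps, the corrected
image and fitted bias field, and a `provenance.json` with the effective
configuration; `phantom --grid` emits all nine noise × bias combinations.

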