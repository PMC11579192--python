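# Methods

## Model and procedure

`esfcm` segments a skull-stripped 3D T1-weighted MRI volume into C tissue
classes (by default C = 3: CSF, GM, WM) by fuzzy C-means clustering of voxel
intensities, extended in two ways: a spatial refinement of the memberships,
and an interleaved estimate of the scanner's smooth intensity inhomogeneity
("bias field").

**Fuzzy C-means core.** Each masked voxel j carries a membership
μ_ij ∈ [0, 1] to every cluster i, with Σ_i μ_ij = 1.  Memberships follow the
standard FCM form

    μ_ij = 1 / Σ_c (D_ij / D_cj)^(2/(m−1)),   D_ij = |Î_j − V_i|,

where Î is the current bias-corrected image, V_i the cluster centers, and
m > 1 the fuzziness exponent.  Centers are updated as the μ^m-weighted mean
of the intensities.  A voxel at zero distance from a center receives
indicator membership (split equally over tied centers) — the standard
resolution of the FCM singularity.  Internally the membership ratio is
scaled by the per-voxel minimum distance so that very small distances cannot
overflow.

**Spatial refinement.** From the second iteration on, a neighbourhood energy
E_ij is computed as the mean of the *previous* iteration's combined
membership of cluster i over the six face-connected neighbours of voxel j.
The combined membership is the pointwise product μ_ij · E_ij, renormalised
per voxel so the unit-sum constraint continues to hold (without
renormalisation the center-update weights drift toward zero).  Neighbours
outside the grid or the brain mask are excluded and the mean is taken over
the remaining count; zero-padding instead would bias memberships downward
along the cortical boundary.  Renormalisation preserves hard memberships
exactly, so the refinement is inert on a perfectly separated image and acts
as a local smoother on noisy ones.

**Bias-field correction.** The inhomogeneity is modelled as an *additive*
field that is a quadratic polynomial of the voxel coordinates: a 10-column
design matrix A over the monomials {1, x, y, z, x², y², z², xy, xz, yz},
with coordinates normalised affinely to [−1, 1] per axis to bound the
condition number.  Each iteration forms the FCM reconstruction of the image,
L_j = Σ_i V_i μ̄_ij, and fits the residual I − L by weighted least squares,

    β̂ = argmin_β ‖W^(1/2) (I − L − Aβ)‖²,

solved by QR-based least squares on √w-scaled rows (never by inverting the
normal equations).  The weights come from a structural-similarity (SSIM) map
between the gradient magnitudes of the raw image and of L, computed in a 7³
uniform window with absolute stabilising constants c1 = 0.0001 and
c2 = 0.0009, and mapped to weights by w = (1 − s)/2 — up-weighting regions
the current prediction explains poorly.  The opposite reading, w = (1 + s)/2,
is one flag away (`weight_transform="important"`); the direction is
genuinely ambiguous and neither is asserted as canonical.  The corrected
image is Î = I − Aβ̂ inside the mask, recomputed from the raw image at every
update so corrections do not accumulate.

**Cost-guarded filtering.** The mean of the SSIM map over the mask serves as
a cost (higher = the prediction explains the image's structure better).  The
filtered image achieving the best cost so far is used as the working image
of subsequent iterations *and* returned as the output.  The guard matters:
if every new fit were fed back unconditionally, fuzzy memberships under
heavy noise compress L toward the global intensity mean, the polynomial fit
absorbs genuine tissue structure, and the contrast collapses iteration over
iteration (mean per-tissue Dice drops well below plain FCM at the 20% noise
level).  Rejecting fits whose cost is below the best seen keeps a poor fit
from eroding the image and is what makes the cost function meaningful.  If
the SSIM map is 1 everywhere up to float rounding (the prediction is exact,
so all weights vanish), the update falls back to the unweighted fit.

**Initialisation and termination.** Centers are initialised by multi-Otsu
thresholding of the masked intensities (256-bin histogram, between-class
variance criterion) and the initial combined membership is the one-hot
encoding of the threshold classes, so the neighbourhood energy is defined at
the second iteration.  The loop stops when the maximum absolute center
change falls below `tol` (default 1e-4 on the intensity scale) or at
`max_iter` (default 50); non-convergence is flagged on the returned state,
not raised.  Final clusters are sorted by ascending center intensity and
mapped to labels 1..C — the T1 ordering CSF < GM < WM — so the labelling is
invariant to initialisation order.  Hard labels are the per-voxel argmax
(ties to the lowest label); background voxels get label 0 and membership 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_clusters` | 3 | tissue classes (CSF/GM/WM) |
| `fuzziness` m | 2.0 | softness of memberships; 2 is the customary FCM choice |
| `max_iter` | 50 | iteration cap |
| `tol` | 1e-4 | center-change convergence threshold, intensity units |
| `bias_update_every` | 1 | bias refit cadence in iterations |
| `ssim_window` | 7 | side of the cubic SSIM window, voxels |
| `c1`, `c2` | 1e-4, 9e-4 | SSIM stabilisers (absolute) |
| `weight_transform` | "neglected" | SSIM→weight direction, see above |

`raw_image_in_center_update` switches the center update from the filtered to
the raw intensities; the filtered image is the default because the distance
computation uses it, and mixing the two images makes the fixed point
inconsistent.

## The synthetic phantom

The phantom is three nested ellipsoids on a cubic grid (default 64³): an
outer CSF shell (which also defines the brain mask), a GM shell, and a WM
core, with semi-axes defaulting to 0.88/0.72/0.50 of the grid half-extent
and piecewise-constant intensities 50/120/200.  Degradations follow the
percent-of-brightest-tissue convention: additive Gaussian noise with
sd = noise_pct/100 × 200, and an additive quadratic field with coefficients
drawn standard-normal from the seed and rescaled so its peak magnitude over
the mask is bias_pct/100 × 200.  Noise and bias are applied inside the mask
only, bias before noise by default (the order is recorded and configurable),
and labels are untouched by either.  Everything is deterministic given the
seed.

What the phantom does *not* emulate: partial-volume mixing at tissue
boundaries, cortical folding, Rician noise statistics, or multiplicative
bias physics.  Passing tests on the phantom therefore demonstrates
correctness of the algorithm's mechanics (membership algebra, planted-field
recovery, robustness ordering), not clinical-grade accuracy on real scans.

## Numerical choices

- All intensities are handled in double precision regardless of on-disk
  dtype; the weighted normal equations are ill-conditioned in single
  precision.
- The SSIM map uses population (uniform-window) moments and is clipped to
  [−1, 1] against rounding; both SSIM factors are individually bounded by 1.
- The Hausdorff distance is the exact max–min form over voxel centers scaled
  by the spacing (no percentile), computed via directed nearest-neighbour
  queries.
- Dice of two empty masks is defined as 1; the Hausdorff distance of an
  empty mask is an error.
- Rank deficiency of the (weighted) design matrix raises with condition
  diagnostics rather than returning a least-norm solution silently.

## Known limitations

**The bias field's class-piecewise-constant component is unidentifiable.**
The observed image I = clean + bias determines the decomposition only up to
fields that are constant on each tissue class: the center update absorbs the
class-mean of any residual field into the centers, so in particular the
global mean (DC) of the bias over the mask cannot be recovered by any
intensity-based method that estimates the class means from the data.  On
phantoms with a planted field this shows up as a near-constant offset
between the corrected image and the clean truth, equal to about the planted
field's mask mean; the labels are unaffected (the offset shifts all centers
equally).  Fitting with a known clean prediction (L = clean) anchors the DC
and recovers all 10 coefficients to machine precision.  The concentric
phantom geometry additionally correlates radial quadratics with the class
partition, so those components are recovered less sharply than on real,
interdigitated anatomy.

**Additive bias model.** Real MRI inhomogeneity is closer to multiplicative;
the additive quadratic model is a deliberate fidelity choice matching the
subtraction-based correction, and the phantom plants its fields the same
way.

**Problem sizes.** The test suite and the reproduction script run on 48³–64³
phantoms with up to five replicate seeds per condition, sizes at which every
pipeline stage (including the 6-neighbour energy and the 7³ SSIM window) is
exercised with realistic masked-voxel counts (~9 × 10⁴).
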