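"""Polynomial bias-field estimation weighted by a gradient-SSIM map.

MRI intensity inhomogeneity is modelled as a smooth additive field that is a
quadratic polynomial of the voxel coordinates.  Given the clustering's
prediction of the image, L_j = sum_i V_i * mu_ij, the residual I - L is fit
by weighted least squares over a 10-column quadratic design matrix; the
weights come from a structural-similarity (SSIM) map between the gradient
magnitudes of the observed image and of the prediction, so that regions where
the current fit explains the image poorly can be emphasised.  The corrected
(filtered) image is I_hat = I - A @ beta inside the brain mask.

The additive model is deliberate: correction is by subtraction of the fitted
field, and the phantom generator plants its bias fields the same way.
Coordinates are normalised affinely to [-1, 1] per axis to bound the
condition number of the design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .volume_io import Volume

__all__ = [
    "PolynomialBasis",
    "BiasFit",
    "SSIMMap",
    "DEFAULT_C1",
    "DEFAULT_C2",
    "DEFAULT_SSIM_WINDOW",
    "build_basis",
    "predict_image",
    "gradient_volume",
    "ssim_map",
    "fit_bias_ols",
    "fit_bias_wls",
    "weights_from_ssim",
    "apply_bias_correction",
    "mean_ssim_cost",
]

#: SSIM stabilising constants (absolute, not scaled by a data range).
DEFAULT_C1 = 0.0001
DEFAULT_C2 = 0.0009
#: Side of the cubic uniform SSIM window, in voxels.
DEFAULT_SSIM_WINDOW = 7

#: Deterministic monomial order of the quadratic basis.
MONOMIAL_NAMES = ("1", "x", "y", "z", "x^2", "y^2", "z^2", "xy", "xz", "yz")


@dataclass
class PolynomialBasis:
    """Design matrix of quadratic monomials over masked voxels.

    Columns follow ``MONOMIAL_NAMES``; coordinates are mapped affinely to
    [-1, 1] per axis over the full grid extent (a single-voxel axis maps
    to 0).  Rows correspond to mask-true voxels in C order.
    """

    A: np.ndarray
    shape: tuple[int, int, int]
    mask: np.ndarray
    names: tuple[str, ...] = MONOMIAL_NAMES


@dataclass
class BiasFit:
    """A fitted bias field and the corrected image."""

    coefficients: np.ndarray       # length-10 beta-hat
    fitted_bias: np.ndarray        # A @ beta-hat over masked voxels
    filtered: Volume               # I - bias inside the mask, I outside


@dataclass
class SSIMMap:
    """Per-voxel structural similarity in [-1, 1] with its provenance."""

    values: np.ndarray
    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2
    window: int = DEFAULT_SSIM_WINDOW


def _normalized_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    axes = []
    for dim in shape:
        if dim > 1:
            axes.append(2.0 * np.arange(dim) / (dim - 1) - 1.0)
        else:
            axes.append(np.zeros(1))
    return list(np.meshgrid(*axes, indexing="ij"))


def build_basis(shape: tuple[int, int, int], mask: np.ndarray) -> PolynomialBasis:
    """Build the n_masked x 10 quadratic design matrix for a grid and mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} != grid shape {tuple(shape)}")
    n = int(mask.sum())
    if n < 10:
        raise ValueError(
            f"mask has {n} voxels; at least 10 are needed to fit a quadratic field"
        )
    x, y, z = (g[mask] for g in _normalized_coords(tuple(shape)))
    A = np.column_stack(
        [np.ones(n), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    )
    return PolynomialBasis(A=A, shape=tuple(shape), mask=mask)


def predict_image(centers: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """FCM reconstruction of the image: L_j = sum_i V_i * mu_ij."""
    centers = np.asarray(centers, dtype=np.float64)
    membership = np.asarray(membership, dtype=np.float64)
    if membership.shape[0] != centers.shape[0]:
        raise ValueError(
            f"{centers.shape[0]} centers vs {membership.shape[0]} membership rows"
        )
    return centers @ membership


def gradient_volume(volume: Volume) -> np.ndarray:
    """Spacing-aware gradient-magnitude grid.

    Central differences in the interior, one-sided at the boundaries; exact
    for linear intensity fields.
    """
    data = volume.data
    if min(data.shape) < 2:
        raise ValueError("gradient needs at least 2 voxels per axis")
    grads = np.gradient(data, *volume.spacing)
    return np.sqrt(sum(g * g for g in grads))


def ssim_map(
    a: np.ndarray,
    b: np.ndarray,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    window: int = DEFAULT_SSIM_WINDOW,
) -> SSIMMap:
    """Per-voxel SSIM between two grids over a cubic uniform window.

    With local means L_a, L_b, standard deviations S_a, S_b and covariance
    S_ab computed over the window (population normalisation):

        ssim = ((2 L_a L_b + c1) (2 S_ab + c2))
               / ((L_a^2 + L_b^2 + c1) (S_a^2 + S_b^2 + c2))

    Both factors lie in [-1, 1], so the product does as well; identical
    inputs give 1 everywhere.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")

    def mean(x: np.ndarray) -> np.ndarray:
        return uniform_filter(x, size=window, mode="reflect")

    mu_a, mu_b = mean(a), mean(b)
    var_a = mean(a * a) - mu_a * mu_a
    var_b = mean(b * b) - mu_b * mu_b
    cov = mean(a * b) - mu_a * mu_b
    # rounding can push variances a hair below zero
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    values = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    )
    return SSIMMap(values=np.clip(values, -1.0, 1.0), c1=c1, c2=c2, window=window)


def _lstsq(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    beta, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < A.shape[1]:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix: rank {rank} < {A.shape[1]} "
            f"(condition number {cond:.3e})"
        )
    return beta


def fit_bias_ols(
    basis: PolynomialBasis, intensities: np.ndarray, predicted: np.ndarray
) -> np.ndarray:
    """Ordinary least-squares fit of the residual I - L onto the basis.

    Solved by QR-based least squares, never by explicit inversion of the
    normal equations.
    """
    r = np.asarray(intensities, dtype=np.float64) - np.asarray(
        predicted, dtype=np.float64
    )
    return _lstsq(basis.A, r)


def fit_bias_wls(
    basis: PolynomialBasis,
    weights: np.ndarray,
    intensities: np.ndarray,
    predicted: np.ndarray,
) -> np.ndarray:
    """Weighted least-squares fit with a per-voxel diagonal weighting.

    With all weights equal this reduces exactly to :func:`fit_bias_ols`.
    The weighted system is solved on sqrt(w)-scaled rows for conditioning.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape[0] != basis.A.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {basis.A.shape[0]} voxels")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("all-zero weights: the weighted fit is undefined")
    sw = np.sqrt(w)
    r = np.asarray(intensities, dtype=np.float64) - np.asarray(
        predicted, dtype=np.float64
    )
    return _lstsq(basis.A * sw[:, None], r * sw)


def weights_from_ssim(ssim: SSIMMap, transform: str = "neglected") -> np.ndarray:
    """Map SSIM values in [-1, 1] to least-squares weights in [0, 1].

    ``"neglected"`` (default): w = (1 - s) / 2, emphasising regions the
    current prediction explains poorly.  ``"important"``: w = (1 + s) / 2,
    emphasising regions of high similarity.  The ambiguity between the two
    readings is genuine; both are provided.
    """
    s = np.asarray(ssim.values, dtype=np.float64)
    if transform == "neglected":
        return (1.0 - s) / 2.0
    if transform == "important":
        return (1.0 + s) / 2.0
    raise ValueError(f"unknown weight transform {transform!r}")


def apply_bias_correction(
    volume: Volume, basis: PolynomialBasis, coefficients: np.ndarray
) -> BiasFit:
    """Subtract the fitted field inside the mask: I_hat = I - A @ beta."""
    beta = np.asarray(coefficients, dtype=np.float64)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite bias coefficients")
    bias = basis.A @ beta
    data = volume.data.copy()
    data[basis.mask] -= bias
    return BiasFit(
        coefficients=beta, fitted_bias=bias, filtered=volume.with_data(data)
    )


def mean_ssim_cost(ssim: SSIMMap, mask: np.ndarray) -> float:
    """Mean SSIM over mask-true voxels; higher means more similar."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: mean SSIM undefined")
    return float(ssim.values[mask].mean())
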