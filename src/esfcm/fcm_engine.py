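"""Enhanced spatial fuzzy C-means (esFCM) for 3D tissue segmentation.

The algorithm clusters masked voxel intensities into C tissue classes.  Each
iteration computes fuzzy memberships from intensity distances to the cluster
centers, refines them by a neighbourhood energy — the mean of the previous
iteration's combined memberships over the 6 face-connected neighbours — and
updates the centers with the refined memberships.  Interleaved with the
clustering, a smooth additive bias field is estimated by SSIM-weighted
quadratic least squares (see :mod:`esfcm.bias_correction`) and subtracted,
and the filtered image with the best mean-SSIM cost is kept as the output.

Disabling both the spatial energy and the bias correction reduces the
procedure exactly to plain fuzzy C-means, which is used as a degenerate
configuration in testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_multiotsu

from . import bias_correction as bc
from .volume_io import DEFAULT_LABEL_NAMES, LabelVolume, Volume

__all__ = [
    "FCMConfig",
    "FCMState",
    "SegmentationResult",
    "initialize_multiotsu",
    "compute_distances",
    "compute_membership",
    "neighborhood_energy",
    "combine_membership",
    "update_centers",
    "defuzzify",
    "run_esfcm",
]

#: Offsets of the 6 face-connected neighbours.
_FACE_NEIGHBORS = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


@dataclass
class FCMConfig:
    """Configuration of the esFCM iteration.

    Parameters
    ----------
    n_clusters:
        Number of tissue classes C (3 for CSF/GM/WM).
    fuzziness:
        Fuzziness exponent m > 1; 2.0 is the customary choice.
    max_iter:
        Iteration cap (50).
    tol:
        Convergence threshold on the maximum absolute center change, on the
        intensity scale.
    enable_spatial:
        Apply the neighbourhood-energy membership refinement (from the
        second iteration on, once a previous combined membership exists).
    enable_bias_correction:
        Interleave SSIM-weighted polynomial bias-field estimation.
    bias_update_every:
        Run the bias update on iterations t with t % bias_update_every == 0.
    ssim_window, c1, c2:
        SSIM window side and stabilising constants.
    weight_transform:
        "neglected" (w = (1-s)/2) or "important" (w = (1+s)/2).
    raw_image_in_center_update:
        If True, the center update uses the raw intensities instead of the
        current filtered ones.
    seed:
        Reserved for randomized tie-breaking; the default pipeline is fully
        deterministic.
    """

    n_clusters: int = 3
    fuzziness: float = 2.0
    max_iter: int = 50
    tol: float = 1e-4
    neighborhood_size: int = 6
    enable_spatial: bool = True
    enable_bias_correction: bool = True
    bias_update_every: int = 1
    ssim_window: int = bc.DEFAULT_SSIM_WINDOW
    c1: float = bc.DEFAULT_C1
    c2: float = bc.DEFAULT_C2
    weight_transform: str = "neglected"
    raw_image_in_center_update: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness m must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.neighborhood_size != 6:
            raise ValueError("only the 6 face-connected neighbourhood is supported")
        if self.bias_update_every < 1:
            raise ValueError("bias_update_every must be positive")


@dataclass
class FCMState:
    """State of a finished (or stepped) esFCM run over masked voxels."""

    centers: np.ndarray                 # length-C, iteration order
    membership: np.ndarray              # C x n raw memberships (Eq. of mu)
    combined_membership: np.ndarray     # C x n refined memberships
    iteration: int = 0
    converged: bool = False
    cost_history: list[float] = field(default_factory=list)
    center_history: list[np.ndarray] = field(default_factory=list)
    best_cost: float = -np.inf
    best_filtered: Volume | None = None
    bias_coefficients: np.ndarray | None = None
    #: worst per-voxel deviation of membership column sums from 1, over all
    #: iterations, for mu and the combined mu respectively
    membership_sum_error: float = 0.0
    combined_sum_error: float = 0.0


@dataclass
class SegmentationResult:
    """Final segmentation with tissue-sorted clusters.

    Clusters are sorted by ascending center intensity and mapped to labels
    1..C (for C=3 on T1: 1=CSF, 2=GM, 3=WM); background is 0.
    """

    state: FCMState
    labels: LabelVolume
    probabilities: np.ndarray           # C x H x W x D, tissue-sorted
    filtered: Volume                    # best-cost bias-corrected image
    sorted_centers: np.ndarray


def initialize_multiotsu(volume: Volume, n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Initial centers and hard labels from multi-Otsu thresholding.

    The C-1 thresholds maximising the between-class variance of the 256-bin
    masked-intensity histogram partition the voxels into C classes; the
    initial center of class i is its mean intensity.  Returns ``(centers,
    class_index)`` with ``class_index`` in 0..C-1 over masked voxels and
    centers strictly increasing.
    """
    values = volume.masked_values()
    n_distinct = np.unique(values).size
    if n_distinct < n_clusters:
        raise ValueError(
            f"only {n_distinct} distinct masked intensities; "
            f"{n_clusters} clusters need at least {n_clusters}"
        )
    thresholds = threshold_multiotsu(values, classes=n_clusters, nbins=256)
    class_index = np.digitize(values, thresholds)
    centers = np.empty(n_clusters)
    for i in range(n_clusters):
        sel = class_index == i
        if not sel.any():
            raise ValueError(f"multi-Otsu produced an empty class {i}")
        centers[i] = values[sel].mean()
    return centers, class_index


def compute_distances(intensities: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """C x n matrix of absolute intensity distances |I_j - V_i|."""
    centers = np.asarray(centers, dtype=np.float64)
    if not np.all(np.isfinite(centers)):
        raise ValueError("non-finite cluster centers")
    return np.abs(np.asarray(intensities, dtype=np.float64)[None, :] - centers[:, None])


def compute_membership(distances: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy memberships mu_ij = 1 / sum_c (D_ij / D_cj)^(2/(m-1)).

    Columns sum to 1.  A zero distance is the standard FCM singularity:
    the voxel gets indicator membership on its zero-distance cluster(s),
    split equally on ties.
    """
    D = np.asarray(distances, dtype=np.float64)
    exponent = 2.0 / (m - 1.0)
    zero = D == 0.0
    any_zero = zero.any(axis=0)
    # mu_ij = (D_ij/s_j)^-e / sum_c (D_cj/s_j)^-e with s_j the column
    # minimum: same value as the textbook form, but the largest ratio is 1,
    # so no overflow for very small distances
    scale = np.where(any_zero, 1.0, D.min(axis=0))
    with np.errstate(divide="ignore", invalid="ignore", under="ignore", over="ignore"):
        inv = (D / scale[None, :]) ** (-exponent)
        mu = inv / inv.sum(axis=0, keepdims=True)
    if any_zero.any():
        cols = np.flatnonzero(any_zero)
        z = zero[:, cols]
        mu[:, cols] = z / z.sum(axis=0, keepdims=True)
    return mu


def neighborhood_energy(prev_combined: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean of the previous combined memberships over face-connected neighbours.

    For each masked voxel j and cluster i, E_ij is the mean of the previous
    iteration's combined membership of cluster i over the up-to-6
    face-connected neighbours of j that lie inside the grid and the mask;
    unavailable neighbours are excluded and the mean is taken over the
    remaining count.  A masked voxel with no masked neighbour keeps its own
    previous membership (the mean of an empty set is replaced by identity).
    """
    mask = np.asarray(mask, dtype=bool)
    C, n = prev_combined.shape
    if int(mask.sum()) != n:
        raise ValueError(f"{n} membership columns for {int(mask.sum())} masked voxels")
    maskf = mask.astype(np.float64)
    counts = np.zeros(mask.shape)
    sums = np.zeros((C,) + mask.shape)
    grids = np.zeros((C,) + mask.shape)
    grids[:, mask] = prev_combined
    for axis_offsets in _FACE_NEIGHBORS:
        shifted_mask = _shift(maskf, axis_offsets)
        counts += shifted_mask
        for i in range(C):
            sums[i] += _shift(grids[i] * maskf, axis_offsets)
    cnt = counts[mask]
    E = np.empty((C, n))
    ok = cnt > 0
    for i in range(C):
        s = sums[i][mask]
        E[i, ok] = s[ok] / cnt[ok]
        E[i, ~ok] = prev_combined[i, ~ok]
    return E


def _shift(grid: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a grid by an offset, zero-filling; out[j] = grid[j + offset]."""
    out = np.zeros_like(grid)
    src = []
    dst = []
    for o, dim in zip(offset, grid.shape):
        if o >= 0:
            src.append(slice(o, dim))
            dst.append(slice(0, dim - o))
        else:
            src.append(slice(0, dim + o))
            dst.append(slice(-o, dim))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def combine_membership(membership: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Pointwise product of membership and energy, renormalised per voxel.

    Renormalisation keeps the unit-sum constraint on the refined
    memberships; a voxel whose products are all zero falls back to its raw
    membership.
    """
    if membership.shape != energy.shape:
        raise ValueError(
            f"shape mismatch {membership.shape} vs {energy.shape}"
        )
    prod = membership * energy
    totals = prod.sum(axis=0, keepdims=True)
    dead = totals[0] == 0.0
    combined = np.where(dead[None, :], membership, prod / np.where(totals == 0, 1.0, totals))
    return combined


def update_centers(
    membership: np.ndarray, intensities: np.ndarray, m: float
) -> np.ndarray:
    """Weighted-mean center update V_i = sum_j mu_ij^m I_j / sum_j mu_ij^m."""
    w = np.asarray(membership, dtype=np.float64) ** m
    totals = w.sum(axis=1)
    empty = np.flatnonzero(totals == 0.0)
    if empty.size:
        raise ValueError(
            f"cluster {empty[0]} has zero total membership weight; "
            "the clustering is degenerate"
        )
    return (w @ np.asarray(intensities, dtype=np.float64)) / totals


def defuzzify(
    combined: np.ndarray,
    mask: np.ndarray,
    label_names=None,
) -> LabelVolume:
    """Hard labels by per-voxel argmax: cluster i -> label i+1, background 0.

    Ties resolve to the lowest cluster index.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = np.argmax(combined, axis=0) + 1
    names = dict(label_names) if label_names is not None else dict(DEFAULT_LABEL_NAMES)
    return LabelVolume(labels=labels, label_names=names)


def _one_hot(class_index: np.ndarray, n_clusters: int) -> np.ndarray:
    out = np.zeros((n_clusters, class_index.size))
    out[class_index, np.arange(class_index.size)] = 1.0
    return out


def run_esfcm(volume: Volume, config: FCMConfig | None = None) -> SegmentationResult:
    """Run the full esFCM loop on a masked volume.

    Per iteration t = 1..max_iter, with filtered image I_hat (initially the
    raw image): distances from I_hat to the centers; raw memberships; from
    t >= 2, the neighbourhood energy of the previous combined membership and
    the renormalised pointwise product; center update from the combined
    memberships; then, if enabled, the bias update — FCM prediction L,
    SSIM map between the gradient magnitudes of the raw image and of L,
    SSIM-derived weights, weighted quadratic fit of I - L, subtraction from
    the raw image, and bookkeeping of the mean-SSIM cost.  The filtered
    image with the best cost so far is both the working image of subsequent
    iterations and the returned output.  Stops when the maximum center
    change drops below ``tol``; hitting ``max_iter`` is flagged, not an
    error.

    The returned labels sort clusters by ascending center intensity
    (CSF < GM < WM on T1) regardless of initialisation order.
    """
    if config is None:
        config = FCMConfig()
    mask = volume.mask
    raw = volume.masked_values()
    centers, init_class = initialize_multiotsu(volume, config.n_clusters)
    combined = _one_hot(init_class, config.n_clusters)
    membership = combined

    filtered_vol = volume.with_data(volume.data.copy())
    filtered = raw.copy()
    basis = None
    raw_grad = None
    if config.enable_bias_correction:
        basis = bc.build_basis(volume.shape, mask)
        raw_grad = bc.gradient_volume(volume)

    state = FCMState(centers=centers, membership=membership, combined_membership=combined)
    state.best_filtered = filtered_vol

    for t in range(1, config.max_iter + 1):
        D = compute_distances(filtered, centers)
        membership = compute_membership(D, config.fuzziness)
        state.membership_sum_error = max(
            state.membership_sum_error,
            float(np.abs(membership.sum(axis=0) - 1.0).max()),
        )
        if config.enable_spatial and t >= 2:
            energy = neighborhood_energy(combined, mask)
            combined = combine_membership(membership, energy)
        else:
            combined = membership
        state.combined_sum_error = max(
            state.combined_sum_error,
            float(np.abs(combined.sum(axis=0) - 1.0).max()),
        )
        update_values = raw if config.raw_image_in_center_update else filtered
        new_centers = update_centers(combined, update_values, config.fuzziness)

        if config.enable_bias_correction and t % config.bias_update_every == 0:
            predicted = bc.predict_image(new_centers, combined)
            pred_vol = volume.with_data(_scatter(predicted, mask))
            pred_grad = bc.gradient_volume(pred_vol)
            smap = bc.ssim_map(
                raw_grad, pred_grad, c1=config.c1, c2=config.c2,
                window=config.ssim_window,
            )
            weights = bc.weights_from_ssim(smap, transform=config.weight_transform)[mask]
            if weights.max() <= 1e-8:
                # SSIM within float rounding of 1 everywhere (the prediction
                # explains the image exactly): fall back to the unweighted fit
                weights = np.ones_like(weights)
            beta = bc.fit_bias_wls(basis, weights, raw, predicted)
            fit = bc.apply_bias_correction(volume, basis, beta)
            cost = bc.mean_ssim_cost(smap, mask)
            state.cost_history.append(cost)
            if cost > state.best_cost:
                state.best_cost = cost
                state.best_filtered = fit.filtered
                state.bias_coefficients = beta
            # the best-cost filtered image is the loop state: a fit whose
            # prediction explains the image worse than an earlier one is
            # recorded but not fed back, which keeps a poor fit from
            # eroding tissue contrast in later iterations
            filtered_vol = state.best_filtered
            filtered = filtered_vol.masked_values()

        delta = float(np.abs(new_centers - centers).max())
        centers = new_centers
        state.center_history.append(centers.copy())
        state.iteration = t
        if delta < config.tol:
            state.converged = True
            break

    state.centers = centers
    state.membership = membership
    state.combined_membership = combined

    order = np.argsort(centers)
    sorted_centers = centers[order]
    sorted_combined = combined[order]
    labels = defuzzify(sorted_combined, mask)
    probs = np.zeros((config.n_clusters,) + volume.shape)
    probs[:, mask] = sorted_combined
    final_filtered = (
        state.best_filtered if config.enable_bias_correction else filtered_vol
    )
    return SegmentationResult(
        state=state,
        labels=labels,
        probabilities=probs,
        filtered=final_filtered,
        sorted_centers=sorted_centers,
    )


def _scatter(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    grid = np.zeros(mask.shape)
    grid[mask] = values
    return grid
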