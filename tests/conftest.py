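"""Shared fixtures and independent reference implementations.

The reference functions here are deliberately written as plain loops (or
direct formula transcriptions) so they stay independent of the vectorised
library code they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from esfcm import FCMConfig, PhantomSpec, Volume, generate_phantom
from esfcm.fcm_engine import initialize_multiotsu


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless, bias-free 32-cubed phantom; fast enough for unit tests."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32)))


@pytest.fixture
def random_volume(rng):
    data = rng.uniform(0, 100, size=(6, 6, 6))
    return Volume(data=data, spacing=(1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# reference implementations (oracles)
# ---------------------------------------------------------------------------

def plain_fcm_reference(volume, n_clusters=3, m=2.0, max_iter=50, tol=1e-4):
    """Straightforward fuzzy C-means from multi-Otsu initialisation.

    Returns the label grid (clusters sorted by ascending center, labels
    1..C inside the mask, 0 outside) for comparison with the degenerate
    esFCM configuration.
    """
    values = volume.masked_values()
    centers, _ = initialize_multiotsu(volume, n_clusters)
    centers = centers.copy()
    mu = None
    for _ in range(max_iter):
        d = np.abs(values[None, :] - centers[:, None])
        mu = np.zeros_like(d)
        for j in range(d.shape[1]):
            col = d[:, j]
            if np.any(col == 0):
                z = col == 0
                mu[:, j] = z / z.sum()
            else:
                for i in range(n_clusters):
                    mu[i, j] = 1.0 / np.sum((col[i] / col) ** (2.0 / (m - 1.0)))
        w = mu ** m
        new_centers = (w @ values) / w.sum(axis=1)
        delta = np.abs(new_centers - centers).max()
        centers = new_centers
        if delta < tol:
            break
    order = np.argsort(centers)
    labels = np.zeros(volume.shape, dtype=np.int32)
    labels[volume.mask] = np.argmax(mu[order], axis=0) + 1
    return labels


def brute_force_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)):
    """Exact Hausdorff distance by a double loop over all point pairs."""
    sp = np.asarray(spacing, dtype=float)
    pa = np.argwhere(a) * sp
    pb = np.argwhere(b) * sp
    d_ab = max(min(np.sqrt(((p - q) ** 2).sum()) for q in pb) for p in pa)
    d_ba = max(min(np.sqrt(((q - p) ** 2).sum()) for p in pa) for q in pb)
    return max(d_ab, d_ba)


def brute_force_dice(a, b):
    tp = int(np.sum(a & b))
    return 1.0 if (a.sum() + b.sum()) == 0 else 2 * tp / (int(a.sum()) + int(b.sum()))


def brute_force_accuracy(a, b):
    return float(np.sum(a == b)) / a.size


def brute_force_neighborhood_energy(prev, mask):
    """Mean of cluster memberships over in-grid, in-mask face neighbours."""
    C = prev.shape[0]
    shape = mask.shape
    grids = np.zeros((C,) + shape)
    grids[:, mask] = prev
    coords = np.argwhere(mask)
    E = np.zeros((C, len(coords)))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for jj, (x, y, z) in enumerate(coords):
        for i in range(C):
            vals = []
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    if mask[nx, ny, nz]:
                        vals.append(grids[i, nx, ny, nz])
            E[i, jj] = np.mean(vals) if vals else prev[i, jj]
    return E


def multiotsu_exhaustive(values, n_classes=3, nbins=256):
    """Thresholds maximising between-class variance by exhaustive search
    over all threshold pairs of the histogram bin edges."""
    hist, edges = np.histogram(values, bins=nbins)
    mids = (edges[:-1] + edges[1:]) / 2
    best, best_thr = -np.inf, None
    for i in range(1, nbins - 1):
        for j in range(i + 1, nbins):
            var = 0.0
            for lo, hi in ((0, i), (i, j), (j, nbins)):
                w = hist[lo:hi].sum()
                if w == 0:
                    continue
                mean = (hist[lo:hi] * mids[lo:hi]).sum() / w
                var += w * mean * mean
            if var > best:
                best, best_thr = var, (edges[i], edges[j])
    return best_thr
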