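"""Synthetic 3-tissue brain phantom generator.

The phantom is a set of nested ellipsoids on a cubic grid: an outer shell of
CSF, a middle shell of GM, and a WM core, with piecewise-constant class
intensities on a T1-like scale (CSF darkest, WM brightest).  Degradations
mirror the augmentation protocol used to stress-test the segmentation:
additive Gaussian noise at a percentage of the brightest class mean, and a
smooth additive quadratic bias field scaled so its peak magnitude is a
percentage of the brightest class mean.  Both conventions follow the
percent-of-brightest-tissue convention familiar from simulated brain
databases, and are recorded in the spec so planted-parameter recovery tests
can check the bias fit exactly.

Everything is deterministic given the seed; labels are untouched by noise
and bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bias_correction as bc
from .volume_io import DEFAULT_LABEL_NAMES, LabelVolume, Volume

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "add_noise", "add_bias"]


@dataclass
class PhantomSpec:
    """Geometry, intensities and degradations of a synthetic phantom.

    ``semi_axes`` are per-ellipsoid voxel semi-axis lengths (outer = CSF
    boundary = brain mask, middle = GM boundary, inner = WM core); defaults
    scale with the grid so the brain fills most of the field of view.
    ``noise_pct`` and ``bias_pct`` are percentages of the maximum class
    mean (the WM intensity by default).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    semi_axes: tuple[tuple[float, float, float], ...] | None = None
    class_means: tuple[float, float, float] = (50.0, 120.0, 200.0)  # CSF, GM, WM
    noise_pct: float = 0.0
    bias_pct: float = 0.0
    bias_coefficients: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_before_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"phantom grid must be 3D with dims >= 8, got {self.shape}")
        if self.semi_axes is None:
            # outer / middle / inner fractions of the half-extent
            fracs = (0.88, 0.72, 0.50)
            half = [(d - 1) / 2.0 for d in self.shape]
            self.semi_axes = tuple(
                tuple(f * h for h in half) for f in fracs
            )
        self.semi_axes = tuple(tuple(float(a) for a in ax) for ax in self.semi_axes)
        if len(self.semi_axes) != 3:
            raise ValueError("three nested ellipsoids are required (CSF, GM, WM)")
        for outer, inner in zip(self.semi_axes, self.semi_axes[1:]):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError("ellipsoid semi-axes must be strictly nested")
        for ax, half_extent in zip(self.semi_axes[0], ((d - 1) / 2.0 for d in self.shape)):
            if ax > half_extent:
                raise ValueError(
                    f"outer ellipsoid semi-axis {ax} exceeds grid half-extent {half_extent}"
                )
        means = tuple(float(v) for v in self.class_means)
        if not (means[0] < means[1] < means[2]):
            raise ValueError(f"class means must increase CSF < GM < WM, got {means}")
        self.class_means = means
        if self.noise_pct < 0 or self.bias_pct < 0:
            raise ValueError("noise_pct and bias_pct must be nonnegative")

    @property
    def reference_intensity(self) -> float:
        """Intensity that noise/bias percentages refer to: the max class mean."""
        return max(self.class_means)


@dataclass
class Phantom:
    """A generated phantom: degraded image, truth labels, clean image, bias."""

    image: Volume
    labels: LabelVolume
    clean: Volume
    bias_coefficients: np.ndarray
    spec: PhantomSpec
    noise_sd: float = 0.0


def _ellipsoid_mask(shape, semi_axes) -> np.ndarray:
    center = [(d - 1) / 2.0 for d in shape]
    grids = np.meshgrid(*[np.arange(d, dtype=np.float64) for d in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the phantom described by ``spec``.

    Labels come from the nested-ellipsoid membership; the clean image is the
    per-class mean intensity; the degraded image adds the scaled bias field
    and the Gaussian noise (bias first by default, order configurable).
    """
    if spec is None:
        spec = PhantomSpec()
    outer = _ellipsoid_mask(spec.shape, spec.semi_axes[0])
    middle = _ellipsoid_mask(spec.shape, spec.semi_axes[1])
    inner = _ellipsoid_mask(spec.shape, spec.semi_axes[2])
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[outer] = 1           # CSF shell
    labels[middle] = 2          # GM shell
    labels[inner] = 3           # WM core

    clean_data = np.zeros(spec.shape)
    for lab, mean in zip((1, 2, 3), spec.class_means):
        clean_data[labels == lab] = mean
    clean = Volume(data=clean_data, spacing=spec.spacing, mask=outer)

    rng = np.random.default_rng(spec.seed)
    image = clean.with_data(clean.data.copy())
    beta = np.zeros(10)
    noise_sd = spec.noise_pct / 100.0 * spec.reference_intensity
    steps = ("noise", "bias") if spec.noise_before_bias else ("bias", "noise")
    for step in steps:
        if step == "bias":
            image, beta = add_bias(
                image,
                spec.bias_pct,
                seed=int(rng.integers(0, 2**31 - 1)),
                reference=spec.reference_intensity,
                coefficients=spec.bias_coefficients,
            )
        else:
            image = add_noise(
                image,
                spec.noise_pct,
                seed=int(rng.integers(0, 2**31 - 1)),
                reference=spec.reference_intensity,
            )
    return Phantom(
        image=image,
        labels=LabelVolume(labels=labels, label_names=dict(DEFAULT_LABEL_NAMES)),
        clean=clean,
        bias_coefficients=beta,
        spec=spec,
        noise_sd=noise_sd,
    )


def add_noise(
    volume: Volume, noise_pct: float, seed: int = 0, reference: float | None = None
) -> Volume:
    """Add zero-mean Gaussian noise with sd = noise_pct/100 * reference.

    Only mask-true voxels are perturbed.  ``reference`` defaults to the
    maximum masked intensity of the input volume.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be nonnegative")
    if noise_pct == 0:
        return volume.with_data(volume.data.copy())
    if reference is None:
        reference = float(volume.masked_values().max())
    sd = noise_pct / 100.0 * reference
    rng = np.random.default_rng(seed)
    data = volume.data.copy()
    data[volume.mask] += rng.normal(0.0, sd, size=volume.n_masked)
    return volume.with_data(data)


def add_bias(
    volume: Volume,
    bias_pct: float,
    seed: int = 0,
    reference: float | None = None,
    coefficients: np.ndarray | None = None,
) -> tuple[Volume, np.ndarray]:
    """Add a quadratic polynomial bias field inside the mask.

    The 10 coefficients are drawn standard-normal from the seed (unless
    given explicitly) and rescaled so max |A @ beta| over the mask equals
    bias_pct/100 * reference.  Returns the degraded volume and the planted
    coefficient vector, enabling exact recovery tests.
    """
    if bias_pct < 0:
        raise ValueError("bias_pct must be nonnegative")
    if bias_pct == 0:
        return volume.with_data(volume.data.copy()), np.zeros(10)
    if reference is None:
        reference = float(volume.masked_values().max())
    basis = bc.build_basis(volume.shape, volume.mask)
    if coefficients is None:
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(10)
    else:
        raw = np.asarray(coefficients, dtype=np.float64)
        if raw.shape != (10,):
            raise ValueError("bias coefficients must be a length-10 vector")
    field_raw = basis.A @ raw
    peak = np.abs(field_raw).max()
    if peak == 0:
        return volume.with_data(volume.data.copy()), np.zeros(10)
    beta = raw * (bias_pct / 100.0 * reference / peak)
    data = volume.data.copy()
    data[volume.mask] += basis.A @ beta
    return volume.with_data(data), beta
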