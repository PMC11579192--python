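"""NIfTI volume and label-map I/O with brain-mask handling.

All downstream computation (clustering, bias fitting, SSIM, metrics) is
restricted to mask-true voxels; background voxels receive label 0 and
membership 0.  Intensities are handled in double precision internally
regardless of the on-disk dtype, because the weighted least-squares normal
equations used for bias correction are ill-conditioned in single precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "DEFAULT_LABEL_NAMES",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

#: Canonical tissue labelling for three-class T1 segmentation.
DEFAULT_LABEL_NAMES: dict[int, str] = {0: "background", 1: "CSF", 2: "GM", 3: "WM"}


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel spacing and a brain mask.

    Parameters
    ----------
    data:
        H x W x D float array of intensities.
    spacing:
        Per-axis voxel size in millimetres; strictly positive.
    mask:
        Boolean array of the same shape; True marks brain voxels.  If not
        given, an all-true mask is used.
    affine:
        4x4 voxel-to-world matrix, carried opaquely for round-tripping.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite intensities inside the brain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Intensities of mask-true voxels, flattened in C order."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "Volume":
        """A copy of this volume carrying new intensities, same geometry."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class LabelVolume:
    """Integer label map aligned with a :class:`Volume`."""

    labels: np.ndarray
    label_names: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_NAMES)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"label volume must be 3D, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        present = set(np.unique(self.labels).tolist())
        declared = set(int(k) for k in self.label_names)
        undeclared = present - declared
        if undeclared:
            raise ValueError(
                f"undeclared label values {sorted(undeclared)}; "
                f"declared labels are {sorted(declared)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _load_3d(path: Path) -> nib.Nifti1Image:
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D scalar image, got shape {tuple(img.shape)}"
        )
    return img


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> Volume:
    """Read a 3D NIfTI volume, optionally with a separate binary brain mask.

    Spacing is taken from the header zooms and the affine is preserved so
    that :func:`write_volume` round-trips orientation metadata.
    """
    path = Path(path)
    img = _load_3d(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mimg = _load_3d(Path(mask_path))
        if tuple(mimg.shape) != tuple(img.shape):
            raise ValueError(
                f"mask shape {tuple(mimg.shape)} does not match "
                f"volume shape {tuple(img.shape)}"
            )
        mask = np.asarray(mimg.dataobj) > 0
    return Volume(data=data, spacing=spacing, mask=mask, affine=img.affine)


def write_volume(volume: Volume, path: str | Path, dtype=np.float64) -> None:
    """Write a volume as NIfTI; data and spacing round-trip through read_volume."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data.astype(dtype), affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_labels(
    path: str | Path, label_names: Mapping[int, str] | None = None
) -> LabelVolume:
    """Read an integer label map; float-stored integers are accepted to 1e-6."""
    path = Path(path)
    img = _load_3d(path)
    raw = np.asarray(img.dataobj, dtype=np.float64)
    rounded = np.rint(raw)
    if np.max(np.abs(raw - rounded)) > 1e-6:
        raise ValueError(f"{path}: voxel values are not integers (tolerance 1e-6)")
    labels = rounded.astype(np.int32)
    names = dict(label_names) if label_names is not None else dict(DEFAULT_LABEL_NAMES)
    return LabelVolume(labels=labels, label_names=names)


def write_labels(labels: LabelVolume, path: str | Path, affine=None,
                 spacing: tuple[float, float, float] | None = None) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    img = nib.Nifti1Image(
        labels.labels.astype(np.int16),
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=np.float64),
    )
    if spacing is not None:
        img.header.set_zooms(spacing)
    nib.save(img, str(path))
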