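"""Volumetric image and label-map I/O.

NIfTI-1 is the canonical on-disk format.  A :class:`Volume` couples a 3D
intensity array with a voxel-to-world affine and a boolean brain mask; a
:class:`LabelMap` holds integer tissue labels on the same grid.

Coordinate convention: 0-based ``(x, y, z)`` indices with the linear index
running x-fastest (Fortran order).  The affine is carried through the
pipeline but never enters any computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Integer coding for the three tissue classes (0 is background).
CSF, GM, WM = 1, 2, 3
TISSUE_NAMES = {CSF: "csf", GM: "gm", WM: "wm"}
VALID_LABELS = frozenset({0, CSF, GM, WM})


@dataclass
class Volume:
    """A 3D intensity image with affine and brain mask.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel intensities on an arbitrary integer or float scale.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    mask : ndarray of bool, shape (X, Y, Z)
        True for brain voxels.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D image, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is None:
            self.mask = self.data > 0
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.data.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Intensities of masked voxels, ordered by linear index."""
        return self.data.ravel(order="F")[linear_indices(self.mask)]


@dataclass
class LabelMap:
    """Integer tissue labels on a volume grid (0=background, 1=CSF, 2=GM, 3=WM)."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label map, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int16)
        extra = set(np.unique(self.labels)) - VALID_LABELS
        if extra:
            raise ValueError(f"invalid label values {sorted(extra)}; allowed: 0..3")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> Volume:
    """Load a 3D NIfTI image, optionally with an explicit brain mask.

    Without ``mask_path`` the mask defaults to strict intensity positivity
    (skull-stripped volumes have zero background).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise FileNotFoundError(mask_path)
        mimg = nib.load(str(mask_path))
        mask = np.asanyarray(mimg.dataobj)
        if mask.shape != data.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {data.shape}"
            )
        mask = mask > 0
    return Volume(data=data, affine=img.affine, mask=mask)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume`'s intensities to a NIfTI file."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    """Load an integer label map from a NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label map, got ndim={labels.ndim}")
    return LabelMap(labels=np.rint(labels).astype(np.int16), affine=img.affine)


def write_labelmap(seg: LabelMap, path: str | Path) -> None:
    """Write a :class:`LabelMap` to a NIfTI file (int16, lossless)."""
    img = nib.Nifti1Image(seg.labels.astype(np.int16), seg.affine)
    nib.save(img, str(path))


def linear_indices(mask: np.ndarray) -> np.ndarray:
    """Linear (x-fastest) indices of True voxels, in increasing order."""
    return np.flatnonzero(np.asarray(mask, dtype=bool).ravel(order="F"))


def coords_from_linear(
    idx: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map linear (x-fastest) indices back to ``(x, y, z)`` coordinate arrays."""
    return np.unravel_index(np.asarray(idx), shape, order="F")


def linear_from_coords(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray], shape: tuple[int, int, int]
) -> np.ndarray:
    """Map ``(x, y, z)`` coordinate arrays to linear (x-fastest) indices."""
    return np.ravel_multi_index(coords, shape, order="F")
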