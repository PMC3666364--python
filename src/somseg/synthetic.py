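"""Synthetic three-tissue phantoms and feature-space toys with ground truth.

The phantom emulates a skull-stripped T1 volume: a WM ellipsoidal core, a
GM shell and an outer CSF shell with strictly increasing mean intensities,
optional per-tissue spatially correlated noise (distinct local texture),
and an optional smooth multiplicative bias field.  Everything is
deterministic per seed, so tests and acceptance runs need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .features import FeatureMatrix
from .io_volume import CSF, GM, WM, LabelMap, Volume

#: Ellipsoid semi-axis fractions (of the half-extent) for WM, GM, CSF shells.
#: Shell thicknesses keep the boundary-window fraction of each tissue low
#: enough that window statistics stay tissue-dominated.
_RADII = (0.50, 0.78, 0.96)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom generator."""

    shape: tuple[int, int, int] = (64, 64, 64)
    tissue_means: tuple[float, float, float] = (30.0, 100.0, 180.0)  # CSF, GM, WM
    noise_sigma: float = 10.0
    bias_amplitude: float = 0.0
    geometry: str = "nested_ellipsoids"
    texture_sigma: tuple[float, float, float] = (0.0, 0.7, 1.4)  # per tissue
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom shape components must be >= 16")
        a, b, c = self.tissue_means
        if not (a < b < c):
            raise ValueError("tissue_means must be strictly increasing (CSF < GM < WM)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.geometry not in ("nested_ellipsoids", "blobs"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _normalized_radius(shape: tuple[int, int, int]) -> np.ndarray:
    """Distance from volume centre, scaled so the half-extent is 1 per axis."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) / ((n - 1) / 2.0)
        for n in shape
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(gx**2 + gy**2 + gz**2)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed Gaussian field rescaled to zero mean and max |.| of 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    f -= f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _labels_nested(shape: tuple[int, int, int]) -> np.ndarray:
    rho = _normalized_radius(shape)
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho < _RADII[2]] = CSF
    labels[rho < _RADII[1]] = GM
    labels[rho < _RADII[0]] = WM
    return labels


def _labels_blobs(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    rho = _normalized_radius(shape)
    brain = rho < _RADII[2]
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 10)
    vals = field[brain]
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    labels = np.zeros(shape, dtype=np.int16)
    labels[brain] = CSF
    labels[brain & (field >= q1)] = GM
    labels[brain & (field >= q2)] = WM
    return labels


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[Volume, LabelMap]:
    """Generate a phantom volume and its ground-truth label map.

    Intensity model: tissue mean x (1 + bias field) + spatially smoothed
    Gaussian noise of standard deviation ``noise_sigma`` whose correlation
    length differs per tissue (``texture_sigma``).  With zero noise and
    bias each tissue region is exactly constant at its mean.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "nested_ellipsoids":
        labels = _labels_nested(spec.shape)
    else:
        labels = _labels_blobs(spec.shape, rng)
    mask = labels > 0

    means = np.array([0.0, *spec.tissue_means])
    data = means[labels].astype(np.float64)

    if spec.bias_amplitude > 0:
        bias = _smooth_unit_field(rng, spec.shape, sigma=min(spec.shape) / 4)
        data *= 1.0 + spec.bias_amplitude * bias

    if spec.noise_sigma > 0:
        for tissue, tsig in zip((CSF, GM, WM), spec.texture_sigma):
            field = rng.standard_normal(spec.shape)
            if tsig > 0:
                field = ndimage.gaussian_filter(field, sigma=tsig)
                field /= field.std()  # restore unit variance after smoothing
            sel = labels == tissue
            data[sel] += spec.noise_sigma * field[sel]

    data[~mask] = 0.0
    affine = np.eye(4)
    return (
        Volume(data=data, affine=affine, mask=mask),
        LabelMap(labels=labels, affine=affine),
    )


def make_feature_toy(
    n_per_cluster: int,
    separation: float,
    noise_dims: int = 0,
    seed: int = 0,
    sigma: float = 1.0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Three Gaussian clusters in 3 informative dims plus pure-noise columns.

    Cluster centres sit at ``separation / sqrt(2)`` along each coordinate
    axis of the informative subspace (mutual distance = ``separation``, and
    every informative dimension carries signal); all columns have noise
    standard deviation ``sigma``.  Returns the matrix and the true cluster
    label (0/1/2) per row.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if noise_dims < 0:
        raise ValueError("noise_dims must be >= 0")
    rng = np.random.default_rng(seed)
    centers = (separation / np.sqrt(2.0)) * np.eye(3)
    rows = []
    labels = []
    for c in range(3):
        rows.append(centers[c] + sigma * rng.standard_normal((n_per_cluster, 3)))
        labels.extend([c] * n_per_cluster)
    X = np.vstack(rows)
    if noise_dims > 0:
        X = np.hstack([X, sigma * rng.standard_normal((X.shape[0], noise_dims))])
    names = tuple(f"informative_{i}" for i in range(3)) + tuple(
        f"noise_{i}" for i in range(noise_dims)
    )
    fm = FeatureMatrix(
        values=X,
        feature_names=names,
        voxel_index=np.arange(X.shape[0]),
        grid_shape=None,
    )
    return fm, np.array(labels)
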