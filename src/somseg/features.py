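"""Per-voxel 23-dimensional statistical descriptors for 3D volumes.

Each masked voxel is described by the concatenation of four feature groups
computed over a sliding w³ cube centred on it:

* 12 Haralick texture statistics averaged over the 13 independent 3D
  co-occurrence directions (direction averaging gives rotation invariance);
* 3 first-order features (central intensity, window mean, window variance);
* 7 normalized local-histogram features;
* 1 global feature: the relative frequency of the voxel's quantized
  intensity over the whole masked volume.

GLCM accumulation is vectorized: for every direction the per-window
co-occurrence histogram is assembled from shifted pair-code volumes, which
is exactly equivalent to looping over windows (an equivalence covered by
tests) but orders of magnitude faster.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import xlogy

from .io_volume import Volume, linear_indices

logger = logging.getLogger(__name__)

HARALICK_NAMES = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "homogeneity",
    "variance",
    "sum_average",
    "dissimilarity",
    "cluster_shade",
    "cluster_tendency",
    "maximum_probability",
    "difference_variance",
)
FIRST_ORDER_NAMES = ("central_intensity", "window_mean", "window_variance")
LOCAL_HIST_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_energy",
    "hist_entropy",
    "hist_skewness",
    "hist_kurtosis",
    "hist_mode",
)
GLOBAL_NAMES = ("global_intensity_probability",)

#: Canonical feature order; full extraction yields exactly these 23 columns.
FEATURE_NAMES: tuple[str, ...] = (
    HARALICK_NAMES + FIRST_ORDER_NAMES + LOCAL_HIST_NAMES + GLOBAL_NAMES
)

#: Extra GLCM statistic selectable by name but not part of the canonical 23:
#: sum over off-diagonal cells of p(i,j) / (1 + (i-j)^2).
INVERSE_VARIANCE = "inverse_variance"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window configuration for feature extraction.

    ``border_policy`` is either ``"pad_reflect"`` (reflect-pad so every
    masked voxel gets a descriptor) or ``"skip"`` (drop voxels whose full
    window is not contained in the brain mask).
    """

    size: int = 3
    quantization_levels: int = 16
    border_policy: str = "pad_reflect"

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        if self.quantization_levels < 2:
            raise ValueError("quantization_levels must be >= 2")
        if self.border_policy not in ("pad_reflect", "skip"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


@dataclass
class GLCM:
    """A symmetric gray-level co-occurrence matrix for one direction."""

    counts: np.ndarray
    direction: tuple[int, int, int]
    distance: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("GLCM counts must be square")
        if (self.counts < 0).any():
            raise ValueError("GLCM counts must be nonnegative")

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    def normalized(self) -> np.ndarray:
        """Probability matrix (sums to 1; all-zero counts stay all-zero)."""
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()


@dataclass
class FeatureMatrix:
    """Voxels-by-features matrix with named columns and voxel bookkeeping.

    ``voxel_index`` holds the x-fastest linear index of each row's voxel in
    the originating grid (``grid_shape``); for non-volumetric matrices
    (e.g. synthetic toys) ``grid_shape`` may be None.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = tuple(self.feature_names)
        self.voxel_index = np.asarray(self.voxel_index)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match number of columns")
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("voxel_index length must match number of rows")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: list[str] | tuple[str, ...]) -> "FeatureMatrix":
        """Column subset by name, keeping this matrix's column order."""
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise KeyError(f"unknown feature name(s): {unknown}")
        keep = [i for i, n in enumerate(self.feature_names) if n in set(names)]
        return FeatureMatrix(
            values=self.values[:, keep],
            feature_names=tuple(self.feature_names[i] for i in keep),
            voxel_index=self.voxel_index,
            grid_shape=self.grid_shape,
            affine=self.affine,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Cache as a tab-separated table (one row per voxel)."""
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "voxel_index", self.voxel_index)
        header = ""
        if self.grid_shape is not None:
            header = "# grid_shape=%d,%d,%d\n" % tuple(self.grid_shape)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            first = fh.readline()
            grid_shape = None
            if first.startswith("# grid_shape="):
                grid_shape = tuple(
                    int(v) for v in first.split("=", 1)[1].strip().split(",")
                )
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t")
        return cls(
            values=df.drop(columns="voxel_index").to_numpy(float),
            feature_names=tuple(c for c in df.columns if c != "voxel_index"),
            voxel_index=df["voxel_index"].to_numpy(np.int64),
            grid_shape=grid_shape,
        )


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize(vol: Volume, levels: int) -> Volume:
    """Equal-width requantization of masked intensities to [0, levels-1].

    The bin edges span the masked min-max range; the mapping is monotone
    non-decreasing and the masked maximum maps to ``levels - 1``.  A
    constant image maps everywhere to level 0 (warning logged).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if vol.n_masked == 0:
        raise ValueError("cannot quantize a volume with an empty mask")
    data = np.asarray(vol.data, dtype=np.float64)
    masked = data[vol.mask]
    lo, hi = float(masked.min()), float(masked.max())
    if hi == lo:
        logger.warning("constant image: all voxels quantized to level 0")
        q = np.zeros(vol.shape, dtype=np.int64)
    else:
        q = np.floor((data - lo) / (hi - lo) * levels).astype(np.int64)
        np.clip(q, 0, levels - 1, out=q)
    return Volume(data=q, affine=vol.affine, mask=vol.mask)


# ---------------------------------------------------------------------------
# GLCM geometry and accumulation
# ---------------------------------------------------------------------------

# The 13 independent co-occurrence directions for unit distance: one
# representative per antipodal pair {d, -d} of the 26 nonzero offsets with
# components in {-1, 0, 1}.
_UNIT_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (0, 1, 0),
    (-1, 1, 0),
    (-1, 0, 0),
    (-1, -1, 0),
    (0, 1, -1),
    (0, 0, 1),
    (0, -1, -1),
    (-1, 0, -1),
    (1, 0, -1),
    (-1, 1, -1),
    (1, -1, -1),
    (-1, -1, -1),
    (1, 1, -1),
)


def glcm_offsets(distance: int = 1) -> list[tuple[int, int, int]]:
    """The 13 independent 3D co-occurrence offsets at the given distance.

    Of the 27 offsets with components in {-distance, 0, distance}, the zero
    offset is dropped and each antipodal pair {d, -d} is represented once
    (the symmetric GLCM makes d and -d redundant).
    """
    if distance < 1:
        raise ValueError("distance must be a positive integer")
    return [(dx * distance, dy * distance, dz * distance) for dx, dy, dz in _UNIT_OFFSETS]


def compute_glcm(
    window: np.ndarray,
    offset: tuple[int, int, int],
    levels: int,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence counts of an integer-valued window for one offset.

    ``counts[i, j]`` is the number of voxel pairs ``(p, p + offset)`` with
    values ``(i, j)`` and both endpoints inside the window; with
    ``symmetric=True`` the transpose is added so the matrix also covers the
    ``-offset`` direction.  An offset exceeding the window extent yields a
    zero matrix.
    """
    window = np.asarray(window)
    if window.ndim != 3:
        raise ValueError("window must be 3D")
    if window.min(initial=0) < 0 or window.max(initial=0) >= levels:
        raise ValueError(f"window values must lie in [0, {levels - 1}]")
    src_sl, dst_sl = [], []
    for size, d in zip(window.shape, offset):
        if abs(d) >= size:
            counts = np.zeros((levels, levels), dtype=np.float64)
            return GLCM(counts=counts, direction=tuple(offset))
        src_sl.append(slice(max(0, -d), size - max(0, d)))
        dst_sl.append(slice(max(0, d), size - max(0, -d)))
    src = window[tuple(src_sl)].ravel()
    dst = window[tuple(dst_sl)].ravel()
    counts = np.bincount(src * levels + dst, minlength=levels * levels).reshape(
        levels, levels
    ).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts=counts, direction=tuple(offset))


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------


def _haralick_batch(P: np.ndarray, levels: int) -> np.ndarray:
    """Vectorized Haralick statistics for a batch of probability matrices.

    Parameters
    ----------
    P : ndarray, shape (V, levels*levels)
        Row-flattened probability matrices (each row sums to 1 or to 0 for
        an empty GLCM, which yields an all-zero feature row).

    Returns
    -------
    ndarray, shape (V, 12) in :data:`HARALICK_NAMES` order.

    Notes
    -----
    Gray levels are 0-based.  ``variance`` is the marginal variance
    sum_i (i - mu_x)^2 p_x(i); ``cluster_shade`` and ``cluster_tendency``
    are the 3rd- and 2nd-power cluster moments of s = i + j about
    mu_x + mu_y; ``difference_variance`` is the variance of the |i - j|
    distribution.  Correlation of a zero-variance matrix is defined as 0.
    """
    V = P.shape[0]
    L = levels
    lv = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    iv, jv = ii.ravel(), jj.ravel()
    diff = iv - jv
    s = iv + jv

    Pm = P.reshape(V, L, L)
    px = Pm.sum(axis=2)  # (V, L)
    py = Pm.sum(axis=1)

    mu_x = px @ lv
    mu_y = py @ lv
    var_x = px @ (lv**2) - mu_x**2
    var_y = py @ (lv**2) - mu_y**2

    energy = np.einsum("vk,vk->v", P, P)
    entropy = -xlogy(P, P).sum(axis=1) / np.log(2.0)
    contrast = P @ (diff**2)
    homogeneity = P @ (1.0 / (1.0 + diff**2))
    dissimilarity = P @ np.abs(diff)
    max_prob = P.max(axis=1)

    cov = P @ (iv * jv) - mu_x * mu_y
    denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_y, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(denom > 1e-12, cov / np.where(denom > 0, denom, 1.0), 0.0)

    variance = np.clip(var_x, 0, None)
    sum_average = P @ s

    m_s = sum_average  # E[s]; equals mu_x + mu_y for normalized P
    e_s2 = P @ (s**2)
    e_s3 = P @ (s**3)
    cluster_tendency = e_s2 - m_s**2
    cluster_shade = e_s3 - 3.0 * m_s * e_s2 + 2.0 * m_s**3

    difference_variance = contrast - dissimilarity**2

    return np.column_stack(
        [
            energy,
            entropy,
            correlation,
            contrast,
            homogeneity,
            variance,
            sum_average,
            dissimilarity,
            cluster_shade,
            cluster_tendency,
            max_prob,
            difference_variance,
        ]
    )


def _inverse_variance_batch(P: np.ndarray, levels: int) -> np.ndarray:
    """Off-diagonal sum of p(i,j) / (1 + (i-j)^2) per row."""
    lv = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    w = 1.0 / (1.0 + (ii - jj) ** 2)
    np.fill_diagonal(w, 0.0)
    return P @ w.ravel()


def haralick_features(glcm: GLCM | np.ndarray) -> np.ndarray:
    """The 12 Haralick statistics of one GLCM, in :data:`HARALICK_NAMES` order.

    Accepts a :class:`GLCM` (normalized internally) or a raw square matrix;
    a non-normalized matrix is normalized with a warning.  An empty (all
    zero) GLCM yields the zero vector.
    """
    if isinstance(glcm, GLCM):
        P = glcm.normalized()
    else:
        P = np.asarray(glcm, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("expected a square matrix")
        total = P.sum()
        if total > 0 and not np.isclose(total, 1.0, atol=1e-8):
            logger.warning("non-normalized GLCM (sum=%g); normalizing", total)
            P = P / total
    L = P.shape[0]
    return _haralick_batch(P.reshape(1, L * L), L)[0]


# ---------------------------------------------------------------------------
# per-voxel extraction
# ---------------------------------------------------------------------------


def _center_coords(vol: Volume, spec: WindowSpec) -> tuple[np.ndarray, ...]:
    """(x, y, z) coordinate arrays of the voxels that receive a descriptor."""
    r = spec.size // 2
    if spec.border_policy == "pad_reflect":
        keep = vol.mask
    else:  # skip: full window must lie inside the mask (and the volume)
        keep = ndimage.minimum_filter(
            vol.mask.astype(np.uint8), size=spec.size, mode="constant", cval=0
        ).astype(bool)
        keep &= vol.mask
    idx = linear_indices(keep)
    return np.unravel_index(idx, vol.shape, order="F") + (idx,)


def _padded(data: np.ndarray, r: int) -> np.ndarray:
    return np.pad(data, r, mode="reflect")


def _window_pair_histograms(
    Qp: np.ndarray,
    centers: tuple[np.ndarray, np.ndarray, np.ndarray],
    offset: tuple[int, int, int],
    w: int,
    levels: int,
) -> np.ndarray:
    """Symmetric per-window co-occurrence histograms for one offset.

    ``Qp`` is the quantized volume reflect-padded by ``w // 2``; ``centers``
    are padded-grid coordinates.  Returns (V, levels**2) counts.
    """
    r = w // 2
    L = levels
    dx, dy, dz = offset
    # pair code at absolute position a: Qp[a] * L + Qp[a + d]
    shape = Qp.shape
    src_sl = tuple(
        slice(max(0, -d), n - max(0, d)) for n, d in zip(shape, offset)
    )
    dst_sl = tuple(
        slice(max(0, d), n - max(0, -d)) for n, d in zip(shape, offset)
    )
    pair = np.zeros(shape, dtype=np.int32)
    pair[src_sl] = Qp[src_sl].astype(np.int32) * L + Qp[dst_sl]

    V = centers[0].shape[0]
    hist = np.zeros((V, L * L), dtype=np.int32)
    rows = np.arange(V)
    # relative window positions p with both p and p+d inside the window
    ranges = [range(max(0, -d), w - max(0, d)) for d in offset]
    cx, cy, cz = centers
    for px, py, pz in product(*ranges):
        codes = pair[cx - r + px, cy - r + py, cz - r + pz]
        hist[rows, codes] += 1  # one code per row per shift: no collisions
    # fold in the transpose (symmetric GLCM)
    transpose_perm = (
        np.arange(L * L).reshape(L, L).T.ravel()
    )
    return hist + hist[:, transpose_perm]


def voxel_haralick(
    vol: Volume,
    spec: WindowSpec = WindowSpec(),
    include_inverse_variance: bool = False,
) -> FeatureMatrix:
    """Direction-averaged Haralick descriptors for every masked voxel.

    ``vol`` must already be quantized to ``spec.quantization_levels``.  For
    each voxel the 13 per-direction GLCMs of its w³ window are accumulated
    and each Haralick statistic is averaged over the 13 directions.
    """
    w = spec.size
    L = spec.quantization_levels
    data = np.asarray(vol.data)
    if data.min() < 0 or data.max() >= L:
        raise ValueError("volume must be quantized to [0, levels-1] first")
    *coords, idx = _center_coords(vol, spec)
    r = w // 2
    Qp = _padded(data.astype(np.int32), r)
    centers = tuple(c + r for c in coords)

    n_extra = 1 if include_inverse_variance else 0
    acc = np.zeros((idx.shape[0], 12 + n_extra), dtype=np.float64)
    offsets = glcm_offsets()
    for off in offsets:
        hist = _window_pair_histograms(Qp, centers, off, w, L)
        totals = hist.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(totals > 0, hist / np.where(totals > 0, totals, 1), 0.0)
        acc[:, :12] += _haralick_batch(P, L)
        if include_inverse_variance:
            acc[:, 12] += _inverse_variance_batch(P, L)
    acc /= len(offsets)
    names = HARALICK_NAMES + ((INVERSE_VARIANCE,) if include_inverse_variance else ())
    return FeatureMatrix(
        values=acc,
        feature_names=names,
        voxel_index=idx,
        grid_shape=vol.shape,
        affine=vol.affine,
    )


def first_order_features(vol: Volume, spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Central intensity, window mean and window (population) variance."""
    data = np.asarray(vol.data, dtype=np.float64)
    *coords, idx = _center_coords(vol, spec)
    mean = ndimage.uniform_filter(data, size=spec.size, mode="reflect")
    mean_sq = ndimage.uniform_filter(data**2, size=spec.size, mode="reflect")
    var = np.clip(mean_sq - mean**2, 0.0, None)
    cx, cy, cz = coords
    values = np.column_stack([data[cx, cy, cz], mean[cx, cy, cz], var[cx, cy, cz]])
    return FeatureMatrix(
        values=values,
        feature_names=FIRST_ORDER_NAMES,
        voxel_index=idx,
        grid_shape=vol.shape,
        affine=vol.affine,
    )


def local_histogram_features(
    vol: Volume, spec: WindowSpec = WindowSpec()
) -> FeatureMatrix:
    """Seven statistics of the normalized window histogram of quantized levels.

    Per voxel: mean, variance, energy sum(h²), entropy -sum(h log2 h),
    skewness m3/m2^1.5, kurtosis m4/m2² (both 0 for a zero-variance
    window), and the most probable level (lowest level on ties).
    """
    w = spec.size
    L = spec.quantization_levels
    data = np.asarray(vol.data)
    if data.min() < 0 or data.max() >= L:
        raise ValueError("volume must be quantized to [0, levels-1] first")
    *coords, idx = _center_coords(vol, spec)
    r = w // 2
    Qp = _padded(data.astype(np.int32), r)
    centers = tuple(c + r for c in coords)
    cx, cy, cz = centers

    V = idx.shape[0]
    hist = np.zeros((V, L), dtype=np.int32)
    rows = np.arange(V)
    for px, py, pz in product(range(w), repeat=3):
        codes = Qp[cx - r + px, cy - r + py, cz - r + pz]
        hist[rows, codes] += 1
    h = hist / float(w**3)

    lv = np.arange(L, dtype=np.float64)
    mean = h @ lv
    m2 = h @ (lv**2) - mean**2
    m2 = np.clip(m2, 0.0, None)
    m3 = h @ (lv**3) - 3 * mean * (h @ (lv**2)) + 2 * mean**3
    m4 = (
        h @ (lv**4)
        - 4 * mean * (h @ (lv**3))
        + 6 * mean**2 * (h @ (lv**2))
        - 3 * mean**4
    )
    energy = np.einsum("vk,vk->v", h, h)
    entropy = -xlogy(h, h).sum(axis=1) / np.log(2.0)
    nonzero = m2 > 1e-12
    skew = np.where(nonzero, m3 / np.where(nonzero, m2, 1.0) ** 1.5, 0.0)
    kurt = np.where(nonzero, m4 / np.where(nonzero, m2, 1.0) ** 2, 0.0)
    mode = np.argmax(h, axis=1).astype(np.float64)

    values = np.column_stack([mean, m2, energy, entropy, skew, kurt, mode])
    return FeatureMatrix(
        values=values,
        feature_names=LOCAL_HIST_NAMES,
        voxel_index=idx,
        grid_shape=vol.shape,
        affine=vol.affine,
    )


def global_intensity_probability(
    vol: Volume, spec: WindowSpec = WindowSpec()
) -> FeatureMatrix:
    """Relative frequency of each voxel's quantized level over masked voxels."""
    data = np.asarray(vol.data)
    L = spec.quantization_levels
    if data.min() < 0 or data.max() >= L:
        raise ValueError("volume must be quantized to [0, levels-1] first")
    *coords, idx = _center_coords(vol, spec)
    masked_vals = data[vol.mask].astype(np.int64)
    counts = np.bincount(masked_vals, minlength=L)
    freq = counts / masked_vals.shape[0]
    cx, cy, cz = coords
    values = freq[data[cx, cy, cz].astype(np.int64)].reshape(-1, 1)
    return FeatureMatrix(
        values=values,
        feature_names=GLOBAL_NAMES,
        voxel_index=idx,
        grid_shape=vol.shape,
        affine=vol.affine,
    )


def extract_features(
    vol: Volume,
    spec: WindowSpec = WindowSpec(),
    selected: list[str] | None = None,
    scale: str = "range",
) -> FeatureMatrix:
    """Full per-voxel descriptor: the four feature groups in canonical order.

    ``selected`` restricts the output to a subset of :data:`FEATURE_NAMES`
    (plus the :data:`INVERSE_VARIANCE` extra), keeping canonical column
    order.

    ``scale`` controls per-column normalization before clustering:
    ``"range"`` (default) maps each column to [0, 1] by its min-max range,
    ``"zscore"`` standardizes to zero mean / unit variance, ``"none"``
    leaves raw values.  Range scaling is the default because z-scoring
    inflates columns whose variance is dominated by within-tissue noise or
    rare boundary-window outliers to the same weight as strongly
    discriminative columns, which measurably breaks prototype clustering;
    min-max scaling preserves each statistic's signal-to-spread ratio.
    Constant columns become all-zero under either scaling.
    """
    known = set(FEATURE_NAMES) | {INVERSE_VARIANCE}
    if selected is not None:
        unknown = [n for n in selected if n not in known]
        if unknown:
            raise KeyError(f"unknown feature name(s): {unknown}")
        wanted = set(selected)
    else:
        wanted = set(FEATURE_NAMES)

    qvol = quantize(vol, spec.quantization_levels)
    blocks: list[FeatureMatrix] = []
    if wanted & (set(HARALICK_NAMES) | {INVERSE_VARIANCE}):
        blocks.append(
            voxel_haralick(
                qvol, spec, include_inverse_variance=INVERSE_VARIANCE in wanted
            )
        )
    if wanted & set(FIRST_ORDER_NAMES):
        blocks.append(first_order_features(vol, spec))
    if wanted & set(LOCAL_HIST_NAMES):
        blocks.append(local_histogram_features(qvol, spec))
    if wanted & set(GLOBAL_NAMES):
        blocks.append(global_intensity_probability(qvol, spec))

    idx = blocks[0].voxel_index
    for b in blocks[1:]:
        if not np.array_equal(b.voxel_index, idx):
            raise RuntimeError("feature groups disagree on voxel set")

    order = list(FEATURE_NAMES) + [INVERSE_VARIANCE]
    cols: dict[str, np.ndarray] = {}
    for b in blocks:
        for k, name in enumerate(b.feature_names):
            cols[name] = b.values[:, k]
    names = tuple(n for n in order if n in wanted and n in cols)
    values = np.column_stack([cols[n] for n in names])

    if not np.isfinite(values).all():
        raise FloatingPointError("non-finite feature values after extraction")

    if scale == "range":
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        values = (values - lo) / safe
        values[:, span == 0] = 0.0  # constant columns carry no information
    elif scale == "zscore":
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        safe = np.where(sd > 0, sd, 1.0)
        values = (values - mu) / safe
        values[:, sd == 0] = 0.0
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")

    return FeatureMatrix(
        values=values,
        feature_names=names,
        voxel_index=idx,
        grid_shape=vol.shape,
        affine=vol.affine,
    )
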