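"""Fuzzy c-means clustering of SOM prototypes and voxel-level segmentation.

The map's prototype vectors are fuzzy-clustered into K tissue clusters;
every voxel inherits the membership row of its best matching unit, is
defuzzified by maximum membership, and may additionally receive multiple
tissue labels wherever the membership of another cluster comes within a
threshold tau of the maximum (partial-volume handling).  Clusters are
mapped to CSF/GM/WM by ranking their mean raw intensity (ascending), the
ordering T1 contrast imposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix
from .io_volume import CSF, GM, WM, LabelMap, Volume, coords_from_linear
from .som import SOMModel, bmu_indices

logger = logging.getLogger(__name__)


@dataclass
class FCMResult:
    """Converged fuzzy partition of the prototype set."""

    memberships: np.ndarray  # (U, K), rows sum to 1
    centers: np.ndarray  # (K, F)
    objective: list[float]
    iterations: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class FuzzySegmentation:
    """Per-voxel fuzzy tissue assignment on a volume grid.

    ``crisp`` holds cluster index + 1 per masked voxel (0 elsewhere) until
    tissues are identified, after which labels are 1=CSF, 2=GM, 3=WM.
    ``pve_labels`` is a (V, K) boolean matrix of multi-assignments; each
    row contains at least the crisp label's cluster.
    """

    crisp: LabelMap
    memberships: np.ndarray  # (V, K)
    pve_labels: np.ndarray  # (V, K) bool
    tau: float
    voxel_index: np.ndarray  # (V,) linear indices into the grid

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[1]

    def crisp_rows(self) -> np.ndarray:
        """Crisp cluster index (0-based) per masked-voxel row."""
        flat = self.crisp.labels.ravel(order="F")
        return flat[self.voxel_index] - 1


def fcm_cluster(
    prototypes: np.ndarray,
    k: int = 3,
    m: float = 2.0,
    eps: float = 1e-5,
    seed: int = 0,
    max_iter: int = 1000,
    weights: np.ndarray | None = None,
    n_init: int = 1,
) -> FCMResult:
    """Fuzzy c-means with fuzzifier ``m`` on the prototype vectors.

    Alternates the stationarity updates for centers (membership^m weighted
    means) and memberships (inverse-distance rule) until the largest
    membership change drops below ``eps``.  A point coinciding with a
    center receives a one-hot membership row (standard singularity rule).
    The objective sum_k sum_i w_k u_ik^m ||x_k - c_i||^2 is recorded every
    iteration and is non-increasing.

    ``weights`` (optional, nonnegative, one per prototype) multiply each
    point's contribution to centers and objective.  Passing the BMU hit
    counts makes prototype clustering equivalent to clustering all voxels
    with each voxel replaced by its BMU prototype, so dense tissue cores
    outweigh sparse boundary prototypes.

    ``n_init > 1`` runs that many seeded restarts (seeds ``seed`` ..
    ``seed + n_init - 1``) and returns the run with the lowest final
    objective; the alternation only guarantees a local minimum, and
    restarts reliably reach the basin that matters.
    """
    X = np.asarray(prototypes, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("prototypes must be 2D")
    U_n = X.shape[0]
    if not (U_n >= k >= 2):
        raise ValueError("need at least k prototypes and k >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if not (0 < eps < 1):
        raise ValueError("eps must lie in (0, 1)")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if weights is None:
        w = np.ones(U_n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (U_n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be nonnegative, one per prototype")

    best: FCMResult | None = None
    for restart in range(n_init):
        res = _fcm_single(X, w, k, m, eps, seed + restart, max_iter)
        if best is None or res.objective[-1] < best.objective[-1]:
            best = res
    return best


def _fcm_single(
    X: np.ndarray,
    w: np.ndarray,
    k: int,
    m: float,
    eps: float,
    seed: int,
    max_iter: int,
) -> FCMResult:
    rng = np.random.default_rng(seed)
    u = rng.random((X.shape[0], k))
    u /= u.sum(axis=1, keepdims=True)

    expo = 2.0 / (m - 1.0)
    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = (u**m) * w[:, None]
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, "sqeuclidean")
        objective.append(float((um * d2).sum()))
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)  # d^(-2/(m-1))
            u_new = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u_new[rows_zero] = 0.0
            u_new[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(
                axis=1, keepdims=True
            )
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < eps:
            converged = True
            break

    um = (u**m) * w[:, None]
    centers = (um.T @ X) / um.sum(axis=0)[:, None]
    d2 = cdist(X, centers, "sqeuclidean")
    objective.append(float((um * d2).sum()))
    return FCMResult(
        memberships=u,
        centers=centers,
        objective=objective,
        iterations=it,
        converged=converged,
    )


def assign_voxels(
    model: SOMModel,
    fcmres: FCMResult,
    features: FeatureMatrix,
    bmus: np.ndarray | None = None,
) -> FuzzySegmentation:
    """Propagate prototype memberships to voxels through BMU lookup.

    Each voxel inherits the membership row of its BMU; the crisp label is
    the argmax cluster (ties -> lowest index), stored as cluster index + 1
    on the grid.  ``bmus`` may carry precomputed BMU indices to avoid a
    second nearest-prototype pass.
    """
    if fcmres.memberships.shape[0] != model.n_units:
        raise ValueError("FCM result does not match the SOM's unit count")
    if features.grid_shape is None:
        raise ValueError("feature matrix lacks grid_shape; cannot build a label map")
    if bmus is None:
        bmus = bmu_indices(model, features)
    memberships = fcmres.memberships[bmus]
    crisp_rows = memberships.argmax(axis=1)

    labels = np.zeros(features.grid_shape, dtype=np.int16)
    x, y, z = coords_from_linear(features.voxel_index, features.grid_shape)
    labels[x, y, z] = crisp_rows + 1
    affine = features.affine if features.affine is not None else np.eye(4)
    crisp = LabelMap(labels=labels, affine=affine)

    K = fcmres.n_clusters
    pve = np.zeros((memberships.shape[0], K), dtype=bool)
    pve[np.arange(memberships.shape[0]), crisp_rows] = True
    return FuzzySegmentation(
        crisp=crisp,
        memberships=memberships,
        pve_labels=pve,
        tau=0.0,
        voxel_index=features.voxel_index,
    )


def pve_assign(seg: FuzzySegmentation, tau: float) -> FuzzySegmentation:
    """Multi-label voxels whose membership comes within ``tau`` of the maximum.

    A cluster c joins the voxel's label set when u_max - u_c < tau; the
    crisp (argmax) cluster is always included, so tau = 0 reduces to the
    crisp segmentation.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    u = seg.memberships
    u_max = u.max(axis=1, keepdims=True)
    pve = (u_max - u) < tau
    pve[np.arange(u.shape[0]), seg.crisp_rows()] = True
    return FuzzySegmentation(
        crisp=seg.crisp,
        memberships=u,
        pve_labels=pve,
        tau=tau,
        voxel_index=seg.voxel_index,
    )


def cluster_intensity_order(seg: FuzzySegmentation, vol: Volume) -> np.ndarray:
    """Cluster indices sorted by ascending mean raw intensity of members.

    Empty clusters sort last and trigger a warning; exact mean ties keep
    cluster-index order (stable sort).
    """
    crisp_rows = seg.crisp_rows()
    raw = vol.data.ravel(order="F")[seg.voxel_index].astype(np.float64)
    K = seg.n_clusters
    means = np.full(K, np.inf)
    for c in range(K):
        sel = crisp_rows == c
        if sel.any():
            means[c] = raw[sel].mean()
        else:
            logger.warning("cluster %d is empty; its tissue label will be absent", c)
    if len(set(means[np.isfinite(means)])) < np.isfinite(means).sum():
        logger.warning("tied cluster mean intensities; ordering by cluster index")
    return np.argsort(means, kind="stable")


def identify_tissues(seg: FuzzySegmentation, vol: Volume) -> LabelMap:
    """Rename clusters to tissue labels by ascending mean intensity.

    On T1 contrast CSF is darkest and WM brightest, so the ascending order
    maps to CSF(1) < GM(2) < WM(3).  Only the first three nonempty
    clusters receive tissue labels.
    """
    order = cluster_intensity_order(seg, vol)
    tissue_of_cluster = np.zeros(seg.n_clusters, dtype=np.int16)
    for rank, c in enumerate(order[: len((CSF, GM, WM))]):
        tissue_of_cluster[c] = (CSF, GM, WM)[rank]
    labels = np.zeros(seg.crisp.shape, dtype=np.int16)
    crisp_rows = seg.crisp_rows()
    x, y, z = coords_from_linear(seg.voxel_index, seg.crisp.shape)
    labels[x, y, z] = tissue_of_cluster[crisp_rows]
    return LabelMap(labels=labels, affine=seg.crisp.affine)


def relabel_to_tissues(
    seg: FuzzySegmentation, vol: Volume
) -> FuzzySegmentation:
    """Reorder membership/PVE columns so cluster index c == tissue label c+1.

    After this, column 0 is CSF, 1 is GM, 2 is WM, and the crisp map equals
    :func:`identify_tissues`'s output.  The result is invariant to any
    permutation of the input cluster indices.
    """
    order = cluster_intensity_order(seg, vol)
    memberships = seg.memberships[:, order]
    pve = seg.pve_labels[:, order]
    crisp = identify_tissues(seg, vol)
    return FuzzySegmentation(
        crisp=crisp,
        memberships=memberships,
        pve_labels=pve,
        tau=seg.tau,
        voxel_index=seg.voxel_index,
    )
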