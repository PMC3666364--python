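"""Self-organizing map vector quantization of the feature space.

Units live on a 2D hexagonal (default) or rectangular lattice — 3D lattices
are accepted for fidelity experiments — and each stores a prototype vector.
Training supports the classical per-sample (online) rule and the batch rule
(neighbourhood-weighted means), both with exponentially decaying learning
rate and neighbourhood radius.  The batch rule is the default: it is
deterministic, fast, and equivalent in the quantization limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """SOM training schedule.

    The learning rate decays as alpha0 * exp(-t / epochs) (online mode
    only); the neighbourhood radius decays exponentially from ``sigma0``
    (default: half the lattice diameter) down to ``sigma_min`` by the last
    epoch, so late epochs fine-tune individual prototypes.
    """

    epochs: int = 200
    alpha0: float = 0.5
    sigma0: float | None = None
    sigma_min: float = 0.3
    seed: int = 0
    mode: str = "batch"
    subsample: int | None = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.alpha0 <= 1):
            raise ValueError("alpha0 must be in (0, 1]")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("batch", "online"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SOMModel:
    """Trained map: prototype vectors plus their lattice geometry."""

    prototypes: np.ndarray
    lattice_coords: np.ndarray
    lattice: str
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
        self.lattice_coords = np.asarray(self.lattice_coords, dtype=np.float64)
        if self.prototypes.shape[0] != int(np.prod(self.shape)):
            raise ValueError("number of prototypes must equal product of shape")
        if self.prototypes.shape[0] != self.lattice_coords.shape[0]:
            raise ValueError("lattice_coords must match prototype count")

    @property
    def n_units(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a small JSON archive (text-only, cache-friendly)."""
        payload = {
            "prototypes": self.prototypes.tolist(),
            "lattice_coords": self.lattice_coords.tolist(),
            "lattice": self.lattice,
            "shape": list(self.shape),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            prototypes=np.array(payload["prototypes"]),
            lattice_coords=np.array(payload["lattice_coords"]),
            lattice=payload["lattice"],
            shape=tuple(payload["shape"]),
        )


def lattice_coordinates(shape: tuple[int, ...], lattice: str = "hexagonal") -> np.ndarray:
    """Unit positions on the output lattice (units linearly indexed, row-major).

    2D hexagonal lattices use offset rows at unit spacing; rectangular and
    3D lattices use integer grid coordinates.
    """
    if lattice not in ("hexagonal", "rectangular"):
        raise ValueError(f"unknown lattice {lattice!r}")
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.column_stack([g.ravel() for g in grids]).astype(np.float64)
    if lattice == "hexagonal" and len(shape) == 2:
        rows = coords[:, 0].copy()
        coords[:, 1] += 0.5 * (rows % 2)  # shift odd rows
        coords[:, 0] = rows * (np.sqrt(3.0) / 2.0)
    return coords


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("features must be a nonempty 2D array")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X


def train_som(
    features: FeatureMatrix | np.ndarray,
    shape: tuple[int, ...] = (10, 10),
    cfg: TrainConfig = TrainConfig(),
    lattice: str = "hexagonal",
) -> SOMModel:
    """Train a SOM on the given samples; deterministic for a fixed seed.

    Prototypes are initialized from random training samples.  Batch mode
    replaces each prototype with the neighbourhood-weighted mean of the
    samples; online mode applies the per-sample competitive update.  For
    very large inputs a seeded uniform subsample of ``cfg.subsample`` rows
    is used for training (BMU mapping afterwards still covers all rows).
    """
    X = _as_array(features)
    rng = np.random.default_rng(cfg.seed)
    if cfg.subsample is not None and X.shape[0] > cfg.subsample:
        pick = rng.choice(X.shape[0], size=cfg.subsample, replace=False)
        X = X[np.sort(pick)]

    coords = lattice_coordinates(shape, lattice)
    U = coords.shape[0]
    V = X.shape[0]

    init_idx = rng.choice(V, size=U, replace=V < U)
    W = X[init_idx].copy()

    lat_d2 = cdist(coords, coords, "sqeuclidean")
    diameter = float(np.sqrt(lat_d2.max()))
    sigma0 = cfg.sigma0 if cfg.sigma0 is not None else max(diameter / 2.0, 1.0)
    sigma_min = min(cfg.sigma_min, sigma0)
    # decay rate chosen so sigma(last epoch) == sigma_min
    if cfg.epochs > 1 and sigma0 > sigma_min:
        lam = (cfg.epochs - 1) / np.log(sigma0 / sigma_min)
    else:
        lam = None

    for t in range(cfg.epochs):
        sigma = sigma0 * np.exp(-t / lam) if lam is not None else sigma_min
        H = np.exp(-lat_d2 / (2.0 * sigma**2))
        if cfg.mode == "batch":
            bmus = cdist(X, W, "sqeuclidean").argmin(axis=1)
            sums = np.zeros_like(W)
            np.add.at(sums, bmus, X)
            counts = np.bincount(bmus, minlength=U).astype(np.float64)
            num = H @ sums
            den = H @ counts
            ok = den > 1e-12
            W[ok] = num[ok] / den[ok, None]
        else:
            alpha = cfg.alpha0 * np.exp(-t / cfg.epochs)
            for i in rng.permutation(V):
                x = X[i]
                b = int(((W - x) ** 2).sum(axis=1).argmin())
                W += alpha * H[b][:, None] * (x - W)

    if not np.isfinite(W).all():
        raise FloatingPointError("non-finite prototypes after training")
    return SOMModel(prototypes=W, lattice_coords=coords, lattice=lattice, shape=tuple(shape))


def bmu(model: SOMModel, v: np.ndarray) -> int:
    """Index of the best matching unit (nearest prototype; ties -> lowest index)."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (model.n_features,):
        raise ValueError(f"expected a vector of length {model.n_features}")
    if not np.isfinite(v).all():
        raise ValueError("input vector contains non-finite values")
    d2 = ((model.prototypes - v) ** 2).sum(axis=1)
    return int(d2.argmin())


def bmu_indices(model: SOMModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """BMU index for each row of a feature matrix (ties -> lowest index)."""
    X = _as_array(features)
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimensionality mismatch")
    return cdist(X, model.prototypes, "sqeuclidean").argmin(axis=1)


def quantization_error(
    model: SOMModel, features: FeatureMatrix | np.ndarray
) -> float:
    """Mean Euclidean distance from each sample to its BMU prototype."""
    X = _as_array(features)
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimensionality mismatch")
    d = cdist(X, model.prototypes)
    return float(d.min(axis=1).mean())
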