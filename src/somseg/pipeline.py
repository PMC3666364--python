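"""End-to-end segmentation: features -> SOM -> FCM -> tissue labels."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .fcm import (
    FuzzySegmentation,
    assign_voxels,
    fcm_cluster,
    pve_assign,
    relabel_to_tissues,
)
from .features import FeatureMatrix, WindowSpec, extract_features
from .io_volume import LabelMap, Volume
from .som import TrainConfig, bmu_indices, quantization_error, train_som

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the segmentation pipeline, every random stage seeded."""

    window: WindowSpec = WindowSpec()
    som_shape: tuple[int, ...] = (10, 10)
    train: TrainConfig = TrainConfig(epochs=100, subsample=50_000)
    k: int = 3
    m: float = 2.0
    eps: float = 1e-5
    fcm_seed: int = 0
    fcm_restarts: int = 8
    tau: float = 0.02
    selected_features: tuple[str, ...] | None = None
    scale: str = "range"
    cache_dir: str | None = None

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (used in cache keys)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cached_features(vol: Volume, cfg: PipelineConfig) -> FeatureMatrix:
    selected = list(cfg.selected_features) if cfg.selected_features else None
    if cfg.cache_dir is None:
        return extract_features(vol, cfg.window, selected=selected, scale=cfg.scale)
    data_hash = hashlib.sha256(np.ascontiguousarray(vol.data).tobytes()).hexdigest()[:16]
    key = f"features_{data_hash}_{cfg.config_hash()}.tsv"
    path = Path(cfg.cache_dir) / key
    if path.exists():
        logger.info("loading cached features from %s", path)
        return FeatureMatrix.from_tsv(path)
    fm = extract_features(vol, cfg.window, selected=selected, scale=cfg.scale)
    path.parent.mkdir(parents=True, exist_ok=True)
    fm.to_tsv(path)
    return fm


def segment(
    vol: Volume, cfg: PipelineConfig = PipelineConfig()
) -> tuple[FuzzySegmentation, LabelMap, dict]:
    """Segment a skull-stripped volume into CSF/GM/WM.

    Stages: feature extraction over masked voxels, SOM training, fuzzy
    c-means clustering of the prototypes, voxel membership inheritance via
    BMU, tau-threshold PVE multi-labeling, and tissue identification by
    ascending mean intensity.  Returns the tissue-ordered fuzzy
    segmentation, the crisp tissue label map, and run metadata.
    """
    if vol.n_masked == 0:
        raise ValueError("volume mask is empty; nothing to segment")

    try:
        features = _cached_features(vol, cfg)
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed: {exc}") from exc

    try:
        model = train_som(features, shape=cfg.som_shape, cfg=cfg.train)
        qerr = quantization_error(model, features)
    except Exception as exc:
        raise RuntimeError(f"SOM training failed: {exc}") from exc

    try:
        bmus = bmu_indices(model, features)
        # hit-count weighting: prototype clustering then matches clustering
        # the voxels themselves (each approximated by its BMU prototype)
        hit_counts = np.bincount(bmus, minlength=model.n_units).astype(float)
        fcmres = fcm_cluster(
            model.prototypes,
            k=cfg.k,
            m=cfg.m,
            eps=cfg.eps,
            seed=cfg.fcm_seed,
            weights=hit_counts,
            n_init=cfg.fcm_restarts,
        )
    except Exception as exc:
        raise RuntimeError(f"FCM clustering failed: {exc}") from exc

    seg = assign_voxels(model, fcmres, features, bmus=bmus)
    seg = pve_assign(seg, cfg.tau)
    seg = relabel_to_tissues(seg, vol)
    labelmap = seg.crisp

    metadata = {
        "config_hash": cfg.config_hash(),
        "n_voxels": int(features.n_voxels),
        "n_features": int(features.n_features),
        "feature_names": list(features.feature_names),
        "som_shape": list(cfg.som_shape),
        "quantization_error": float(qerr),
        "fcm_iterations": int(fcmres.iterations),
        "fcm_converged": bool(fcmres.converged),
        "fcm_objective_final": float(fcmres.objective[-1]),
        "tau": float(cfg.tau),
        "seeds": {"som": cfg.train.seed, "fcm": cfg.fcm_seed},
    }
    return seg, labelmap, metadata
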