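"""Segmentation scoring against reference label maps (per-tissue Jaccard)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcm import FuzzySegmentation
from .io_volume import CSF, GM, WM, TISSUE_NAMES, LabelMap

logger = logging.getLogger(__name__)

TISSUES = (CSF, GM, WM)


@dataclass
class SegScore:
    """Per-tissue Jaccard overlap plus voxel counts in each map."""

    per_tissue: dict[int, float]
    mean: float
    counts: dict[int, tuple[int, int]]  # tissue -> (pred voxels, ref voxels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tissue": TISSUE_NAMES.get(t, str(t)),
                "jaccard": self.per_tissue[t],
                "pred_voxels": self.counts[t][0],
                "ref_voxels": self.counts[t][1],
            }
            for t in sorted(self.per_tissue)
        ]
        return pd.DataFrame(rows)


def _jaccard_sets(a_set: np.ndarray, b_set: np.ndarray) -> float:
    inter = int(np.logical_and(a_set, b_set).sum())
    union = int(np.logical_or(a_set, b_set).sum())
    if union == 0:
        logger.warning("tissue absent from both maps; Jaccard defined as 1")
        return 1.0
    return inter / union


def jaccard(a: LabelMap, b: LabelMap, tissue: int) -> float:
    """|A ∩ B| / |A ∪ B| over the voxel sets carrying ``tissue``.

    Symmetric in its arguments.  Both sets empty -> 1 (trivial agreement,
    warning logged); one empty -> 0.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return _jaccard_sets(a.labels == tissue, b.labels == tissue)


def score_segmentation(
    pred: FuzzySegmentation,
    ref: LabelMap,
    use_pve: bool = False,
    restrict_to_overlap: bool = True,
) -> SegScore:
    """Per-tissue Jaccard of a fuzzy segmentation against a reference.

    ``pred`` must already be in tissue space (columns CSF, GM, WM).  With
    ``use_pve`` a voxel counts as tissue t whenever t is in its PVE label
    set, so near-tie voxels enter several tissues.  By default scoring is
    restricted to the intersection of the two brain masks (voxels labeled
    nonzero in both maps), which removes brain-extraction disagreements.
    """
    if pred.crisp.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.crisp.shape} vs {ref.shape}")
    shape = ref.shape
    ref_flat = ref.labels.ravel(order="F")
    pred_flat = pred.crisp.labels.ravel(order="F")
    if restrict_to_overlap:
        keep_flat = (ref_flat > 0) & (pred_flat > 0)
    else:
        keep_flat = np.ones(ref_flat.shape, dtype=bool)
    keep_rows = keep_flat[pred.voxel_index]

    per: dict[int, float] = {}
    counts: dict[int, tuple[int, int]] = {}
    for t in TISSUES:
        ref_set = (ref_flat == t) & keep_flat
        if use_pve:
            col = t - 1
            pred_set = np.zeros(ref_flat.shape, dtype=bool)
            pred_set[pred.voxel_index[keep_rows]] = pred.pve_labels[keep_rows, col]
        else:
            pred_set = (pred_flat == t) & keep_flat
        per[t] = _jaccard_sets(pred_set, ref_set)
        counts[t] = (int(pred_set.sum()), int(ref_set.sum()))
    return SegScore(per_tissue=per, mean=float(np.mean(list(per.values()))), counts=counts)
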