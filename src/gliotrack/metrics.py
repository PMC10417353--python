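"""Segmentation evaluation: Dice, Jaccard, and directed Hausdorff distance.

Conventions: Dice and Jaccard return 1.0 when both masks are empty (perfect
agreement on "nothing there"), and 0.0 when exactly one is empty. The
Hausdorff distance here is the *directed* distance from ground truth to
prediction — the largest distance from a ground-truth voxel to its closest
predicted voxel, in millimetres between voxel centres — which penalizes
missed ground truth but not over-segmentation. Symmetric and percentile
variants are available as flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .grids import VolumeGrid

__all__ = ["MetricsReport", "dice", "jaccard", "hausdorff", "evaluate_case"]


def _as_bool(mask, name: str) -> np.ndarray:
    arr = mask.voxels if isinstance(mask, VolumeGrid) else np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1, True, False)).all():
        raise ValidationError(f"{name} must be binary")
    return arr.astype(bool)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    aa, bb = _as_bool(a, "a"), _as_bool(b, "b")
    if aa.shape != bb.shape:
        raise ValidationError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return aa, bb


def dice(a, b) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); 1.0 if both masks are empty."""
    aa, bb = _pair(a, b)
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((aa & bb).sum()) / denom


def jaccard(a, b) -> float:
    """Jaccard index |A∩B|/|A∪B|; 1.0 if both masks are empty."""
    aa, bb = _pair(a, b)
    union = int((aa | bb).sum())
    if union == 0:
        return 1.0
    return int((aa & bb).sum()) / union


def hausdorff(
    gt,
    pred,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    symmetric: bool = False,
    percentile: float | None = None,
) -> float:
    """Directed Hausdorff distance from ground truth to prediction, in mm.

    max over ground-truth voxels of the Euclidean distance (voxel centres,
    spacing-scaled) to the nearest predicted voxel. ``symmetric=True`` takes
    the max of both directions; ``percentile`` (e.g. 95) replaces the max by
    that percentile of the per-voxel distances. Either mask empty -> inf
    with a warning.
    """
    if isinstance(gt, VolumeGrid):
        spacing_mm = gt.spacing_mm
    gg, pp = _pair(gt, pred)
    if not gg.any() or not pp.any():
        warnings.warn("empty mask in hausdorff(); returning inf", stacklevel=2)
        return math.inf

    def directed(src: np.ndarray, dst: np.ndarray) -> float:
        # distance map to dst, sampled at src voxels
        dist = ndimage.distance_transform_edt(~dst, sampling=spacing_mm)
        vals = dist[src]
        if percentile is not None:
            return float(np.percentile(vals, percentile))
        return float(vals.max())

    d = directed(gg, pp)
    if symmetric:
        d = max(d, directed(pp, gg))
    return d


@dataclass
class MetricsReport:
    """The evaluation triad for one case (Hausdorff may be inf)."""

    dice: float
    jaccard: float
    hausdorff_mm: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_case(pred, gt, spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> MetricsReport:
    """Dice/Jaccard/directed-Hausdorff report for one predicted mask."""
    if isinstance(gt, VolumeGrid):
        spacing_mm = gt.spacing_mm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hd = hausdorff(gt, pred, spacing_mm=spacing_mm)
    return MetricsReport(
        dice=dice(pred, gt), jaccard=jaccard(pred, gt), hausdorff_mm=hd
    )
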