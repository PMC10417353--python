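"""Resection-cavity removal by multi-level Otsu thresholding, and volumetry.

The CE-T1w high-dose target (GTV2) deliberately includes the resection
cavity, but longitudinal tracking should follow only the *enhancing* tissue.
Within the GTV2 mask the CE-T1w intensity histogram separates into a dark
cavity mode and bright enhancement, with partial-volume voxels in between:
the intensities are clustered into four classes by multi-level Otsu
thresholding (maximizing between-class variance) and the lowest-intensity
class — the cavity — is removed, leaving the enhancing lesion for
volumetry. Thresholds are invariant to affine intensity rescaling (up to
histogram binning), so normalized or raw intensities give the same result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu

from .errors import DegenerateInputError, ValidationError
from .grids import VolumeGrid

__all__ = ["OtsuResult", "multi_otsu_thresholds", "remove_cavity", "mask_volume_cc"]

DEFAULT_BINS = 128


@dataclass
class OtsuResult:
    """Multi-level Otsu clustering of a value sample.

    ``thresholds`` are the ``class_count - 1`` ascending cut points;
    ``class_labels`` assigns each input value its class index 0 (darkest)
    to ``class_count - 1`` (brightest).
    """

    thresholds: np.ndarray
    class_count: int
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.class_count - 1:
            raise ValidationError("need class_count - 1 thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly ascending")


def multi_otsu_thresholds(
    values: np.ndarray, n_classes: int = 4, n_bins: int = DEFAULT_BINS
) -> OtsuResult:
    """Otsu thresholds splitting ``values`` into ``n_classes`` intensity classes.

    The thresholds maximize between-class variance over the binned
    histogram, equivalently minimizing within-class variance; this matches
    an exhaustive search over all threshold tuples on the same histogram.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty value sample")
    if np.unique(values).size < n_classes:
        raise DegenerateInputError(
            f"need at least {n_classes} distinct values for {n_classes}-class Otsu"
        )
    thresholds = np.asarray(threshold_multiotsu(values, classes=n_classes, nbins=n_bins), float)
    # Each threshold is the centre of the last histogram bin of its lower
    # class; label by bin membership (class boundary = the bin edge above
    # the threshold's bin), so coarse binning cannot split a bin's values.
    _, edges = np.histogram(values, bins=n_bins)
    t_bins = np.clip(np.digitize(thresholds, edges) - 1, 0, n_bins - 1)
    boundaries = edges[t_bins + 1]
    labels = np.digitize(values, bins=boundaries)
    return OtsuResult(thresholds=thresholds, class_count=n_classes, class_labels=labels)


def remove_cavity(
    t1ce: VolumeGrid, gtv2_mask: VolumeGrid, n_classes: int = 4, n_bins: int = DEFAULT_BINS
) -> VolumeGrid:
    """Enhancing-lesion mask: GTV2 minus its lowest Otsu intensity class.

    Otsu runs only on CE-T1w intensities inside the GTV2 mask. If those
    intensities are too degenerate to cluster, the mask is returned
    unchanged with a warning (no cavity can be separated). The result is
    always a subset of ``gtv2_mask``.
    """
    if t1ce.shape != gtv2_mask.shape:
        raise ValidationError(
            f"image shape {t1ce.shape} != mask shape {gtv2_mask.shape}"
        )
    if not gtv2_mask.is_binary():
        raise ValidationError("gtv2_mask must be binary")
    mask = gtv2_mask.voxels.astype(bool)
    if not mask.any():
        raise ValidationError("gtv2_mask is empty")

    vals = t1ce.voxels[mask]
    try:
        otsu = multi_otsu_thresholds(vals, n_classes=n_classes, n_bins=n_bins)
    except DegenerateInputError:
        warnings.warn(
            "GTV2 intensities are degenerate; cannot separate a cavity — "
            "returning the mask unchanged",
            stacklevel=2,
        )
        return gtv2_mask.like(gtv2_mask.voxels.copy())

    keep = otsu.class_labels > 0  # drop the lowest-intensity (cavity) class
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[mask] = keep.astype(np.uint8)
    return gtv2_mask.like(out)


def mask_volume_cc(mask: VolumeGrid, spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Volume of a binary mask in cc (voxel count x voxel volume)."""
    spacing = mask.spacing_mm if spacing_mm is None else spacing_mm
    if any(s <= 0 for s in spacing):
        raise ValidationError("spacing must be positive")
    count = float(np.count_nonzero(mask.voxels))
    return count * float(np.prod(spacing)) / 1000.0
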