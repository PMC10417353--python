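"""Image standardization and model-input assembly.

Inputs are assumed pre-registered onto the CE-T1w grid (registration
estimation is out of scope). Standardization comprises: resampling every
volume to a common grid with the physical field of view preserved,
zero-mean/unit-variance normalization computed over nonzero voxels only
(so the background stays exactly zero), and brain-mask application for the
skull-stripped channels.

The segmentation networks take a 3-channel volume whose composition depends
on the target:

* GTV1 (FLAIR target): skull-stripped FLAIR, skull-stripped CE-T1w,
  with-skull FLAIR;
* GTV2 (CE-T1w target): skull-stripped CE-T1w, skull-stripped FLAIR,
  with-skull CE-T1w.

The with-skull third channel helps delineate resection cavities abutting
the skull. Training samples are fixed-size crops, oversampled around the
label so the foreground is seen often enough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .grids import VolumeGrid

__all__ = [
    "STANDARD_GRID",
    "ChannelStack",
    "resample_to_grid",
    "normalize_nonzero",
    "apply_brain_mask",
    "assemble_channels",
    "extract_training_crops",
    "standardize_case",
]

#: Common grid every case is resampled to at full scale.
STANDARD_GRID: tuple[int, int, int] = (256, 256, 160)


@dataclass
class ChannelStack:
    """Ordered 3-channel model input on a single shared grid."""

    channels: tuple[VolumeGrid, VolumeGrid, VolumeGrid]
    target: str  # "GTV1" | "GTV2"

    def __post_init__(self) -> None:
        if self.target not in ("GTV1", "GTV2"):
            raise ValidationError(f"target must be 'GTV1' or 'GTV2', got {self.target!r}")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if not ch.same_grid_as(ref):
                raise ValidationError("all channels must share one grid (shape and spacing)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.channels[0].spacing_mm

    def as_array(self, dtype=np.float32) -> np.ndarray:
        """(3, D, H, W) array view for the network."""
        return np.stack([c.voxels for c in self.channels]).astype(dtype, copy=False)


def resample_to_grid(
    v: VolumeGrid, target_shape: tuple[int, int, int] = STANDARD_GRID, kind: str = "image"
) -> VolumeGrid:
    """Resample onto ``target_shape`` preserving the physical field of view.

    Spacing is rescaled so shape x spacing is unchanged per axis. Images use
    trilinear interpolation; masks use nearest-neighbour and must be binary.
    """
    if kind not in ("image", "mask"):
        raise ValidationError(f"kind must be 'image' or 'mask', got {kind!r}")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ParameterError(f"target_shape must be a positive triple, got {target_shape}")
    if kind == "mask" and not v.is_binary():
        raise ValidationError("kind='mask' requires a binary volume")

    new_spacing = tuple(
        s * n / t for s, n, t in zip(v.spacing_mm, v.shape, target_shape)
    )
    if target_shape == v.shape:
        return v.like(v.voxels.copy())

    zoom = [t / n for t, n in zip(target_shape, v.shape)]
    order = 1 if kind == "image" else 0
    out = ndimage.zoom(
        v.voxels.astype(np.float64 if kind == "image" else v.voxels.dtype),
        zoom,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    # grid_mode=True treats the array as spanning the full field of view,
    # but rounding can still leave the shape off by one: assert instead
    assert out.shape == target_shape, (out.shape, target_shape)
    return VolumeGrid(out, spacing_mm=new_spacing)


def normalize_nonzero(v: VolumeGrid) -> VolumeGrid:
    """Zero-mean/unit-variance normalization over the nonzero voxels.

    The population (n) denominator is used; originally-zero voxels remain
    exactly zero, so the background never leaks into the statistics.
    """
    vals = v.voxels
    nz = vals != 0
    n = int(nz.sum())
    if n < 2:
        raise ParameterError("need at least 2 nonzero voxels to normalize")
    mean = float(vals[nz].mean())
    sd = float(vals[nz].std())  # population denominator
    if sd == 0:
        raise ParameterError("nonzero voxels have zero variance; cannot normalize")
    out = np.zeros_like(vals, dtype=np.float64)
    out[nz] = (vals[nz] - mean) / sd
    return v.like(out)


def apply_brain_mask(v: VolumeGrid, brain_mask: VolumeGrid) -> VolumeGrid:
    """Zero out voxels outside the brain mask (skull stripping by mask)."""
    if v.shape != brain_mask.shape:
        raise ValidationError(
            f"volume shape {v.shape} != mask shape {brain_mask.shape}"
        )
    if not brain_mask.is_binary():
        raise ValidationError("brain_mask must be binary")
    return v.like(v.voxels * (brain_mask.voxels != 0))


def assemble_channels(
    flair_ss: VolumeGrid,
    t1ce_ss: VolumeGrid,
    flair_skull: VolumeGrid,
    t1ce_skull: VolumeGrid,
    target: str,
) -> ChannelStack:
    """Build the target-specific 3-channel input (pure channel selection).

    GTV1 -> (FLAIR stripped, CE-T1w stripped, FLAIR with skull);
    GTV2 -> (CE-T1w stripped, FLAIR stripped, CE-T1w with skull).
    """
    vols = (flair_ss, t1ce_ss, flair_skull, t1ce_skull)
    ref = vols[0]
    for v in vols[1:]:
        if not v.same_grid_as(ref):
            raise ValidationError("all four volumes must share one grid")
    if target == "GTV1":
        channels = (flair_ss, t1ce_ss, flair_skull)
    elif target == "GTV2":
        channels = (t1ce_ss, flair_ss, t1ce_skull)
    else:
        raise ValidationError(f"target must be 'GTV1' or 'GTV2', got {target!r}")
    return ChannelStack(channels=channels, target=target)


def standardize_case(
    t1ce: VolumeGrid,
    flair: VolumeGrid,
    brain_mask: VolumeGrid,
    target: str,
    grid_shape: tuple[int, int, int] | None = None,
) -> ChannelStack:
    """Full standardization of one registered case into a model input.

    Optionally resamples everything to ``grid_shape``, then normalizes and
    assembles the target-specific channels. The skull-stripped channels are
    normalized over brain voxels (strip, then normalize); the with-skull
    third channel is normalized over the whole head, keeping each channel
    internally standardized.
    """
    if grid_shape is not None:
        t1ce = resample_to_grid(t1ce, grid_shape, kind="image")
        flair = resample_to_grid(flair, grid_shape, kind="image")
        brain_mask = resample_to_grid(brain_mask, grid_shape, kind="mask")
    flair_ss = normalize_nonzero(apply_brain_mask(flair, brain_mask))
    t1ce_ss = normalize_nonzero(apply_brain_mask(t1ce, brain_mask))
    flair_skull = normalize_nonzero(flair)
    t1ce_skull = normalize_nonzero(t1ce)
    return assemble_channels(flair_ss, t1ce_ss, flair_skull, t1ce_skull, target)


def extract_training_crops(
    stack: ChannelStack,
    label: VolumeGrid,
    crop_shape: tuple[int, int, int] = (128, 128, 128),
    n: int = 1,
    rng_seed: int = 0,
    foreground_prob: float = 0.5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ``n`` training crops of exactly ``crop_shape``.

    With probability ``foreground_prob`` a crop is centred on a uniformly
    chosen label voxel (clamped to stay inside the volume), otherwise its
    corner is uniform over all valid positions. Returns (channels, label)
    array pairs of shapes (3, *crop_shape) and crop_shape.
    """
    crop_shape = tuple(int(c) for c in crop_shape)
    shape = stack.shape
    if label.shape != shape:
        raise ValidationError(f"label shape {label.shape} != stack shape {shape}")
    if any(c > s for c, s in zip(crop_shape, shape)):
        raise ParameterError(f"crop_shape {crop_shape} exceeds volume shape {shape}")

    arr = stack.as_array()
    lab = np.ascontiguousarray(label.voxels.astype(np.float32))
    fg = np.argwhere(lab > 0)
    rng = np.random.default_rng(rng_seed)
    max_corner = [s - c for s, c in zip(shape, crop_shape)]

    out = []
    for _ in range(n):
        if len(fg) > 0 and rng.random() < foreground_prob:
            center = fg[rng.integers(len(fg))]
            corner = [
                int(np.clip(ci - cs // 2, 0, mc))
                for ci, cs, mc in zip(center, crop_shape, max_corner)
            ]
        else:
            corner = [int(rng.integers(mc + 1)) for mc in max_corner]
        sl = tuple(slice(c, c + cs) for c, cs in zip(corner, crop_shape))
        out.append((arr[(slice(None), *sl)].copy(), lab[sl].copy()))
    return out
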