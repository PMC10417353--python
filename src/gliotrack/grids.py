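"""The universal 3D image carrier used throughout the package.

A :class:`VolumeGrid` is a 3D scalar voxel array plus the physical metadata
needed to interpret it: voxel spacing in millimetres and an affine mapping
voxel indices to scanner coordinates (RAS+ by convention, as in NIfTI-1).
All coordinates in this package are 0-based voxel indices; physical
quantities (volumes, distances) are derived through ``spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid"]


def _default_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class VolumeGrid:
    """A 3D scalar voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        3D array of voxel values. Stored as float unless it is a mask.
    spacing_mm
        Voxel edge lengths along each axis, in millimetres. Strictly positive.
    affine
        Optional 4x4 voxel-to-world affine (NIfTI convention). If omitted, a
        diagonal affine built from ``spacing_mm`` is used.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be a positive triple, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must contain finite values only")
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def like(self, voxels: np.ndarray, spacing_mm=None) -> "VolumeGrid":
        """A new grid carrying ``voxels`` with this grid's metadata."""
        return VolumeGrid(
            voxels,
            spacing_mm=self.spacing_mm if spacing_mm is None else spacing_mm,
            affine=None if spacing_mm is not None else self.affine.copy(),
        )

    def is_binary(self) -> bool:
        v = self.voxels
        return bool(np.isin(np.unique(v), (0, 1)).all())

    def same_grid_as(self, other: "VolumeGrid", spacing_rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm, rtol=spacing_rtol
        )
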