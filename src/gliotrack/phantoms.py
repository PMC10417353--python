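"""Synthetic post-operative brain MRI phantoms with ground-truth target masks.

After glioblastoma resection, the imaging appearance that radiotherapy
targets are drawn on is characteristic: a resection cavity that is dark on
contrast-enhanced T1-weighted MRI (CE-T1w), a thin enhancing rim and possibly
a residual enhancing nodule around it, and a surrounding region of
T2w/FLAIR hyperintensity (edema and infiltrative disease) that contains the
cavity and post-operative blood products. The two radiotherapy gross tumor
volumes are nested: GTV2 (high-dose target, drawn on CE-T1w) covers cavity +
enhancing lesion, while GTV1 (lower-dose target, drawn on FLAIR) covers the
full hyperintense region and therefore contains GTV2.

This module generates that morphology with analytically known geometry —
spheres and spherical shells — so every downstream stage (preprocessing,
segmentation, cavity removal, longitudinal scoring) can be exercised and
checked against closed-form volumes without patient data. A Gaussian
point-spread blur emulates partial-volume transitions at tissue boundaries;
intensities are arbitrary units, not calibrated MRI signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .btrads import VisitRecord
from .errors import ParameterError
from .grids import VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "VisitSpec",
    "TrajectorySpec",
    "generate_phantom",
    "generate_series",
    "analytic_volumes",
    "DEFAULT_TISSUE_MEANS",
]

# Arbitrary-unit tissue intensities per modality. Chosen so contrast
# directions match the clinical appearance: cavity dark on both sequences,
# enhancement bright on CE-T1w, edema and blood bright on FLAIR.
DEFAULT_TISSUE_MEANS: dict[str, float] = {
    "background": 0.0,
    "brain": 100.0,
    "skull": 60.0,
    "cavity": 20.0,
    "rim_enhancement": 180.0,
    "edema": 160.0,
    "blood_product": 200.0,
}

_SKULL_THICKNESS_MM = 4.0
_BLOOD_THICKNESS_MM = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and intensity description of one synthetic case.

    Radii are in millimetres; ``cavity_center`` is in (0-based) voxel
    coordinates. ``noise_sd`` is the Gaussian noise standard deviation as a
    fraction of the brain tissue mean; ``psf_sigma_mm`` is the width of the
    partial-volume blur applied to the noiseless tissue-mean field (0
    disables it, giving exactly piecewise-constant intensities).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0
    cavity_center: tuple[float, float, float] | None = None
    cavity_radius_mm: float = 10.0
    rim_thickness_mm: float = 3.0
    edema_radius_mm: float = 22.0
    nodule_radius_mm: float = 4.0
    noise_sd: float = 0.05
    psf_sigma_mm: float = 1.0
    tissue_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    abut_skull: bool = False

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ParameterError(f"grid_shape must be a triple of ints >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError("spacing_mm must be strictly positive")
        for name in ("cavity_radius_mm", "rim_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.nodule_radius_mm < 0 or self.noise_sd < 0 or self.psf_sigma_mm < 0:
            raise ParameterError("nodule_radius_mm, noise_sd and psf_sigma_mm must be >= 0")
        inner = self.cavity_radius_mm + self.rim_thickness_mm
        if self.edema_radius_mm < inner:
            raise ParameterError(
                f"edema_radius_mm ({self.edema_radius_mm}) must be >= cavity_radius_mm + "
                f"rim_thickness_mm ({inner}): GTV2 region must nest inside GTV1"
            )
        if self.nodule_radius_mm > 0 and self.edema_radius_mm < inner + 2 * self.nodule_radius_mm:
            raise ParameterError(
                "with a residual nodule, edema_radius_mm must be >= cavity + rim + "
                "2*nodule so the nodule stays inside GTV1"
            )
        half_extent = 0.5 * min(n * s for n, s in zip(self.grid_shape, self.spacing_mm))
        reach = max(self.edema_radius_mm, inner + 2 * self.nodule_radius_mm)
        if reach >= half_extent:
            raise ParameterError(
                f"lesion extent {reach:.1f} mm exceeds half the grid's physical extent "
                f"({half_extent:.1f} mm): grid too small"
            )
        missing = set(DEFAULT_TISSUE_MEANS) - set(self.tissue_means)
        if missing:
            raise ParameterError(f"tissue_means missing classes: {sorted(missing)}")

    # derived geometry -----------------------------------------------------

    @property
    def brain_radius_mm(self) -> float:
        half_extent = 0.5 * min(n * s for n, s in zip(self.grid_shape, self.spacing_mm))
        return 0.78 * half_extent

    def center_mm(self) -> np.ndarray:
        """Physical coordinates of the cavity centre (grid centre if unset)."""
        if self.cavity_center is not None:
            return np.asarray(self.cavity_center, float) * np.asarray(self.spacing_mm)
        return (np.asarray(self.grid_shape, float) - 1) / 2 * np.asarray(self.spacing_mm)


@dataclass
class PhantomCase:
    """One synthetic patient: images, masks, and analytic ground truth."""

    ce_t1w: VolumeGrid
    flair: VolumeGrid
    brain_mask: VolumeGrid
    skull_mask: VolumeGrid
    gtv1_true: VolumeGrid
    gtv2_true: VolumeGrid
    enh_true: VolumeGrid  # rim + nodule: the enhancing compartment after cavity removal
    analytic_gtv1_cc: float
    analytic_gtv2_cc: float
    spec: PhantomSpec


@dataclass(frozen=True)
class VisitSpec:
    days_since_surgery: int
    days_since_rt: int | None = None
    gtv1_volume_multiplier: float = 1.0
    enh_volume_multiplier: float = 1.0


@dataclass(frozen=True)
class TrajectorySpec:
    """An ordered longitudinal visit sequence; multipliers are relative to
    the first (baseline) visit's ground-truth volumes."""

    visits: tuple[VisitSpec, ...]

    def __post_init__(self) -> None:
        if not self.visits:
            raise ParameterError("trajectory must contain at least one visit")
        days = [v.days_since_surgery for v in self.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError(f"visit days must be strictly increasing, got {days}")
        for v in self.visits:
            if v.gtv1_volume_multiplier <= 0 or v.enh_volume_multiplier < 0:
                raise ParameterError("gtv1 multiplier must be > 0, enh multiplier >= 0")


def _sphere_cc(radius_mm: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_mm**3 / 1000.0


def analytic_volumes(spec: PhantomSpec) -> tuple[float, float]:
    """Closed-form (gtv1_cc, gtv2_cc) for a spec's geometry.

    GTV2 is the cavity+rim sphere plus the (tangent, disjoint) nodule
    sphere; GTV1 is the edema sphere, which contains both.
    """
    gtv2 = _sphere_cc(spec.cavity_radius_mm + spec.rim_thickness_mm) + _sphere_cc(
        spec.nodule_radius_mm
    )
    gtv1 = _sphere_cc(spec.edema_radius_mm)
    return gtv1, gtv2


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one post-operative phantom; deterministic for a fixed seed."""
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, float)
    means = spec.tissue_means

    # physical coordinates of voxel centres
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    grid_center = (np.asarray(shape, float) - 1) / 2 * spacing

    cav_center = spec.center_mm()
    if spec.abut_skull:
        # slide the cavity centre outward along +x until it is tangent to
        # the inner skull (= brain) surface
        direction = np.array([1.0, 0.0, 0.0])
        cav_center = grid_center + direction * (spec.brain_radius_mm - spec.cavity_radius_mm)

    r_head = np.sqrt(
        (xx - grid_center[0]) ** 2 + (yy - grid_center[1]) ** 2 + (zz - grid_center[2]) ** 2
    )
    brain = r_head <= spec.brain_radius_mm
    skull = (r_head > spec.brain_radius_mm) & (
        r_head <= spec.brain_radius_mm + _SKULL_THICKNESS_MM
    )

    r_cav = np.sqrt(
        (xx - cav_center[0]) ** 2 + (yy - cav_center[1]) ** 2 + (zz - cav_center[2]) ** 2
    )
    inner = spec.cavity_radius_mm + spec.rim_thickness_mm
    cavity = (r_cav <= spec.cavity_radius_mm) & brain
    rim = (r_cav > spec.cavity_radius_mm) & (r_cav <= inner) & brain
    edema = (r_cav <= spec.edema_radius_mm) & brain

    if spec.nodule_radius_mm > 0:
        nod_center = cav_center + np.array([inner + spec.nodule_radius_mm, 0.0, 0.0])
        r_nod = np.sqrt(
            (xx - nod_center[0]) ** 2 + (yy - nod_center[1]) ** 2 + (zz - nod_center[2]) ** 2
        )
        nodule = (r_nod <= spec.nodule_radius_mm) & brain
    else:
        nodule = np.zeros(shape, bool)

    # blood product: a crescent of FLAIR hyperintensity hugging the cavity
    # (posterior half-shell just outside the rim); no separate ground-truth mask
    blood = (
        (r_cav > inner)
        & (r_cav <= inner + _BLOOD_THICKNESS_MM)
        & (xx < cav_center[0])
        & edema
    )

    gtv2 = cavity | rim | nodule
    gtv1 = edema | gtv2
    enh = rim | nodule

    # piecewise-constant tissue-mean fields, painted most-general first
    t1 = np.zeros(shape, np.float64)
    t1[brain] = means["brain"]
    t1[skull] = means["skull"]
    t1[rim | nodule] = means["rim_enhancement"]
    t1[cavity] = means["cavity"]

    fl = np.zeros(shape, np.float64)
    fl[brain] = means["brain"]
    fl[skull] = means["skull"]
    fl[edema] = means["edema"]
    fl[blood] = means["blood_product"]
    fl[nodule] = means["edema"]
    fl[cavity] = means["cavity"]

    if spec.psf_sigma_mm > 0:
        sigma_vox = spec.psf_sigma_mm / spacing
        t1 = ndimage.gaussian_filter(t1, sigma=sigma_vox)
        fl = ndimage.gaussian_filter(fl, sigma=sigma_vox)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd * means["brain"]
        head = brain | skull
        t1 = t1 + sd * rng.standard_normal(shape) * head
        fl = fl + sd * rng.standard_normal(shape) * head

    spacing_t = tuple(spacing)
    g1_cc, g2_cc = analytic_volumes(spec)
    as_grid = lambda a: VolumeGrid(a, spacing_mm=spacing_t)
    as_mask = lambda m: VolumeGrid(m.astype(np.uint8), spacing_mm=spacing_t)
    return PhantomCase(
        ce_t1w=as_grid(t1),
        flair=as_grid(fl),
        brain_mask=as_mask(brain),
        skull_mask=as_mask(skull),
        gtv1_true=as_mask(gtv1),
        gtv2_true=as_mask(gtv2),
        enh_true=as_mask(enh),
        analytic_gtv1_cc=g1_cc,
        analytic_gtv2_cc=g2_cc,
        spec=spec,
    )


def _mask_cc(mask: VolumeGrid) -> float:
    return float(mask.voxels.sum()) * mask.voxel_volume_mm3 / 1000.0


def _visit_spec(base: PhantomSpec, visit: VisitSpec) -> PhantomSpec:
    """Rescale lesion radii so ground-truth volumes hit the visit multipliers.

    The GTV1 (FLAIR) multiplier rescales the edema radius cubically. The
    enhancing multiplier targets the total enhancing compartment
    (rim shell + nodule): the rim is held fixed and the nodule radius is
    resolved in closed form; a target at or below the rim volume removes
    the nodule entirely.
    """
    edema_r = base.edema_radius_mm * visit.gtv1_volume_multiplier ** (1.0 / 3.0)

    inner = base.cavity_radius_mm + base.rim_thickness_mm
    rim_cc = _sphere_cc(inner) - _sphere_cc(base.cavity_radius_mm)
    base_enh_cc = rim_cc + _sphere_cc(base.nodule_radius_mm)
    target_cc = base_enh_cc * visit.enh_volume_multiplier
    extra = max(target_cc - rim_cc, 0.0)
    nodule_r = (extra * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    if nodule_r > 0 and edema_r < inner + 2 * nodule_r:
        # nesting forces the edema sphere to grow beyond its own multiplier
        grown = inner + 2 * nodule_r
        if (grown / edema_r) ** 3 > 1.05:
            warnings.warn(
                f"enh multiplier {visit.enh_volume_multiplier} needs a nodule of "
                f"{nodule_r:.1f} mm; growing the edema radius {edema_r:.1f} -> "
                f"{grown:.1f} mm overshoots the requested GTV1 volume multiplier",
                stacklevel=3,
            )
        edema_r = grown
    return replace(base, edema_radius_mm=edema_r, nodule_radius_mm=nodule_r)


def generate_series(
    spec: PhantomSpec, traj: TrajectorySpec
) -> list[tuple[PhantomCase, VisitRecord]]:
    """Generate a longitudinal phantom series with ground-truth visit records.

    The first visit is the baseline; each later visit's lesion radii are
    rescaled so its true volumes equal baseline volume x multiplier. The
    returned :class:`~gliotrack.btrads.VisitRecord` volumes are voxel-counted
    from the true masks (FLAIR volume = GTV1, enhancing volume = rim+nodule).
    """
    out: list[tuple[PhantomCase, VisitRecord]] = []
    for i, visit in enumerate(traj.visits):
        vspec = _visit_spec(spec, visit)
        case = generate_phantom(replace(vspec, seed=spec.seed + i))
        record = VisitRecord(
            date_days=visit.days_since_surgery,
            flair_cc=_mask_cc(case.gtv1_true),
            enh_cc=_mask_cc(case.enh_true),
            days_since_rt=visit.days_since_rt,
            is_baseline=(i == 0),
        )
        out.append((case, record))
    return out
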