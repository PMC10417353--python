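"""NIfTI case bundles, phantom serialization, and tracking reports.

A "case" on disk is a directory of NIfTI-1 files sharing one grid:
``ce_t1w.nii.gz``, ``flair.nii.gz``, ``brain_mask.nii.gz`` and optionally
``gtv1.nii.gz`` / ``gtv2.nii.gz`` (absent for inference-only cases), plus a
``case.json`` sidecar. A longitudinal series is one sub-directory per visit
plus a ``visits.csv`` table. Tracking results are written as ``scores.json``,
``volumes.csv`` and a static volume-vs-time plot annotated with scores.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .btrads import ScoreResult, VisitRecord
from .errors import ValidationError
from .grids import VolumeGrid
from .phantoms import PhantomCase

__all__ = [
    "CaseBundle",
    "load_volume",
    "save_volume",
    "load_case",
    "save_case",
    "save_series",
    "load_visits",
    "write_tracking_report",
]

_IMAGE_FILES = ("ce_t1w", "flair")
_MASK_FILES = ("brain_mask", "gtv1", "gtv2")
_OPTIONAL = ("gtv1", "gtv2", "skull_mask")


@dataclasses.dataclass
class CaseBundle:
    """In-memory view of one on-disk case; GTV masks may be absent."""

    ce_t1w: VolumeGrid
    flair: VolumeGrid
    brain_mask: VolumeGrid
    gtv1: VolumeGrid | None = None
    gtv2: VolumeGrid | None = None
    skull_mask: VolumeGrid | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def inference_only(self) -> bool:
        return self.gtv1 is None and self.gtv2 is None


def save_volume(v: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), affine=v.affine)
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, path)
    return path


def load_volume(path: str | Path, mask: bool = False) -> VolumeGrid:
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several format errors
        raise ValidationError(f"cannot read NIfTI file {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(
        data.astype(np.uint8) if mask else data, spacing_mm=spacing, affine=img.affine
    )
    if mask and not grid.is_binary():
        raise ValidationError(f"mask file {path} is not binary")
    return grid


def save_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write a phantom case as a NIfTI directory with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(case.ce_t1w, out / "ce_t1w.nii.gz")
    save_volume(case.flair, out / "flair.nii.gz")
    for name in ("brain_mask", "skull_mask", "gtv1_true", "gtv2_true", "enh_true"):
        fname = name.replace("_true", "") + ".nii.gz"
        save_volume(getattr(case, name), out / fname)
    sidecar = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(case.spec).items()
        },
        "analytic_gtv1_cc": case.analytic_gtv1_cc,
        "analytic_gtv2_cc": case.analytic_gtv2_cc,
    }
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_case(case_dir: str | Path) -> CaseBundle:
    """Load a case directory; GTV masks are optional (inference-only mode)."""
    case_dir = Path(case_dir)
    paths = {name: case_dir / f"{name}.nii.gz" for name in (*_IMAGE_FILES, *_MASK_FILES, "skull_mask")}
    for name in ("ce_t1w", "flair", "brain_mask"):
        if not paths[name].exists():
            raise ValidationError(f"missing required file: {paths[name]}")

    vols: dict[str, VolumeGrid | None] = {}
    for name, path in paths.items():
        if not path.exists():
            if name in _OPTIONAL:
                vols[name] = None
                continue
            raise ValidationError(f"missing required file: {path}")
        vols[name] = load_volume(path, mask=name in (*_MASK_FILES, "skull_mask"))

    ref = vols["ce_t1w"]
    for name, v in vols.items():
        if v is not None and not v.same_grid_as(ref, spacing_rtol=1e-3):
            raise ValidationError(
                f"{name} grid ({v.shape}, {v.spacing_mm}) is incompatible with ce_t1w"
            )
    meta_path = case_dir / "case.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CaseBundle(
        ce_t1w=vols["ce_t1w"],
        flair=vols["flair"],
        brain_mask=vols["brain_mask"],
        gtv1=vols["gtv1"],
        gtv2=vols["gtv2"],
        skull_mask=vols["skull_mask"],
        metadata=metadata,
    )


def save_series(
    series: list[tuple[PhantomCase, VisitRecord]], out_dir: str | Path
) -> Path:
    """Write a longitudinal phantom series: one directory per visit + visits.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (case, rec) in enumerate(series):
        save_case(case, out / f"visit_{i:02d}")
        rows.append(
            {
                "visit_index": i,
                "date_days": rec.date_days,
                "days_since_rt": rec.days_since_rt,
                "gtv1_cc_true": rec.flair_cc,
                "enh_cc_true": rec.enh_cc,
                "is_baseline": rec.is_baseline,
            }
        )
    pd.DataFrame(rows).to_csv(out / "visits.csv", index=False)
    return out


def load_visits(path: str | Path) -> list[VisitRecord]:
    """Read a visits table (CSV or JSON) into VisitRecords.

    Expected columns/keys: date_days (or visit_date_days), flair_cc, enh_cc,
    optional days_since_rt, is_baseline.
    """
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    records = []
    for row in rows:
        days_rt = row.get("days_since_rt")
        if days_rt is not None and (isinstance(days_rt, float) and np.isnan(days_rt)):
            days_rt = None
        records.append(
            VisitRecord(
                date_days=int(row.get("date_days", row.get("visit_date_days"))),
                flair_cc=float(row.get("flair_cc", row.get("gtv1_cc_true"))),
                enh_cc=float(row.get("enh_cc", row.get("enh_cc_true"))),
                days_since_rt=None if days_rt is None else int(days_rt),
                is_baseline=bool(row.get("is_baseline", False)),
            )
        )
    return records


def write_tracking_report(
    visits: list[VisitRecord],
    results: list[ScoreResult],
    out_dir: str | Path,
    plot: bool = True,
) -> dict[str, Path]:
    """Write scores.json, volumes.csv and a volume-vs-time plot.

    The JSON carries per-visit score, sub-letter, percent changes and the
    fired-rule rationale; the CSV mirrors the plot data (one row per visit).
    """
    if not results or len(visits) != len(results):
        raise ValidationError("need one ScoreResult per visit (nonempty)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def chg(c):
        return None if c is None or c.pct is None else round(c.pct, 3)

    payload = [
        {
            "date_days": v.date_days,
            "flair_cc": v.flair_cc,
            "enh_cc": v.enh_cc,
            "days_since_rt": v.days_since_rt,
            "major": r.major,
            "sub": r.sub,
            "code": r.code,
            "flair_change_pct": chg(r.flair_change),
            "enh_change_pct": chg(r.enh_change),
            "rationale": r.rationale,
        }
        for v, r in zip(visits, results)
    ]
    scores_path = out / "scores.json"
    scores_path.write_text(json.dumps(payload, indent=2))
    csv_path = out / "volumes.csv"
    pd.DataFrame(
        [{k: row[k] for k in ("date_days", "flair_cc", "enh_cc", "code")} for row in payload]
    ).to_csv(csv_path, index=False)

    paths = {"scores": scores_path, "volumes": csv_path}
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        days = [v.date_days for v in visits]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(days, [v.flair_cc for v in visits], "o-", label="T2w/FLAIR lesion (GTV1)")
        ax.plot(days, [v.enh_cc for v in visits], "s-", label="Enhancing lesion (ENH)")
        for v, r in zip(visits, results):
            ax.annotate(
                r.code.upper(),
                (v.date_days, max(v.flair_cc, v.enh_cc)),
                textcoords="offset points",
                xytext=(0, 8),
                ha="center",
                fontsize=9,
            )
        ax.set_xlabel("days since surgery")
        ax.set_ylabel("lesion volume (cc)")
        ax.legend()
        fig.tight_layout()
        plot_path = out / "tracking.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
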