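"""Volume I/O (NIfTI primary, NRRD secondary), DICOM RTSTRUCT import,
run configuration and the end-to-end pipeline driver.

On-disk conventions: masks are stored as 8-bit 0/1 volumes; the in-memory
(slice, row, column) array maps to an axis-aligned NIfTI affine
``diag(col_spacing, row_spacing, slice_spacing)`` with the origin in the
translation column (voxel-centre convention).  Round-trips preserve shape,
spacing, origin and occupancy losslessly; rotated/oblique affines are
rejected rather than silently reinterpreted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import SimpleITK as sitk
import yaml
from skimage.draw import polygon2mask

from .cohort import CohortReport, build_report
from .dosimetry import DoseGrid
from .errors import ConfigError, FormatError, UnsupportedFeatureError
from .geometry import Mask3D
from .phantoms import DosePrescription, default_head_neck_spec, make_cohort
from .qa_rules import RoundInput, default_rules, load_rules, run_benchmark

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "import_dicom_rtstruct",
    "RunConfig",
    "run_pipeline",
    "write_report_files",
]

log = logging.getLogger(__name__)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _grid_to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    return img


def _write_volume(data: np.ndarray, spacing, origin, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        # nibabel stores fastest-varying axis first: transpose to (x, y, z)
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0]).astype(float)
        affine[:3, 3] = [origin[2], origin[1], origin[0]]
        # NIfTI-2: float64 affine, so grid geometry round-trips exactly
        nib.save(nib.Nifti2Image(np.ascontiguousarray(data.T), affine), str(path))
    else:
        sitk.WriteImage(_grid_to_sitk(data, spacing, origin), str(path))


def _read_volume(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise FormatError(f"{path}: only axis-aligned affines are supported")
        sp_xyz = np.diag(rot)
        if np.any(sp_xyz <= 0):
            raise FormatError(f"{path}: non-positive spacing in affine: {sp_xyz}")
        data = np.asarray(img.dataobj).T  # back to (slice, row, col)
        spacing = (float(sp_xyz[2]), float(sp_xyz[1]), float(sp_xyz[0]))
        origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
        return data, spacing, origin
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)
    spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
    origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: missing or non-positive spacing metadata")
    return data, spacing, origin


def write_mask(m: Mask3D, path) -> None:
    """Write a binary mask as an 8-bit 0/1 NIfTI (.nii/.nii.gz) or NRRD."""
    _write_volume(m.data.astype(np.uint8), m.spacing, m.origin, Path(path))


def read_mask(path) -> Mask3D:
    """Read a binary mask; rejects volumes with values other than 0/1."""
    data, spacing, origin = _read_volume(Path(path))
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        raise FormatError(
            f"{path}: mask is not binary (value range {data.min()}..{data.max()})"
        )
    return Mask3D(data.astype(bool), spacing, origin)


def write_dose(d: DoseGrid, path) -> None:
    """Write a dose grid (Gy) as a floating-point volume."""
    _write_volume(d.data.astype(np.float64), d.spacing, d.origin, Path(path))


def read_dose(path) -> DoseGrid:
    data, spacing, origin = _read_volume(Path(path))
    return DoseGrid(np.asarray(data, dtype=float), spacing, origin)


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT import (optional feature)
# ---------------------------------------------------------------------------

def import_dicom_rtstruct(path, reference: Mask3D) -> dict[str, Mask3D]:
    """Rasterise the closed planar contours of an RTSTRUCT onto a grid.

    Each contour polygon is filled slice-wise with a voxel-centre even-odd
    test (multiple polygons on one slice XOR together, so holes work).  Any
    contour whose geometric type is not CLOSED_PLANAR raises
    :class:`UnsupportedFeatureError` — never a silent skip.
    """
    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    out: dict[str, Mask3D] = {}
    nz, ny, nx = reference.shape
    sz, sy, sx = reference.spacing
    oz, oy, ox = reference.origin
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi_contour.ReferencedROINumber), str(roi_contour.ReferencedROINumber))
        data = np.zeros(reference.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            gtype = str(getattr(contour, "ContourGeometricType", ""))
            if gtype != "CLOSED_PLANAR":
                raise UnsupportedFeatureError(
                    f"ROI {name!r}: contour type {gtype!r} is not supported"
                )
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = pts[:, 2]
            if np.ptp(z) > 1e-3:
                raise UnsupportedFeatureError(f"ROI {name!r}: non-planar contour")
            k = (z[0] - oz) / sz
            ki = int(round(k))
            if abs(k - ki) > 0.5 or not (0 <= ki < nz):
                raise FormatError(
                    f"ROI {name!r}: contour plane z={z[0]:g} mm not on the reference grid"
                )
            poly_rc = np.column_stack(((pts[:, 1] - oy) / sy, (pts[:, 0] - ox) / sx))
            data[ki] ^= polygon2mask((ny, nx), poly_rc)
        out[name] = Mask3D(data, reference.spacing, reference.origin)
    return out


# ---------------------------------------------------------------------------
# run configuration + pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one benchmark pipeline run.

    ``mode='synthetic'`` generates the scripted cohort; ``mode='disk'`` reads
    gold and per-institution submissions from ``gold_dir``/``submissions_dir``
    (layout ``<inst>/round_<k>/<structure>.nii.gz`` plus optional
    ``dose.nii.gz`` per round).
    """

    output_dir: str = "rtqa_out"
    mode: str = "synthetic"
    n_institutions: int = 35
    seed: int = 0
    hd_percentile: float = 95.0
    dvh_bin_width_gy: float = 0.5
    rules_path: Optional[str] = None
    gold_dir: Optional[str] = None
    submissions_dir: Optional[str] = None
    dose_on_gold_contours: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.hd_percentile <= 100.0):
            raise ConfigError("hd_percentile must be in (0, 100]")
        if self.dvh_bin_width_gy <= 0:
            raise ConfigError("dvh_bin_width_gy must be positive")
        if self.mode not in ("synthetic", "disk"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _load_disk_submissions(config: RunConfig):
    if not config.gold_dir or not config.submissions_dir:
        raise ConfigError("disk mode requires gold_dir and submissions_dir")
    gold_dir = Path(config.gold_dir)
    gold = {
        p.name.split(".")[0]: read_mask(p)
        for p in sorted(gold_dir.iterdir())
        if p.suffix in (".nii", ".gz", ".nrrd")
    }
    submissions: dict[str, list[RoundInput]] = {}
    for inst_dir in sorted(Path(config.submissions_dir).iterdir()):
        if not inst_dir.is_dir():
            continue
        rounds = []
        for round_dir in sorted(inst_dir.glob("round_*")):
            structures = {}
            dose = None
            for p in sorted(round_dir.iterdir()):
                stem = p.name.split(".")[0]
                if stem == "dose":
                    dose = read_dose(p)
                elif p.suffix in (".nii", ".gz", ".nrrd"):
                    structures[stem] = read_mask(p)
            rounds.append(RoundInput(structures=structures, dose=dose))
        submissions[inst_dir.name] = rounds
    return gold, submissions


def write_report_files(report: CohortReport, output_dir) -> None:
    """Emit the cohort report: CSV tables plus a JSON summary.

    Display rounding (DSI 2 decimals, HD 0.1 mm, doses 0.01 Gy) is applied
    here only; the JSON summary keeps raw fractions.  Output is byte-stable
    for identical inputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rec_rows = [
        {
            "institution": r.institution_id,
            "round": r.round_number,
            "structure": r.structure_name,
            "criterion": r.criterion_id,
            "category": r.category,
            "severity": r.severity,
            "observed_value": "" if r.observed_value is None else round(r.observed_value, 3),
            "limit": r.limit or "",
        }
        for r in report.records
    ]
    pd.DataFrame(
        rec_rows,
        columns=["institution", "round", "structure", "criterion",
                 "category", "severity", "observed_value", "limit"],
    ).to_csv(out / "deviations.csv", index=False)

    paired = report.paired.copy()
    for c in paired.columns:
        if c.startswith("dsi"):
            paired[c] = paired[c].round(2)
        elif c.startswith("hd"):
            paired[c] = paired[c].round(1)
    paired.to_csv(out / "paired_first_final.csv", index=False)

    finals = report.finals.copy()
    for c in ("dsi_mean", "dsi_sd"):
        if c in finals:
            finals[c] = finals[c].round(2)
    for c in ("hd_mean", "hd_sd"):
        if c in finals:
            finals[c] = finals[c].round(1)
    finals.to_csv(out / "final_metrics.csv", index=False)

    doses = report.doses.copy()
    for c in ("mean_Gy", "sd_Gy"):
        if c in doses:
            doses[c] = doses[c].round(2)
    doses.to_csv(out / "dose_summary.csv", index=False)

    report.tally.to_frame().to_csv(out / "deviation_tally.csv", index=False)
    if report.metrics_long is not None:
        long_df = report.metrics_long.copy()
        long_df["value"] = long_df["value"].round(4)
        long_df.to_csv(out / "metrics_long.csv", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> CohortReport:
    """Evaluate → decide → dose-check → aggregate; write report files."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.rules_path:
        delineation_rules, constraint_rules = load_rules(config.rules_path)
    else:
        delineation_rules, constraint_rules = default_rules()
    if config.mode == "synthetic":
        cohort = make_cohort(config.n_institutions, seed=config.seed)
        gold, submissions = cohort.gold, cohort.submissions
    else:
        gold, submissions = _load_disk_submissions(config)
    histories = run_benchmark(
        submissions,
        gold,
        delineation_rules,
        constraint_rules,
        hd_percentile=config.hd_percentile,
        dose_on_gold_contours=config.dose_on_gold_contours,
    )
    report = build_report(histories, constraint_rules)
    write_report_files(report, config.output_dir)
    log.info(
        "benchmark complete: %d institutions, %d unacceptable deviations, %d%% resubmission",
        report.resubmissions.n_institutions,
        report.tally.total,
        report.resubmissions.percent,
    )
    return report
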