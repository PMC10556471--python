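"""Volume, manifest, and plan serialization.

Volumes travel as NIfTI (primary; NRRD accepted through SimpleITK when
installed) with a JSON manifest mapping structure names to mask files; plans
and reports are JSON.  Arrays are indexed (x, y, z) in the LPS patient frame
with the affine carrying spacing and origin, matching the in-memory grid, so
write/read round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import nibabel as nib

from .beams import Beam, FieldSet
from .dose import DoseGrid
from .planning import CompositePlan
from .precheck import CompatibilityReport, FieldConfig, MachineLimits
from .structures import DensityVolume, Grid, LabeledVolume

__all__ = ["save_volume", "load_volume", "save_phantom", "load_phantom",
           "beam_to_dict", "beam_from_dict", "fieldset_to_dict",
           "fieldset_from_dict", "report_to_dict", "save_plan"]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def save_volume(path: Path, values: np.ndarray, grid: Grid) -> None:
    path = Path(path)
    if path.suffix == ".nrrd":
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
        img.SetSpacing(tuple(float(s) for s in grid.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in grid.origin_mm))
        sitk.WriteImage(img, str(path))
        return
    nib.save(nib.Nifti1Image(np.asarray(values), _affine(grid)), str(path))


def load_volume(path: Path) -> Tuple[np.ndarray, Grid]:
    path = Path(path)
    if path.suffix == ".nrrd":
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).T
        grid = Grid(spacing_mm=tuple(img.GetSpacing()),
                    origin_mm=tuple(img.GetOrigin()), shape=arr.shape)
        return arr, grid
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    aff = img.affine
    grid = Grid(spacing_mm=(float(aff[0, 0]), float(aff[1, 1]), float(aff[2, 2])),
                origin_mm=tuple(float(v) for v in aff[:3, 3]), shape=arr.shape)
    return arr, grid


def save_phantom(density: DensityVolume, sv: LabeledVolume, outdir: Path,
                 fmt: str = "nii.gz") -> Path:
    """Write density + per-structure masks + manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    density_file = f"density.{fmt}"
    save_volume(outdir / density_file, density.values, density.grid)
    manifest = {
        "spacing_mm": list(density.grid.spacing_mm),
        "origin_mm": list(density.grid.origin_mm),
        "shape": list(density.grid.shape),
        "orientation": "LPS",
        "density": density_file,
        "structures": {},
    }
    for name in sorted(sv.names()):
        f = f"masks/{name}.{fmt}"
        save_volume(outdir / f, sv.get(name).astype(np.uint8), sv.grid)
        manifest["structures"][name] = f
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_phantom(manifest_path: Path) -> Tuple[DensityVolume, LabeledVolume]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    dens_arr, grid = load_volume(root / manifest["density"])
    masks: Dict[str, np.ndarray] = {}
    for name, rel in manifest["structures"].items():
        arr, g = load_volume(root / rel)
        if g.shape != grid.shape:
            raise ValueError(f"mask {name!r} grid differs from density grid")
        masks[name] = arr.astype(bool)
    return DensityVolume(grid, dens_arr), LabeledVolume(grid, masks)


def beam_to_dict(beam: Beam) -> dict:
    return {
        "label": beam.label,
        "gantry_deg": beam.gantry_deg,
        "collimator_deg": beam.collimator_deg,
        "couch_deg": beam.couch_deg,
        "isocenter_mm": list(beam.isocenter_mm),
        "sad_cm": beam.sad_cm,
        "ssd_setup_cm": beam.ssd_setup_cm,
        "jaws_cm": list(beam.jaws_cm),
        "leaf_width_cm": beam.leaf_width_cm,
        "mlc_y0_cm": beam.mlc_y0_cm,
        "mlc_left_cm": beam.mlc_left_cm.tolist(),
        "mlc_right_cm": beam.mlc_right_cm.tolist(),
        "energy_mv": beam.energy_mv,
        "weight": beam.weight,
    }


def beam_from_dict(d: dict) -> Beam:
    d = dict(d)
    d["isocenter_mm"] = tuple(d["isocenter_mm"])
    d["jaws_cm"] = tuple(d["jaws_cm"])
    d["mlc_left_cm"] = np.asarray(d["mlc_left_cm"])
    d["mlc_right_cm"] = np.asarray(d["mlc_right_cm"])
    return Beam(**d)


def fieldset_to_dict(fs: FieldSet) -> dict:
    return {
        "config": fs.config.value,
        "junction_z_mm": list(fs.junction_z_mm),
        "match_point_mm": list(fs.match_point_mm) if fs.match_point_mm else None,
        "brain_beams": [beam_to_dict(b) for b in fs.brain_beams],
        "spine_beams": [beam_to_dict(b) for b in fs.spine_beams],
        "spine_subfields": [beam_to_dict(b) for b in fs.spine_subfields],
    }


def fieldset_from_dict(d: dict) -> FieldSet:
    return FieldSet(
        brain_beams=[beam_from_dict(b) for b in d["brain_beams"]],
        spine_beams=[beam_from_dict(b) for b in d["spine_beams"]],
        spine_subfields=[beam_from_dict(b) for b in d["spine_subfields"]],
        junction_z_mm=list(d["junction_z_mm"]),
        config=FieldConfig(d["config"]),
        match_point_mm=tuple(d["match_point_mm"]) if d.get("match_point_mm") else None,
    )


def report_to_dict(report: CompatibilityReport) -> dict:
    return {
        "accepted": report.accepted,
        "junction_spacing_cm": report.junction_spacing_cm,
        "feather_ok": report.feather_ok,
        "half_beam_ok": report.half_beam_ok,
        "field_config": report.field_config.value,
        "reasons": list(report.reasons),
        "measurements": {
            "canal_length_cm": report.measurements.canal_length_cm,
            "brain_to_mandible_cm": report.measurements.brain_to_mandible_cm,
            "feather_space_cm": report.measurements.feather_space_cm,
        },
    }


def save_plan(plan: CompositePlan, outdir: Path, fmt: str = "nii.gz") -> Path:
    """Write the plan JSON (beams, weights, scalars) and the composite dose."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dose_file = f"composite_dose.{fmt}"
    save_volume(outdir / dose_file, plan.composite_dose.values, plan.composite_dose.grid)
    doc = {
        "prescription": {
            "total_dose_gy": plan.prescription.total_dose_gy,
            "n_fractions": plan.prescription.n_fractions,
            "feather_fractions": list(plan.prescription.feather_fractions),
        },
        "precheck": report_to_dict(plan.report),
        "fraction_weights": list(plan.fraction_weights),
        "normalization_scalars": plan.normalization_scalars,
        "subfield_weights": plan.subfield_weights,
        "optimizer_info": plan.optimizer_info,
        "composite_dose": dose_file,
        "sub_plans": [fieldset_to_dict(fs) for fs in plan.sub_plans],
    }
    path = outdir / "plan.json"
    path.write_text(json.dumps(doc, indent=2))
    return path
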