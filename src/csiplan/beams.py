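"""Treatment-field construction for craniospinal irradiation.

Builds the classical 3D-conformal CSI field arrangement: two opposed lateral
brain fields (gantry 90/270) with a half-beam block at the cranio-spinal
junction, matched to one posterior-anterior spine field (gantry 180) —
standard, extended-SSD, or two matched fields abutting just anterior to the
spinal canal — with MLC apertures conformed to a 1 cm uniform expansion of
the brain and a 1 cm lateral expansion of the spinal canal.

Geometry conventions (IEC 61217 angles, LPS patient frame, head-first
supine): gantry 0 enters anteriorly, 90 from the patient's left, 180
posteriorly; the couch is always 0 and all energies 6 MV.  Beam's-eye-view
(BEV) coordinates are measured in cm on the isocenter plane; BEV +y is
patient-superior at collimator 0, so jaw y2 is the superior jaw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .precheck import CompatibilityReport, FieldConfig, MachineLimits
from .structures import (Grid, LabeledVolume, expand_lateral, expand_uniform,
                         feather_interval_mm, mask_centroid_mm)

__all__ = [
    "Beam", "FieldSet", "BEVFootprint", "IsocenterPlan",
    "beam_axes", "project_points", "bev_project", "fit_mlc",
    "apply_half_beam_block", "match_divergence", "compute_field_gap",
    "place_isocenters", "build_fields",
]

BRAIN_MARGIN_CM = 1.0      # uniform expansion defining the brain aperture
SPINE_MARGIN_CM = 1.0      # lateral expansion defining the spine aperture
JAW_MARGIN_CM = 0.4        # penumbra clearance between footprint and jaws
MATCH_ANTERIOR_CM = 0.5    # spine-spine match point sits this far anterior to the canal


class PlanningError(RuntimeError):
    """Raised when field construction is attempted on incompatible anatomy."""


@dataclass(frozen=True, eq=False)
class Beam:
    """One treatment field.

    Jaw and leaf positions are cm on the isocenter plane; ``ssd_setup_cm``
    (extended fields) moves the source so the source-to-isocenter distance is
    the setup SSD instead of the SAD.  MLC leaves are stacked along BEV y
    starting at ``mlc_y0_cm`` and travel along BEV x.
    """

    label: str
    gantry_deg: float
    isocenter_mm: Tuple[float, float, float]
    jaws_cm: Tuple[float, float, float, float]  # (x1, x2, y1, y2)
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    sad_cm: float = 100.0
    ssd_setup_cm: Optional[float] = None
    leaf_width_cm: float = 0.5
    mlc_y0_cm: float = 0.0
    mlc_left_cm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mlc_right_cm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    energy_mv: float = 6.0
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "mlc_left_cm", np.asarray(self.mlc_left_cm, float))
        object.__setattr__(self, "mlc_right_cm", np.asarray(self.mlc_right_cm, float))
        x1, x2, y1, y2 = self.jaws_cm
        if x1 > x2 or y1 > y2:
            raise ValueError("jaws must satisfy x1 <= x2 and y1 <= y2")
        if self.couch_deg != 0.0:
            raise ValueError("couch rotations are not used (couch_deg must be 0)")
        if self.energy_mv != 6.0:
            raise ValueError("all beam energies are 6 MV")
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if self.mlc_left_cm.shape != self.mlc_right_cm.shape:
            raise ValueError("MLC banks must have equal leaf counts")
        if np.any(self.mlc_left_cm > self.mlc_right_cm + 1e-9):
            raise ValueError("each MLC pair must satisfy left <= right")

    @property
    def source_to_iso_cm(self) -> float:
        return self.ssd_setup_cm if self.ssd_setup_cm is not None else self.sad_cm

    @property
    def n_leaves(self) -> int:
        return self.mlc_left_cm.size

    def mlc_y_edges_cm(self) -> np.ndarray:
        return self.mlc_y0_cm + self.leaf_width_cm * np.arange(self.n_leaves + 1)

    def with_weight(self, weight: float) -> "Beam":
        return replace(self, weight=weight)


@dataclass
class FieldSet:
    """One sub-plan's fields: 2 brain laterals + 1-2 PA spine fields."""

    brain_beams: List[Beam]
    spine_beams: List[Beam]
    spine_subfields: List[Beam] = field(default_factory=list)
    junction_z_mm: List[float] = field(default_factory=list)
    config: FieldConfig = FieldConfig.SINGLE
    match_point_mm: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        gantries = sorted(b.gantry_deg for b in self.brain_beams)
        if gantries != [90.0, 270.0]:
            raise ValueError("brain beams must be the opposed laterals (gantry 90, 270)")
        if any(b.gantry_deg != 180.0 for b in self.spine_beams):
            raise ValueError("spine beams must be posterior-anterior (gantry 180)")

    def all_beams(self) -> List[Beam]:
        return [*self.brain_beams, *self.spine_beams, *self.spine_subfields]


@dataclass
class BEVFootprint:
    """Binary occupancy of a projected structure on the isocenter plane."""

    pixel_cm: float
    x0_cm: float            # center of pixel [0, :] along BEV x
    y0_cm: float            # center of pixel [:, 0] along BEV y
    occupancy: np.ndarray   # bool, indexed [ix, iy]

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        nx, ny = self.occupancy.shape
        return (self.x0_cm + self.pixel_cm * np.arange(nx),
                self.y0_cm + self.pixel_cm * np.arange(ny))


def beam_axes(beam: Beam) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Source position (mm) and the beam frame (axis b, BEV x u, BEV y v)."""
    g = math.radians(beam.gantry_deg)
    c = math.radians(beam.collimator_deg)
    src_dir = np.array([math.sin(g), -math.cos(g), 0.0])
    S = np.asarray(beam.isocenter_mm) + beam.source_to_iso_cm * 10.0 * src_dir
    b = -src_dir
    u0 = np.array([math.cos(g), math.sin(g), 0.0])
    v0 = np.array([0.0, 0.0, 1.0])
    u = math.cos(c) * u0 + math.sin(c) * v0
    v = -math.sin(c) * u0 + math.cos(c) * v0
    return S, b, u, v


def project_points(points_mm: np.ndarray, beam: Beam) -> np.ndarray:
    """Divergent projection of world points onto the isocenter plane (BEV cm)."""
    S, b, u, v = beam_axes(beam)
    w = np.atleast_2d(points_mm) - S
    depth = w @ b
    if np.any(depth <= 0):
        raise ValueError("points behind the source cannot be projected")
    t = beam.source_to_iso_cm * 10.0 / depth
    return np.stack([t * (w @ u), t * (w @ v)], axis=-1) / 10.0


def bev_project(mask: np.ndarray, grid: Grid, beam: Beam,
                pixel_cm: float = 0.1) -> BEVFootprint:
    """Project every voxel of a mask through the source onto the iso plane.

    Each voxel is splatted through its 8 corners so the footprint covers the
    full projected voxel extent (the aperture fitted to it covers the voxel).
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("cannot project an empty mask")
    centers = grid.world_coords(idx)
    half = np.asarray(grid.spacing_mm) / 2.0
    corners = np.stack([project_points(centers + np.array([dx, dy, dz]), beam)
                        for dx in (-half[0], half[0])
                        for dy in (-half[1], half[1])
                        for dz in (-half[2], half[2])])
    box_lo = corners.min(axis=0)   # (n, 2) per-voxel projected bounding boxes
    box_hi = corners.max(axis=0)
    lo = box_lo.min(axis=0) - pixel_cm
    hi = box_hi.max(axis=0) + pixel_cm
    nx = int(np.ceil((hi[0] - lo[0]) / pixel_cm)) + 2
    ny = int(np.ceil((hi[1] - lo[1]) / pixel_cm)) + 2
    i0 = np.clip(np.rint((box_lo[:, 0] - lo[0]) / pixel_cm).astype(int), 0, nx - 1)
    j0 = np.clip(np.rint((box_lo[:, 1] - lo[1]) / pixel_cm).astype(int), 0, ny - 1)
    i1 = np.clip(np.rint((box_hi[:, 0] - lo[0]) / pixel_cm).astype(int), 0, nx - 1)
    j1 = np.clip(np.rint((box_hi[:, 1] - lo[1]) / pixel_cm).astype(int), 0, ny - 1)
    # union of filled rectangles via a 2D difference array + cumulative sums
    acc = np.zeros((nx + 1, ny + 1), dtype=np.int64)
    np.add.at(acc, (i0, j0), 1)
    np.add.at(acc, (i0, j1 + 1), -1)
    np.add.at(acc, (i1 + 1, j0), -1)
    np.add.at(acc, (i1 + 1, j1 + 1), 1)
    occ = np.cumsum(np.cumsum(acc, axis=0), axis=1)[:nx, :ny] > 0
    return BEVFootprint(pixel_cm=pixel_cm, x0_cm=float(lo[0]), y0_cm=float(lo[1]),
                        occupancy=occ)


def fit_mlc(footprint: BEVFootprint, leaf_width_cm: float,
            jaws_cm: Tuple[float, float, float, float]) -> Tuple[float, np.ndarray, np.ndarray]:
    """Conform leaf pairs to a footprint: per-track min/max extents.

    Tracks containing no footprint (or lying outside the y jaws) are parked
    closed at the x1 jaw.  Returns (y0 of the first track, left bank, right
    bank), all cm at the isocenter plane.
    """
    if not footprint.occupancy.any():
        raise ValueError("cannot fit MLC to an empty footprint")
    x1, x2, y1, y2 = jaws_cm
    k_lo = int(np.floor(y1 / leaf_width_cm))
    k_hi = int(np.ceil(y2 / leaf_width_cm))
    n = max(k_hi - k_lo, 1)
    y0 = k_lo * leaf_width_cm
    left = np.full(n, float(x1))
    right = np.full(n, float(x1))

    xs, ys = footprint.pixel_centers()
    occ_ix, occ_iy = np.nonzero(footprint.occupancy)
    px, py = xs[occ_ix], ys[occ_iy]
    track = np.floor((py - y0) / leaf_width_cm).astype(int)
    ok = (track >= 0) & (track < n)
    track, px = track[ok], px[ok]
    half_px = footprint.pixel_cm / 2.0
    if track.size:
        lo = np.full(n, np.inf)
        hi = np.full(n, -np.inf)
        np.minimum.at(lo, track, px - half_px)
        np.maximum.at(hi, track, px + half_px)
        open_tracks = np.isfinite(lo) & (lo < hi)
        left[open_tracks] = lo[open_tracks]
        right[open_tracks] = hi[open_tracks]
    return y0, left, right


def apply_half_beam_block(beam: Beam, blocked_side: str = "inferior") -> Beam:
    """Close one y jaw exactly at the central axis (non-divergent junction edge).

    Only meaningful on the lateral brain fields; leaf tracks entirely on the
    blocked side are parked closed.
    """
    if beam.gantry_deg not in (90.0, 270.0):
        raise ValueError("half-beam block applies to the lateral brain fields only")
    x1, x2, y1, y2 = beam.jaws_cm
    edges = beam.mlc_y_edges_cm()
    left = beam.mlc_left_cm.copy()
    right = beam.mlc_right_cm.copy()
    if blocked_side == "inferior":
        jaws = (x1, x2, 0.0, y2)
        blocked = edges[1:] <= 1e-9
    elif blocked_side == "superior":
        jaws = (x1, x2, y1, 0.0)
        blocked = edges[:-1] >= -1e-9
    else:
        raise ValueError("blocked_side must be 'inferior' or 'superior'")
    left[blocked] = x1
    right[blocked] = x1
    return replace(beam, jaws_cm=jaws, mlc_left_cm=left, mlc_right_cm=right)


def match_divergence(spine_beam: Beam) -> float:
    """Collimator tilt (deg) matching the brain-field inferior edge to the
    diverging superior edge of the spine field.

    theta = atan(L_sup / SSD) with L_sup the spine field's superior
    half-length at the isocenter plane.
    """
    L_sup = max(spine_beam.jaws_cm[3], 0.0)
    return math.degrees(math.atan2(L_sup, spine_beam.source_to_iso_cm))


def compute_field_gap(upper: Beam, lower: Beam, match_depth_cm: float,
                      ssd1_cm: Optional[float] = None,
                      ssd2_cm: Optional[float] = None) -> float:
    """Skin gap G = (d/2) (L1/SSD1 + L2/SSD2) for abutment at depth d.

    L1, L2 are the field lengths; SSDs default to each beam's
    source-to-isocenter distance.
    """
    if match_depth_cm <= 0:
        raise ValueError("match_depth_cm must be > 0")
    L1 = upper.jaws_cm[3] - upper.jaws_cm[2]
    L2 = lower.jaws_cm[3] - lower.jaws_cm[2]
    s1 = ssd1_cm if ssd1_cm is not None else upper.source_to_iso_cm
    s2 = ssd2_cm if ssd2_cm is not None else lower.source_to_iso_cm
    return match_depth_cm / 2.0 * (L1 / s1 + L2 / s2)


@dataclass(frozen=True)
class IsocenterPlan:
    """Isocenter and junction placement derived from the structure set."""

    brain_iso_mm: Tuple[float, float, float]
    spine_iso_mm: List[Tuple[float, float, float]]
    junction_z_mm: List[float]
    match_point_mm: Optional[Tuple[float, float, float]]
    feather_interval_mm: Tuple[float, float]


def _canal_extent_mm(sv: LabeledVolume) -> Tuple[float, float]:
    canal = sv.require("spinal_canal")
    ks = np.flatnonzero(canal.any(axis=(0, 1)))
    zc = sv.grid.axis_coords(2)
    return float(zc[ks[0]]), float(zc[ks[-1]])


def place_isocenters(sv: LabeledVolume, report: CompatibilityReport,
                     limits: MachineLimits = MachineLimits(),
                     junction_offset_cm: float = 0.0) -> IsocenterPlan:
    """Place the brain/spine isocenters and the junction plane(s).

    The cranio-spinal junction starts at the midpoint of the mandible-shoulder
    feather interval minus one junction spacing, so both superior feathering
    shifts stay inside the measured space; the brain isocenter sits on that
    plane (half-beam matching).  For MULTIPLE, the spine-spine match point is
    placed just anterior to the canal at the mid-canal plane.
    """
    if not report.accepted:
        raise PlanningError("; ".join(report.reasons))
    s_mm = report.junction_spacing_cm * 10.0
    off = junction_offset_cm * 10.0
    lo, hi = feather_interval_mm(sv)
    z0_base = (lo + hi) / 2.0 - s_mm
    z0 = z0_base + off

    canal_lo, canal_hi = _canal_extent_mm(sv)
    canal_c = mask_centroid_mm(sv.require("spinal_canal"), sv.grid)
    brain_c = mask_centroid_mm(sv.require("brain"), sv.grid)
    # Brain iso y follows the spine axis so the divergence-matched edges share
    # one junction line; x stays on the brain midline.
    brain_iso = (float(brain_c[0]), float(canal_c[1]), float(z0))
    field_bot = canal_lo - 10.0   # 1 cm inferior aperture margin

    if report.field_config in (FieldConfig.SINGLE, FieldConfig.EXTENDED):
        iso_z = (z0 + field_bot) / 2.0
        return IsocenterPlan(
            brain_iso_mm=brain_iso,
            spine_iso_mm=[(float(canal_c[0]), float(canal_c[1]), float(iso_z))],
            junction_z_mm=[float(z0)],
            match_point_mm=None,
            feather_interval_mm=(lo, hi),
        )

    # every junction translates by the same feathering offset, so the
    # spine-spine match plane is derived from the unshifted geometry
    z_match = (z0_base + field_bot) / 2.0 + off
    canal = sv.require("spinal_canal")
    k_match = int(np.clip(round((z_match - sv.grid.origin_mm[2]) / sv.grid.spacing_mm[2]),
                          0, sv.grid.shape[2] - 1))
    slice_mask = canal[:, :, k_match]
    ys = sv.grid.axis_coords(1)
    y_anterior = float(ys[np.flatnonzero(slice_mask.any(axis=0))[0]])
    y_match = y_anterior - sv.grid.spacing_mm[1] / 2.0 - MATCH_ANTERIOR_CM * 10.0
    iso_u = (z0 + z_match) / 2.0
    iso_l = (z_match + field_bot) / 2.0
    return IsocenterPlan(
        brain_iso_mm=brain_iso,
        spine_iso_mm=[(float(canal_c[0]), float(canal_c[1]), float(iso_u)),
                      (float(canal_c[0]), float(canal_c[1]), float(iso_l))],
        junction_z_mm=[float(z0), float(z_match)],
        match_point_mm=(float(canal_c[0]), float(y_match), float(z_match)),
        feather_interval_mm=(lo, hi),
    )


def _fit_beam(label: str, gantry: float, iso: Tuple[float, float, float],
              target: np.ndarray, grid: Grid, limits: MachineLimits,
              collimator: float = 0.0, ssd_setup: Optional[float] = None,
              y_jaws: Optional[Tuple[float, float]] = None) -> Beam:
    """Project a target, derive jaws from its extents, and conform the MLC."""
    probe = Beam(label=label, gantry_deg=gantry, isocenter_mm=iso,
                 jaws_cm=(-20, 20, -25, 25), collimator_deg=collimator,
                 sad_cm=limits.sad_cm, ssd_setup_cm=ssd_setup,
                 leaf_width_cm=limits.leaf_width_at_iso_cm)
    fp = bev_project(target, grid, probe)
    xs, ys = fp.pixel_centers()
    occ_x = xs[fp.occupancy.any(axis=1)]
    occ_y = ys[fp.occupancy.any(axis=0)]
    x1 = float(occ_x.min() - JAW_MARGIN_CM)
    x2 = float(occ_x.max() + JAW_MARGIN_CM)
    if y_jaws is None:
        jy = (float(occ_y.min() - JAW_MARGIN_CM), float(occ_y.max() + JAW_MARGIN_CM))
    else:
        jy = y_jaws
    jaws = (x1, x2, jy[0], jy[1])
    y0, left, right = fit_mlc(fp, limits.leaf_width_at_iso_cm, jaws)
    return replace(probe, jaws_cm=jaws, mlc_y0_cm=y0,
                   mlc_left_cm=left, mlc_right_cm=right)


def build_fields(sv: LabeledVolume, report: CompatibilityReport,
                 limits: MachineLimits = MachineLimits(),
                 junction_offset_cm: float = 0.0) -> FieldSet:
    """Construct the full field arrangement for an accepted patient."""
    if not report.accepted:
        raise PlanningError("; ".join(report.reasons))
    plan = place_isocenters(sv, report, limits, junction_offset_cm)
    grid = sv.grid
    z0 = plan.junction_z_mm[0]

    spine_target = expand_lateral(sv.require("spinal_canal"), SPINE_MARGIN_CM,
                                  grid.spacing_mm[0])
    spine_beams: List[Beam] = []
    if report.field_config in (FieldConfig.SINGLE, FieldConfig.EXTENDED):
        iso = plan.spine_iso_mm[0]
        ssd = limits.extended_ssd_cm if report.field_config is FieldConfig.EXTENDED else None
        y2 = (z0 - iso[2]) / 10.0
        y1 = -y2
        spine_beams.append(_fit_beam("spine", 180.0, iso, spine_target, grid,
                                     limits, ssd_setup=ssd, y_jaws=(y1, y2)))
    else:
        z_match = plan.junction_z_mm[1]
        xm, ym, zm = plan.match_point_mm
        for label, iso, sup in (("spine_upper", plan.spine_iso_mm[0], True),
                                ("spine_lower", plan.spine_iso_mm[1], False)):
            dist_iso = limits.sad_cm * 10.0
            a = iso[1] - ym  # match point this far anterior of the iso plane
            edge = (zm - iso[2]) * dist_iso / (dist_iso + a) / 10.0
            if sup:
                y2 = (z0 - iso[2]) / 10.0
                y_jaws = (edge, y2)
            else:
                y1 = (_canal_extent_mm(sv)[0] - 10.0 - iso[2]) / 10.0
                y_jaws = (y1, edge)
            spine_beams.append(_fit_beam(label, 180.0, iso, spine_target, grid,
                                         limits, y_jaws=y_jaws))

    theta = match_divergence(spine_beams[0])
    brain_target = expand_uniform(sv.require("brain"), BRAIN_MARGIN_CM, grid.spacing_mm)
    brain_beams = []
    for label, gantry, sign in (("brain_L", 90.0, -1.0), ("brain_R", 270.0, 1.0)):
        beam = _fit_beam(label, gantry, plan.brain_iso_mm, brain_target, grid,
                         limits, collimator=sign * theta)
        beam = apply_half_beam_block(beam, "inferior")
        brain_beams.append(beam)

    return FieldSet(brain_beams=brain_beams, spine_beams=spine_beams,
                    junction_z_mm=list(plan.junction_z_mm),
                    config=report.field_config,
                    match_point_mm=plan.match_point_mm)
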