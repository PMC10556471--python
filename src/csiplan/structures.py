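"""Structure-set data model, anatomical measurements, and margin expansions.

Volumes live on a regular voxel grid in an LPS patient frame: ``x`` increases
toward the patient's left, ``y`` posteriorly, ``z`` superiorly (superior =
increasing slice index, head-first supine).  All world coordinates are in
millimetres; the measurement operations report centimetres, the unit the
planning rules are written in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "DensityVolume",
    "LabeledVolume",
    "AnatomicalMeasurements",
    "REQUIRED_STRUCTURES",
    "REVIEW_STRUCTURES",
    "canonical_name",
    "measure_spinal_canal_length",
    "measure_brain_to_mandible",
    "measure_feather_space",
    "expand_uniform",
    "expand_lateral",
]


class StructureError(KeyError):
    """A required structure is missing or empty."""


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: ``world = origin + index * spacing`` (mm, LPS)."""

    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float]
    shape: Tuple[int, int, int]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm: all spacings must be > 0")

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)


@dataclass
class DensityVolume:
    """Mass-density volume (g/cc) co-registered with the structure set."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError("density array shape does not match grid")


# The 15 structures the physicians review, plus the planning landmarks.
REVIEW_STRUCTURES = (
    "eyes", "lacrimal_glands", "lenses", "cribriform_plate", "optic_nerves",
    "pituitary", "cochleae", "brainstem", "mandible", "brain", "thyroid",
    "lungs", "heart", "kidneys", "spinal_canal",
)
REQUIRED_STRUCTURES = ("brain", "spinal_canal", "mandible", "shoulders", "body")

_SYNONYMS = {
    "cochlea": "cochleae",
    "eye": "eyes",
    "lens": "lenses",
    "optic_nerve": "optic_nerves",
    "lacrimal_gland": "lacrimal_glands",
    "lung": "lungs",
    "kidney": "kidneys",
    "shoulder": "shoulders",
    "vertebral_body": "vertebral_column",
    "spine_canal": "spinal_canal",
}


def canonical_name(name: str) -> str:
    """Normalize a structure name: case-insensitive, CamelCase/space tolerant."""
    s = re.sub(r"([a-z0-9])([A-Z])", r"\1_\2", name.strip())
    s = re.sub(r"[\s\-]+", "_", s).lower()
    return _SYNONYMS.get(s, s)


@dataclass
class LabeledVolume:
    """Named binary structure masks sharing one grid (the planning substrate)."""

    grid: Grid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        canon = {}
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} shape does not match grid")
            canon[canonical_name(name)] = mask
        self.masks = canon

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self.masks

    def get(self, name: str) -> np.ndarray:
        return self.masks[canonical_name(name)]

    def require(self, name: str) -> np.ndarray:
        """Fetch a mask, raising a descriptive error if missing or empty."""
        key = canonical_name(name)
        if key not in self.masks:
            raise StructureError(f"structure {key!r} missing from structure set")
        mask = self.masks[key]
        if not mask.any():
            raise StructureError(f"structure {key!r} is empty")
        return mask

    def names(self) -> Iterable[str]:
        return self.masks.keys()


@dataclass(frozen=True)
class AnatomicalMeasurements:
    """Pre-check measurements, all in cm and non-negative."""

    canal_length_cm: float
    brain_to_mandible_cm: float
    feather_space_cm: float

    def __post_init__(self):
        for f in ("canal_length_cm", "brain_to_mandible_cm", "feather_space_cm"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _z_slices(mask: np.ndarray) -> np.ndarray:
    """Indices of axial slices (axis 2) containing any mask voxel."""
    return np.flatnonzero(mask.any(axis=(0, 1)))


def measure_spinal_canal_length(sv: LabeledVolume) -> float:
    """Superior-inferior extent of the spinal canal in cm.

    Length counts whole occupied slices: a tube spanning slices ``a..b`` at
    slice thickness ``t`` measures ``(b - a + 1) * t``.
    """
    ks = _z_slices(sv.require("spinal_canal"))
    sz = sv.grid.spacing_mm[2]
    return (ks[-1] - ks[0] + 1) * sz / 10.0


def measure_brain_to_mandible(sv: LabeledVolume) -> float:
    """|z(top of brain) - z(bottom of mandible)| in cm (half-beam-block check)."""
    brain_top = _z_slices(sv.require("brain"))[-1]
    mand_bot = _z_slices(sv.require("mandible"))[0]
    sz = sv.grid.spacing_mm[2]
    return abs(brain_top - mand_bot) * sz / 10.0


def measure_feather_space(sv: LabeledVolume) -> float:
    """Longitudinal clearance between mandible bottom and shoulder top, cm.

    Returns 0 when the structures overlap longitudinally.
    """
    mand_bot = _z_slices(sv.require("mandible"))[0]
    shoulder_top = _z_slices(sv.require("shoulders"))[-1]
    sz = sv.grid.spacing_mm[2]
    return max(0.0, (mand_bot - shoulder_top) * sz / 10.0)


def feather_interval_mm(sv: LabeledVolume) -> Tuple[float, float]:
    """World-z interval (mm) between shoulder top and mandible bottom."""
    zc = sv.grid.axis_coords(2)
    mand_bot = zc[_z_slices(sv.require("mandible"))[0]]
    shoulder_top = zc[_z_slices(sv.require("shoulders"))[-1]]
    return (shoulder_top, mand_bot)


def expand_uniform(mask: np.ndarray, margin_cm: float,
                   spacing_mm: Tuple[float, float, float]) -> np.ndarray:
    """Isotropic 3D dilation by ``margin_cm``, spacing-aware.

    Voxels whose centers lie within the margin (ties included) of any input
    voxel center are set.  Computed with a Euclidean distance transform so
    anisotropic voxels are handled in mm space.
    """
    if margin_cm < 0:
        raise ValueError("margin_cm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_cm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= margin_cm * 10.0 + 1e-6


def expand_lateral(mask: np.ndarray, margin_cm: float, spacing_x_mm: float) -> np.ndarray:
    """Dilation along the patient left-right (x) axis only.

    Superior-inferior and anterior-posterior extents are unchanged; used for
    the 1 cm lateral expansion of the spinal canal that defines the spine
    field aperture.
    """
    if margin_cm < 0:
        raise ValueError("margin_cm must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    n = int(np.floor(margin_cm * 10.0 / spacing_x_mm + 1e-6))
    if n == 0 or not mask.any():
        return mask.copy()
    struct = np.ones((2 * n + 1, 1, 1), dtype=bool)
    return ndimage.binary_dilation(mask, structure=struct)


def mask_centroid_mm(mask: np.ndarray, grid: Grid) -> np.ndarray:
    """World-mm centroid of a binary mask."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise StructureError("cannot take centroid of empty mask")
    return grid.world_coords(idx.mean(axis=0))
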