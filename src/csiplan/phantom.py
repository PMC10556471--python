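"""Parametric pediatric whole-body phantoms for craniospinal planning.

The planner consumes only binary structure masks and a density volume, so the
phantom is built from stylized geometric primitives (ellipsoids, tubes,
boxes) on a regular LPS grid, head-first supine, superior = increasing slice
index.  The parameters that drive the anatomical pre-checks — spinal-canal
length, chin-tuck (head tilt), and the mandible-shoulder feathering gap — are
placed exactly so the measurement operations recover them to within one slice.

Densities are water-equivalent soft tissue (1.0 g/cc), lung 0.26, bone 1.6,
air 0; a contrast flag adds a small kidney density offset only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .structures import DensityVolume, Grid, LabeledVolume

__all__ = ["PhantomSpec", "generate_phantom", "sample_cohort",
           "expected_brain_to_mandible_cm", "DEFAULT_COHORT_RANGES"]

# Brain-top to mandible-bottom distance (cm) as a function of chin tuck.
# Zero tilt leaves ~13.5 cm of cranium above the jaw; each degree of tuck
# lowers the mandible 2.5 mm, so strong tilts push past the 20 cm half-beam cap.
_BRAIN_MANDIBLE_BASE_CM = 13.5
_BRAIN_MANDIBLE_PER_DEG = 0.25

_DENSITY = {"soft": 1.0, "lung": 0.26, "bone": 1.6, "air": 0.0, "contrast_kidney": 1.08}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient.

    ``slice_thickness_mm`` overrides the z component of ``voxel_spacing_mm``
    when given (CT slice spacing varies independently of in-plane spacing).
    """

    canal_length_cm: float = 30.0
    head_tilt_deg: float = 2.0
    mandible_shoulder_gap_cm: float = 2.5
    body_height_cm: Optional[float] = None
    voxel_spacing_mm: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    slice_thickness_mm: Optional[float] = None
    seed: int = 0
    include_contrast_kidneys: bool = False

    def __post_init__(self):
        if not (20.0 <= self.canal_length_cm <= 70.0):
            raise ValueError("canal_length_cm must be in [20, 70]")
        if not (0.0 <= self.head_tilt_deg <= 45.0):
            raise ValueError("head_tilt_deg must be in [0, 45]")
        if self.mandible_shoulder_gap_cm < 0:
            raise ValueError("mandible_shoulder_gap_cm must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm entries must be > 0")
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be > 0")
        if self.body_height_cm is not None and self.body_height_cm <= 0:
            raise ValueError("body_height_cm must be > 0")

    @property
    def spacing_mm(self) -> Tuple[float, float, float]:
        sx, sy, _ = self.voxel_spacing_mm
        sz = self.slice_thickness_mm or self.voxel_spacing_mm[2]
        return (sx, sy, sz)


def expected_brain_to_mandible_cm(spec: PhantomSpec) -> float:
    """Brain-top to mandible-bottom distance the phantom is built to have."""
    return _BRAIN_MANDIBLE_BASE_CM + _BRAIN_MANDIBLE_PER_DEG * spec.head_tilt_deg


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _cylinder_z(X, Y, Z, cx, cy, rx, ry, z0, z1) -> np.ndarray:
    return (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0) & (Z >= z0) & (Z <= z1)


def _box(X, Y, Z, center, half) -> np.ndarray:
    cx, cy, cz = center
    hx, hy, hz = half
    return (np.abs(X - cx) <= hx) & (np.abs(Y - cy) <= hy) & (np.abs(Z - cz) <= hz)


def _capsule(X, Y, Z, a, b, r) -> np.ndarray:
    """All points within radius r of segment a-b (used for the optic nerves)."""
    a = np.asarray(a, float)
    d = np.asarray(b, float) - a
    L2 = float(d @ d)
    t = ((X - a[0]) * d[0] + (Y - a[1]) * d[1] + (Z - a[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = ((X - a[0] - t * d[0]) ** 2 + (Y - a[1] - t * d[1]) ** 2
             + (Z - a[2] - t * d[2]) ** 2)
    return dist2 <= r * r


def generate_phantom(spec: PhantomSpec) -> Tuple[DensityVolume, LabeledVolume]:
    """Build the density volume and the 18-structure set for one spec.

    Deterministic: identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = (s / 10.0 for s in spec.spacing_mm)  # cm

    # --- longitudinal layout (cm; z = 0 at the mandible inferior edge) -----
    D = expected_brain_to_mandible_cm(spec)          # brain top - mandible bottom
    gap = spec.mandible_shoulder_gap_cm
    brain_top = D
    mand_bot = 0.0
    shoulder_top = mand_bot - gap
    canal_top = shoulder_top - 1.0
    canal_bot = canal_top - spec.canal_length_cm
    torso_bot = canal_bot - 4.0
    head_top = brain_top + 1.5
    if spec.body_height_cm is not None:
        torso_bot = min(torso_bot, head_top - spec.body_height_cm)

    # z voxel centers aligned so the mandible bottom lies exactly on a center:
    # edge quantization is then one-sided and parameter recovery stays within
    # one slice thickness.
    k_lo = -int(np.ceil((mand_bot - (torso_bot - 1.0)) / sz))
    k_hi = int(np.ceil((head_top + 1.0 - mand_bot) / sz))
    zc = mand_bot + sz * np.arange(k_lo, k_hi + 1)

    half_x, half_y = 17.2, 11.5
    nx = 2 * int(np.floor(half_x / sx)) + 1
    ny = 2 * int(np.floor(half_y / sy)) + 1
    xc = sx * (np.arange(nx) - (nx - 1) / 2)
    yc = sy * (np.arange(ny) - (ny - 1) / 2)

    grid = Grid(spacing_mm=tuple(spec.spacing_mm),
                origin_mm=(float(xc[0] * 10), float(yc[0] * 10), float(zc[0] * 10)),
                shape=(nx, ny, zc.size))
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]

    def jit(n=3, amp=0.15):
        return rng.uniform(-amp, amp, size=n)

    m: Dict[str, np.ndarray] = {}

    # --- body envelope -----------------------------------------------------
    head = _ellipsoid(X, Y, Z, (0, -0.5, brain_top - 7.25), (7.0, 8.5, 8.75))
    neck = _cylinder_z(X, Y, Z, 0, 0, 5.0, 6.0, shoulder_top - 1.0, brain_top - 9.0)
    torso = _cylinder_z(X, Y, Z, 0, 0, 16.0, 10.0, torso_bot, shoulder_top + 1.0)
    body = head | neck | torso
    m["body"] = body

    # --- cranial structures ------------------------------------------------
    # The brain stays >= ~1.2 cm under the scalp so no brain voxel sits in the
    # lateral-field build-up region (the coverage normalization would
    # otherwise chase a grazing surface voxel).
    m["brain"] = _ellipsoid(X, Y, Z, (0, -0.5, brain_top - 6.25), (5.5, 7.0, 6.25))
    # flat clipped bottom: the inferior edge is a full cross-section exactly at
    # mand_bot, so the measured edge is one-sided on any slice grid
    m["mandible"] = (_ellipsoid(X, Y, Z, (0, -5.6, mand_bot + 1.2), (4.0, 1.6, 1.7))
                     & (Z >= mand_bot) & ~m["brain"])
    ez = brain_top - 11.0
    eye_c = [(-2.8, -6.6, ez) + jit(amp=0.1), (2.8, -6.6, ez) + jit(amp=0.1)]
    m["eyes"] = (_ellipsoid(X, Y, Z, eye_c[0], (1.2,) * 3)
                 | _ellipsoid(X, Y, Z, eye_c[1], (1.2,) * 3))
    m["lenses"] = (_ellipsoid(X, Y, Z, (eye_c[0][0], eye_c[0][1] - 0.8, eye_c[0][2]), (0.45,) * 3)
                   | _ellipsoid(X, Y, Z, (eye_c[1][0], eye_c[1][1] - 0.8, eye_c[1][2]), (0.45,) * 3))
    m["optic_nerves"] = (_capsule(X, Y, Z, (eye_c[0][0] + 0.2, eye_c[0][1] + 1.0, ez),
                                  (-1.2, -2.0, ez), 0.25)
                         | _capsule(X, Y, Z, (eye_c[1][0] - 0.2, eye_c[1][1] + 1.0, ez),
                                    (1.2, -2.0, ez), 0.25))
    m["lacrimal_glands"] = (_ellipsoid(X, Y, Z, (-3.9, -6.2, ez + 0.9) + jit(amp=0.1), (0.6,) * 3)
                            | _ellipsoid(X, Y, Z, (3.9, -6.2, ez + 0.9) + jit(amp=0.1), (0.6,) * 3))
    m["cochleae"] = (_ellipsoid(X, Y, Z, (-5.0, 0.7, ez + 0.3) + jit(amp=0.08), (0.4,) * 3)
                     | _ellipsoid(X, Y, Z, (5.0, 0.7, ez + 0.3) + jit(amp=0.08), (0.4,) * 3))
    m["pituitary"] = _ellipsoid(X, Y, Z, (0, -1.0, brain_top - 11.5) + jit(amp=0.08), (0.5,) * 3)
    m["cribriform_plate"] = _box(X, Y, Z, (0, -4.0, brain_top - 11.0), (1.5, 0.7, 0.35))

    # --- spine and junction region -----------------------------------------
    canal = _cylinder_z(X, Y, Z, 0, 2.5, 0.8, 0.8, canal_bot, canal_top)
    m["spinal_canal"] = canal
    m["vertebral_column"] = (_cylinder_z(X, Y, Z, 0, 2.9, 1.9, 2.2,
                                         canal_bot - 1.0, canal_top + 1.0) & ~canal)
    m["brainstem"] = _cylinder_z(X, Y, Z, 0, 1.0, 0.9, 0.9, canal_top, brain_top - 10.5)
    m["shoulders"] = (_box(X, Y, Z, (-9.75, 0, shoulder_top - 1.5), (5.25, 8.0, 1.5))
                      | _box(X, Y, Z, (9.75, 0, shoulder_top - 1.5), (5.25, 8.0, 1.5)))
    m["thyroid"] = _ellipsoid(X, Y, Z, (0, -3.2, shoulder_top + 1.4) + jit(amp=0.1),
                              (1.8, 0.9, 1.2))

    # --- thorax and abdomen ------------------------------------------------
    lung_z = shoulder_top - 10.0
    m["lungs"] = (_ellipsoid(X, Y, Z, (-7.5, 1.5, lung_z) + jit(), (5.5, 5.5, 8.5))
                  | _ellipsoid(X, Y, Z, (7.5, 1.5, lung_z) + jit(), (5.5, 5.5, 8.5)))
    m["heart"] = _ellipsoid(X, Y, Z, (1.5, -4.8, shoulder_top - 13.0) + jit(), (4.5, 4.2, 5.0))
    kid_z = canal_bot + 6.0
    m["kidneys"] = (_ellipsoid(X, Y, Z, (-5.5, 4.3, kid_z) + jit(), (2.6, 2.0, 4.2))
                    | _ellipsoid(X, Y, Z, (5.5, 4.3, kid_z) + jit(), (2.6, 2.0, 4.2)))

    for name in list(m):
        if name != "body":
            m[name] &= body

    # --- density -----------------------------------------------------------
    rho = np.zeros(grid.shape, dtype=np.float32)
    rho[body] = _DENSITY["soft"]
    rho[m["lungs"]] = _DENSITY["lung"]
    rho[m["vertebral_column"] | m["mandible"]] = _DENSITY["bone"]
    if spec.include_contrast_kidneys:
        rho[m["kidneys"]] = _DENSITY["contrast_kidney"]

    return DensityVolume(grid, rho), LabeledVolume(grid, m)


DEFAULT_COHORT_RANGES: Dict[str, Tuple[float, float]] = {
    "canal_length_cm": (25.0, 60.0),
    "head_tilt_deg": (0.0, 15.0),
    "mandible_shoulder_gap_cm": (1.0, 4.0),
    "slice_thickness_mm": (1.0, 3.0),
}


def sample_cohort(n: int, ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                  seed: int = 0) -> list:
    """Draw ``n`` phantom specs with parameters uniform within ``ranges``.

    Unspecified parameters use :data:`DEFAULT_COHORT_RANGES`; each spec gets
    its own derived seed so phantoms differ while the cohort is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eff = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        eff.update(ranges)
    for name, (lo, hi) in eff.items():
        if lo > hi:
            raise ValueError(f"range for {name!r} is ill-ordered: {lo} > {hi}")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        draw = {name: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                for name, (lo, hi) in eff.items()}
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        specs.append(PhantomSpec(seed=child_seed, **draw))
    return specs
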