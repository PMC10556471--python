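"""DVH computation and the quantitative plan-quality report.

Target coverage is quantified with V95 (% of structure volume receiving at
least 95% of the 23.4 Gy prescription) for the brain, spinal canal and
cribriform plate; normal-tissue dose with the maximum dose (brain, spinal
canal, brainstem, cochleae, eyes, lenses, optic nerves) and the mean dose
(cochleae, heart, kidneys, lacrimal glands, lungs, pituitary, thyroid), plus
the body volume of the 107% hotspot.  Dmax is the point maximum over mask
voxels (no small-volume smoothing) and the V95 threshold is inclusive, so the
normalization target is exactly attainable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .dose import DoseGrid
from .planning import CompositePlan, Prescription
from .structures import LabeledVolume

__all__ = ["DVHCurve", "PlanReport", "compute_dvh", "v_at", "d_max", "d_mean",
           "hotspot_volume", "evaluate_plan",
           "V95_STRUCTURES", "DMAX_STRUCTURES", "DMEAN_STRUCTURES"]

log = logging.getLogger(__name__)

V95_STRUCTURES = ("brain", "spinal_canal", "cribriform_plate")
DMAX_STRUCTURES = ("brain", "spinal_canal", "brainstem", "cochleae", "eyes",
                   "lenses", "optic_nerves")
DMEAN_STRUCTURES = ("cochleae", "heart", "kidneys", "lacrimal_glands", "lungs",
                    "pituitary", "thyroid")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``volume_fraction[i]`` is the fraction of the structure receiving at
    least ``dose_gy[i]``; the curve starts at 1.0 at zero dose and is
    monotone non-increasing.
    """

    structure: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def v_at(self, dose_gy: float) -> float:
        """Volume percentage at >= dose_gy, read from the curve bins."""
        i = int(np.searchsorted(self.dose_gy, dose_gy, side="right")) - 1
        i = max(i, 0)
        return float(self.volume_fraction[i] * 100.0)


def compute_dvh(dose: DoseGrid, mask: np.ndarray, structure: str = "",
                bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH over mask voxels (volume-weighted by the voxel volume)."""
    vals = dose.values[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError(f"empty mask for DVH of {structure or 'structure'!r}")
    top = float(vals.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    srt = np.sort(vals)
    at_least = 1.0 - np.searchsorted(srt, edges, side="left") / vals.size
    at_least[0] = 1.0
    return DVHCurve(structure=structure, dose_gy=edges, volume_fraction=at_least)


def v_at(dose: DoseGrid, mask: np.ndarray, threshold_gy: float) -> float:
    """Percent of structure volume receiving >= threshold (inclusive)."""
    vals = dose.values[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(np.mean(vals >= threshold_gy) * 100.0)


def d_max(dose: DoseGrid, mask: np.ndarray) -> float:
    vals = dose.values[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.max())


def d_mean(dose: DoseGrid, mask: np.ndarray) -> float:
    vals = dose.values[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean())


def hotspot_volume(dose: DoseGrid, rx_gy: float, level_pct: float = 107.0,
                   mask: Optional[np.ndarray] = None) -> float:
    """Volume (cc) receiving at least ``level_pct`` % of the prescription."""
    region = dose.values if mask is None else dose.values[np.asarray(mask, bool)]
    n = int(np.count_nonzero(region >= level_pct / 100.0 * rx_gy))
    return n * dose.grid.voxel_volume_cc


@dataclass
class PlanReport:
    """The quantitative evaluation panel of one composite plan."""

    rx_gy: float
    v95_pct: Dict[str, float] = field(default_factory=dict)
    dmax_gy: Dict[str, float] = field(default_factory=dict)
    dmean_gy: Dict[str, float] = field(default_factory=dict)
    hotspot_107_cc: float = 0.0
    missing_structures: list = field(default_factory=list)

    def dmax_pct(self, name: str) -> float:
        return self.dmax_gy[name] / self.rx_gy * 100.0

    def dmean_pct(self, name: str) -> float:
        return self.dmean_gy[name] / self.rx_gy * 100.0

    def to_dict(self) -> dict:
        return {
            "rx_gy": self.rx_gy,
            "v95_pct": self.v95_pct,
            "dmax_gy": self.dmax_gy,
            "dmax_pct": {k: self.dmax_pct(k) for k in self.dmax_gy},
            "dmean_gy": self.dmean_gy,
            "dmean_pct": {k: self.dmean_pct(k) for k in self.dmean_gy},
            "hotspot_107_cc": self.hotspot_107_cc,
            "missing_structures": self.missing_structures,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_markdown(self) -> str:
        lines = [f"| structure | V95 (%) | Dmax (Gy) | Dmean (Gy) |",
                 f"|---|---|---|---|"]
        names = sorted(set(self.v95_pct) | set(self.dmax_gy) | set(self.dmean_gy))
        for n in names:
            v = f"{self.v95_pct[n]:.1f}" if n in self.v95_pct else ""
            dx = f"{self.dmax_gy[n]:.2f}" if n in self.dmax_gy else ""
            dm = f"{self.dmean_gy[n]:.2f}" if n in self.dmean_gy else ""
            lines.append(f"| {n} | {v} | {dx} | {dm} |")
        lines.append(f"| 107% hotspot | {self.hotspot_107_cc:.1f} cc | | |")
        return "\n".join(lines)


def evaluate_plan(plan: CompositePlan, sv: LabeledVolume,
                  rx: Optional[Prescription] = None) -> PlanReport:
    """Fill the full metric panel from the composite dose.

    Structures absent from the set are recorded as missing with a warning
    rather than failing the whole report.
    """
    rx = rx or plan.prescription
    dose = plan.composite_dose
    report = PlanReport(rx_gy=rx.total_dose_gy)
    thr = rx.threshold_gy

    def have(name):
        if name in sv and sv.get(name).any():
            return True
        if name not in report.missing_structures:
            report.missing_structures.append(name)
            log.warning("structure %r missing from structure set; metric skipped", name)
        return False

    for name in V95_STRUCTURES:
        if have(name):
            report.v95_pct[name] = v_at(dose, sv.get(name), thr)
    for name in DMAX_STRUCTURES:
        if have(name):
            report.dmax_gy[name] = d_max(dose, sv.get(name))
    for name in DMEAN_STRUCTURES:
        if have(name):
            report.dmean_gy[name] = d_mean(dose, sv.get(name))
    body = sv.get("body") if "body" in sv else None
    report.hotspot_107_cc = hotspot_volume(dose, rx.total_dose_gy, 107.0, body)
    return report


def dvh_panel(plan: CompositePlan, sv: LabeledVolume,
              structures: Optional[Sequence[str]] = None,
              bin_width_gy: float = 0.1) -> Dict[str, DVHCurve]:
    """DVH curves for the evaluation structures present in the set."""
    names = structures or sorted(set(V95_STRUCTURES) | set(DMAX_STRUCTURES)
                                 | set(DMEAN_STRUCTURES))
    out = {}
    for n in names:
        if n in sv and sv.get(n).any():
            out[n] = compute_dvh(plan.composite_dose, sv.get(n), n, bin_width_gy)
    return out


def dvh_to_csv(curves: Dict[str, DVHCurve]) -> str:
    """Long-format CSV (structure, dose_gy, volume_fraction)."""
    rows = ["structure,dose_gy,volume_fraction"]
    for name, c in curves.items():
        for d, f in zip(c.dose_gy, c.volume_fraction):
            rows.append(f"{name},{d:.3f},{f:.6f}")
    return "\n".join(rows)
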