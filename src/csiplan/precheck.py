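"""Anatomical compatibility checks and spine field-configuration selection.

Three rules run before any planning:

* junction spacing — feathering shifts the junction twice by the spacing
  ``s``, so the shifts span ``2 s`` of the mandible-shoulder gap: a gap of
  at least 2 cm supports a 1 cm junction, [1, 2) cm a 0.5 cm junction, and
  below 1 cm the patient is flagged and rejected;
* half-beam block — the lateral brain fields carry a half-beam block, which
  caps the brain-top to mandible-bottom distance at 20 cm (strictly larger
  is rejected);
* field configuration — the spinal canal length selects a single PA spine
  field, an extended-SSD field, or two matched fields.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .structures import (AnatomicalMeasurements, LabeledVolume,
                         measure_brain_to_mandible, measure_feather_space,
                         measure_spinal_canal_length)

__all__ = ["FieldConfig", "MachineLimits", "CompatibilityReport",
           "determine_junction_spacing", "check_half_beam",
           "select_field_config", "run_precheck",
           "HALF_BEAM_MAX_CM", "MIN_FEATHER_SPACE_CM"]

#: Brain-to-mandible cap for the half-beam block (rejection is strict >).
HALF_BEAM_MAX_CM = 20.0
#: Feathering needs at least this much mandible-shoulder clearance (strict <1 flag).
MIN_FEATHER_SPACE_CM = 1.0


class FieldConfig(str, enum.Enum):
    SINGLE = "SINGLE"
    EXTENDED = "EXTENDED"
    MULTIPLE = "MULTIPLE"


@dataclass(frozen=True)
class MachineLimits:
    """Treatment-machine geometry the configuration thresholds derive from."""

    max_field_len_at_iso_cm: float = 36.0
    sad_cm: float = 100.0
    extended_ssd_cm: float = 120.0
    leaf_width_at_iso_cm: float = 0.5

    def __post_init__(self):
        for f in ("max_field_len_at_iso_cm", "sad_cm", "extended_ssd_cm",
                  "leaf_width_at_iso_cm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if self.extended_ssd_cm < self.sad_cm:
            raise ValueError("extended_ssd_cm must be >= sad_cm")


@dataclass(frozen=True)
class CompatibilityReport:
    junction_spacing_cm: Optional[float]     # 1.0, 0.5, or None when rejected
    feather_ok: bool
    half_beam_ok: bool
    field_config: FieldConfig
    reasons: Tuple[str, ...]
    measurements: AnatomicalMeasurements

    @property
    def accepted(self) -> bool:
        return not self.reasons


def determine_junction_spacing(feather_space_cm: float) -> Tuple[Optional[float], Optional[str]]:
    """Map the feathering gap to a junction spacing, or a rejection reason.

    Two superior shifts of ``s`` span ``2 s``, so 1 cm spacing needs >= 2 cm
    of gap and 0.5 cm spacing needs >= 1 cm; the printed flag is strict
    (< 1 cm rejects, exactly 1 cm gets the 0.5 cm junction).
    """
    if feather_space_cm < 0:
        raise ValueError("feather_space_cm must be >= 0")
    if feather_space_cm >= 2.0:
        return 1.0, None
    if feather_space_cm >= MIN_FEATHER_SPACE_CM:
        return 0.5, None
    return None, (f"feathering space {feather_space_cm:.1f} cm between mandible and "
                  f"shoulders is below the {MIN_FEATHER_SPACE_CM:.0f} cm minimum")


def check_half_beam(brain_to_mandible_cm: float) -> Tuple[bool, Optional[str]]:
    """Pass iff the brain-to-mandible distance is <= 20 cm (strictly larger fails)."""
    if brain_to_mandible_cm < 0:
        raise ValueError("brain_to_mandible_cm must be >= 0")
    if brain_to_mandible_cm <= HALF_BEAM_MAX_CM:
        return True, None
    return False, (f"brain-to-mandible distance {brain_to_mandible_cm:.1f} cm exceeds "
                   f"the {HALF_BEAM_MAX_CM:.0f} cm half-beam block limit on the brain field")


def select_field_config(canal_length_cm: float,
                        limits: MachineLimits = MachineLimits()) -> FieldConfig:
    """Choose SINGLE / EXTENDED / MULTIPLE from the canal length.

    One field at nominal SAD covers up to the machine's maximum field length;
    the extended-SSD setup magnifies that by ``extended_ssd / sad``; anything
    longer needs two matched fields.
    """
    if canal_length_cm <= 0:
        raise ValueError("canal_length_cm must be > 0")
    L1 = limits.max_field_len_at_iso_cm
    if canal_length_cm <= L1:
        return FieldConfig.SINGLE
    if canal_length_cm <= L1 * limits.extended_ssd_cm / limits.sad_cm:
        return FieldConfig.EXTENDED
    return FieldConfig.MULTIPLE


def run_precheck(sv: LabeledVolume,
                 limits: MachineLimits = MachineLimits()) -> CompatibilityReport:
    """Aggregate the three pre-planning checks into one report.

    Pure function of the structure set: the reasons list is empty iff plan
    generation may proceed.
    """
    meas = AnatomicalMeasurements(
        canal_length_cm=measure_spinal_canal_length(sv),
        brain_to_mandible_cm=measure_brain_to_mandible(sv),
        feather_space_cm=measure_feather_space(sv),
    )
    reasons: List[str] = []
    spacing, why = determine_junction_spacing(meas.feather_space_cm)
    if why:
        reasons.append(why)
    half_ok, why = check_half_beam(meas.brain_to_mandible_cm)
    if why:
        reasons.append(why)
    config = select_field_config(meas.canal_length_cm, limits)
    return CompatibilityReport(
        junction_spacing_cm=spacing,
        feather_ok=spacing is not None,
        half_beam_ok=half_ok,
        field_config=config,
        reasons=tuple(reasons),
        measurements=meas,
    )
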