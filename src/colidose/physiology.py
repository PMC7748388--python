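"""Anthropometric and renal-function derivations.

Two quantities feed the dosing engine: ideal body weight (Devine formula),
used for the loading dose, and creatinine clearance (Cockcroft-Gault), used
to select the maintenance daily dose.  Both are deterministic closed forms.

Cockcroft-Gault is applied to actual body weight — the weight the clinician
enters — in its canonical form

    CrCl (mL/min) = (140 - age) * weight_kg / (72 * SCr_mg_dL)   [* 0.85 female]

with the result floored at zero.  No alternative GFR estimator (CKD-EPI,
MDRD) is offered: the dose bands were derived against Cockcroft-Gault.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .units import ValidationError

__all__ = [
    "Sex",
    "PatientDemographics",
    "CrClResult",
    "DEFAULT_AGE_BAND",
    "IBW_FLOOR_HEIGHT_IN",
    "ideal_body_weight",
    "creatinine_clearance",
    "creatinine_mg_dl",
]

DEFAULT_AGE_BAND = (18.0, 120.0)

#: below 5 feet the Devine line extrapolates downward; IBW is floored at the
#: sex-specific base constant instead
IBW_FLOOR_HEIGHT_IN = 60.0

UMOL_L_PER_MG_DL = 88.4


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


def _require_positive(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or not math.isfinite(value) or value <= 0:
        raise ValidationError(name, f"must be a positive number, got {value!r}")


@dataclass(frozen=True)
class PatientDemographics:
    """Validated adult patient demographics in canonical units.

    Heights are inches, weights kilograms, serum creatinine mg/dL; use
    :func:`colidose.units.normalize_length` / ``normalize_mass`` /
    :func:`creatinine_mg_dl` to convert other input units first.
    """

    sex: Sex
    age: float
    height_in: float
    weight_kg: float
    serum_creatinine: float
    age_band: tuple[float, float] = field(default=DEFAULT_AGE_BAND, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            raise ValidationError("sex", f"must be Sex.MALE or Sex.FEMALE, got {self.sex!r}")
        _require_positive("age", self.age)
        _require_positive("height_in", self.height_in)
        _require_positive("weight_kg", self.weight_kg)
        _require_positive("serum_creatinine", self.serum_creatinine)
        lo, hi = self.age_band
        if not (lo <= self.age <= hi):
            raise ValidationError(
                "age", f"{self.age} outside plausibility band [{lo}, {hi}] years (adult dosing only)"
            )


class CrClResult(NamedTuple):
    """Creatinine clearance with a flag for the age-driven floor at zero."""

    ml_min: float
    clamped: bool


def ideal_body_weight(sex: Sex, height_in: float) -> float:
    """Devine ideal body weight in kg.

    50 kg (males) or 45.5 kg (females) plus 2.3 kg per inch over 60 inches.
    For heights below 60 inches the value is floored at the sex-specific base
    constant rather than extrapolated downward.
    """
    sex = Sex(sex)
    _require_positive("height_in", height_in)
    base = 50.0 if sex is Sex.MALE else 45.5
    return base + 2.3 * max(height_in - 60.0, 0.0)


def creatinine_mg_dl(value: float, unit: str = "mg_dl") -> float:
    """Serum creatinine in mg/dL; accepts ``"mg_dl"`` or ``"umol_l"``."""
    _require_positive("serum_creatinine", value)
    if unit == "mg_dl":
        return float(value)
    if unit == "umol_l":
        return value / UMOL_L_PER_MG_DL
    raise ValidationError("serum_creatinine_unit", f"unknown unit {unit!r}")


def creatinine_clearance(demo: PatientDemographics) -> CrClResult:
    """Cockcroft-Gault creatinine clearance (mL/min), never negative.

    Ages at or above 140 years would drive the (140 - age) term non-positive;
    the estimate is clamped to 0 and flagged rather than raising, since
    end-stage renal inputs are clinically real.
    """
    raw = (140.0 - demo.age) * demo.weight_kg / (72.0 * demo.serum_creatinine)
    if demo.sex is Sex.FEMALE:
        raw *= 0.85
    if raw <= 0.0:
        return CrClResult(0.0, True)
    return CrClResult(raw, False)
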