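"""Dose and anthropometric unit handling.

Colistimethate doses are labelled in three conventions that clinicians mix at
their peril: milligrams of colistin base activity (mg CBA, North America),
million international units (MIU, Europe/Asia), and milligrams of the prodrug
colistimethate sodium itself (mg CMS, chemical mass).  The fixed equivalence
used throughout this package is

    1 million IU == 33.3 mg CBA == 80 mg CMS

pinned as exact constants so that conversions are reproducible and round-trip
losslessly.  All engine arithmetic runs in mg CBA; other units appear only at
input/output boundaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "DoseUnit",
    "LengthUnit",
    "MassUnit",
    "DoseAmount",
    "ValidationError",
    "MG_CBA_PER_MIU",
    "MG_CMS_PER_MIU",
    "CM_PER_INCH",
    "KG_PER_LB",
    "convert_dose",
    "dual_unit_render",
    "normalize_length",
    "normalize_mass",
    "round_mg",
]

MG_CBA_PER_MIU = 33.3
MG_CMS_PER_MIU = 80.0

# international yard-and-pound definitions
CM_PER_INCH = 2.54
KG_PER_LB = 0.45359237


class ValidationError(ValueError):
    """An input failed validation; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DoseUnit(str, enum.Enum):
    MG_CBA = "mg_cba"
    MIU = "miu"
    MG_CMS = "mg_cms"


class LengthUnit(str, enum.Enum):
    INCH = "in"
    CM = "cm"


class MassUnit(str, enum.Enum):
    LB = "lb"
    KG = "kg"


# mg-CBA value of one unit of each dose convention
_TO_MG_CBA = {
    DoseUnit.MG_CBA: 1.0,
    DoseUnit.MIU: MG_CBA_PER_MIU,
    DoseUnit.MG_CMS: MG_CBA_PER_MIU / MG_CMS_PER_MIU,
}


@dataclass(frozen=True)
class DoseAmount:
    """A non-negative drug quantity with an explicit dose unit."""

    value: float
    unit: DoseUnit

    def __post_init__(self) -> None:
        if not isinstance(self.unit, DoseUnit):
            raise ValidationError("unit", f"must be a DoseUnit, got {self.unit!r}")
        if not math.isfinite(self.value):
            raise ValidationError("value", f"must be finite, got {self.value!r}")
        if self.value < 0:
            raise ValidationError("value", f"must be non-negative, got {self.value!r}")


def convert_dose(amount: DoseAmount, target_unit: DoseUnit) -> DoseAmount:
    """Express *amount* in *target_unit* using the pinned equivalence.

    Conversion is performed on the unrounded value; rounding is a display
    concern (see :func:`dual_unit_render`).  Converting to the same unit is
    the identity.
    """
    target_unit = DoseUnit(target_unit)
    if amount.unit is target_unit:
        return amount
    mg_cba = amount.value * _TO_MG_CBA[amount.unit]
    return DoseAmount(mg_cba / _TO_MG_CBA[target_unit], target_unit)


def round_mg(value: float) -> int:
    """Round a milligram dose to the nearest whole mg, halves up."""
    return int(math.floor(value + 0.5))


def dual_unit_render(amount: DoseAmount) -> str:
    """Render a dose in both mg CBA and million IU, e.g. ``300 mg CBA (9.0 million IU)``.

    mg CBA is shown to the nearest whole milligram; MIU to one decimal place,
    so the 300 mg CBA ceiling renders as exactly 9.0 million IU.
    """
    cba = convert_dose(amount, DoseUnit.MG_CBA).value
    miu = convert_dose(amount, DoseUnit.MIU).value
    return f"{round_mg(cba)} mg CBA ({miu:.1f} million IU)"


def normalize_length(height: float, unit: LengthUnit) -> float:
    """Return a body height in inches, converting from cm when needed."""
    unit = LengthUnit(unit)
    if not math.isfinite(height) or height <= 0:
        raise ValidationError("height", f"must be a positive number, got {height!r}")
    if unit is LengthUnit.CM:
        return height / CM_PER_INCH
    return float(height)


def normalize_mass(weight: float, unit: MassUnit) -> float:
    """Return a body weight in kilograms, converting from pounds when needed."""
    unit = MassUnit(unit)
    if not math.isfinite(weight) or weight <= 0:
        raise ValidationError("weight", f"must be a positive number, got {weight!r}")
    if unit is MassUnit.LB:
        return weight * KG_PER_LB
    return float(weight)
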