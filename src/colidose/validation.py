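"""Mock-patient generation and the independent manual-calculation oracle.

The dosing engine is validated the way the shipped calculator was: doses for
a panel of synthetic patients are recomputed by an independently written
straight-line pass over the same published equations ("manual calculation"),
and the two are required to agree within a rounding tolerance of 0.5 mg CBA.
The default panel mirrors the original validation design — 8 patients, 2 on
each of IHD, SLED and CRRT and 2 on no RRT — and arbitrarily large random
panels can be generated for property testing.

The oracle in :func:`oracle_dose` deliberately shares no code with the
engine: it re-derives ideal body weight, Cockcroft-Gault clearance, the band
lookup, the 10%-per-hour supplement and the 300 mg cap as one flat
arithmetic pass at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dosing import (
    CSS_GRID,
    DosingModelConfig,
    RenalReplacement,
    RRTMode,
    daily_recommendation,
    loading_dose,
)
from .physiology import PatientDemographics, Sex, ideal_body_weight
from .units import ValidationError

__all__ = [
    "MockPatient",
    "MockPatientPanel",
    "ValidationReport",
    "DEFAULT_TOLERANCE_MG",
    "generate_panel",
    "oracle_dose",
    "run_validation",
]

#: engine-vs-oracle agreement tolerance, mg CBA ("minor differences being due
#: to number rounding")
DEFAULT_TOLERANCE_MG = 0.5

#: default 8-patient design: 2 patients on each RRT type, 2 on none
DEFAULT_DESIGN = (
    RRTMode.NONE, RRTMode.NONE,
    RRTMode.IHD, RRTMode.IHD,
    RRTMode.SLED, RRTMode.SLED,
    RRTMode.CRRT, RRTMode.CRRT,
)

# plausible adult sampling ranges for the generator
AGE_RANGE = (18.0, 90.0)
HEIGHT_RANGE_IN = (55.0, 78.0)
WEIGHT_RANGE_KG = (40.0, 150.0)
SCR_RANGE_MG_DL = (0.4, 8.0)
IHD_HOURS_RANGE = (2.0, 5.0)
SLED_HOURS_RANGE = (6.0, 12.0)
CRRT_HOURS = 24.0


class MockPatient(NamedTuple):
    demographics: PatientDemographics
    css: float
    rrt: RenalReplacement


@dataclass(frozen=True)
class MockPatientPanel:
    seed: int
    patients: tuple[MockPatient, ...]


class ValidationReport(NamedTuple):
    table: pd.DataFrame
    passed: bool
    tolerance_mg: float


def _sample_rrt(mode: RRTMode, rng: np.random.Generator) -> RenalReplacement:
    if mode is RRTMode.NONE:
        return RenalReplacement(RRTMode.NONE)
    if mode is RRTMode.IHD:
        # alternate printed session lengths; half the panel on a dialysis day
        return RenalReplacement(
            RRTMode.IHD,
            session_hours=float(rng.choice(IHD_HOURS_RANGE)),
            dialysis_day=bool(rng.integers(0, 2)),
        )
    if mode is RRTMode.SLED:
        return RenalReplacement(RRTMode.SLED, session_hours=float(rng.uniform(*SLED_HOURS_RANGE)))
    return RenalReplacement(RRTMode.CRRT, session_hours=CRRT_HOURS)


def generate_panel(
    seed: int,
    n: int = 8,
    design: Sequence[RRTMode] | None = None,
) -> MockPatientPanel:
    """Deterministically generate *n* synthetic adult patients.

    Demographics are drawn uniformly from plausible adult ranges (age 18-90 y,
    height 55-78 in, weight 40-150 kg, serum creatinine 0.4-8 mg/dL) and the
    target Css,avg from the selectable grid.  ``design`` fixes the RRT mode of
    each patient; the default for n=8 is 2 patients per RRT type and 2 on
    none, other sizes draw modes uniformly.  Identical seeds yield identical
    panels.
    """
    if not isinstance(n, int) or n < 1:
        raise ValidationError("n", f"panel size must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed)
    if design is None:
        if n == len(DEFAULT_DESIGN):
            design = DEFAULT_DESIGN
        else:
            modes = [m.value for m in RRTMode]
            design = tuple(RRTMode(str(m)) for m in rng.choice(modes, size=n))
    elif len(design) != n:
        raise ValidationError("design", f"design length {len(design)} != n {n}")
    patients = []
    for mode in design:
        demo = PatientDemographics(
            sex=Sex.MALE if rng.integers(0, 2) else Sex.FEMALE,
            age=float(rng.uniform(*AGE_RANGE)),
            height_in=float(rng.uniform(*HEIGHT_RANGE_IN)),
            weight_kg=float(rng.uniform(*WEIGHT_RANGE_KG)),
            serum_creatinine=float(rng.uniform(*SCR_RANGE_MG_DL)),
        )
        css = float(rng.choice(CSS_GRID))
        patients.append(MockPatient(demo, css, _sample_rrt(RRTMode(mode), rng)))
    return MockPatientPanel(seed=seed, patients=tuple(patients))


def oracle_dose(patient: MockPatient, model: DosingModelConfig) -> tuple[float, float]:
    """Manual-calculation oracle: ``(loading mg CBA, daily total mg CBA)``.

    One independent arithmetic pass over the published equations, full
    precision, no intermediate rounding, no engine code.
    """
    demo, css, rrt = patient

    # Devine IBW, floored at the base constant below 5 feet
    base = 50.0 if demo.sex is Sex.MALE else 45.5
    ibw = base + 2.3 * (demo.height_in - 60.0) if demo.height_in > 60.0 else base
    loading = min(css * 2.0 * ibw, model.max_daily_cba)

    # Cockcroft-Gault on actual body weight, floored at zero
    crcl = (140.0 - demo.age) * demo.weight_kg / (72.0 * demo.serum_creatinine)
    if demo.sex is Sex.FEMALE:
        crcl *= 0.85
    crcl = max(crcl, 0.0)

    # band lookup / knot interpolation
    if model.interpolate:
        xs = [b for b, _ in model.bands]
        ys = [d for _, d in model.bands]
        per_css = float(np.interp(crcl, xs, ys))
    else:
        per_css = model.bands[-1][1]
        for bound, dose in model.bands:
            if crcl < bound:
                per_css = dose
                break
    baseline = css * per_css

    # 10% of baseline per hour of dialysis (IHD dialysis day, SLED, CRRT)
    if rrt.mode in (RRTMode.SLED, RRTMode.CRRT) or (rrt.mode is RRTMode.IHD and rrt.dialysis_day):
        supplement = 0.10 * rrt.session_hours * baseline
    else:
        supplement = 0.0
    daily = min(baseline + supplement, model.max_daily_cba)
    return loading, daily


def run_validation(
    panel: MockPatientPanel,
    model: DosingModelConfig,
    tolerance_mg: float = DEFAULT_TOLERANCE_MG,
    oracle: Callable[[MockPatient, DosingModelConfig], tuple[float, float]] = oracle_dose,
) -> ValidationReport:
    """Engine-vs-oracle comparison table for every patient in the panel.

    Each row holds the engine and oracle loading and daily doses and their
    absolute differences; the report passes when every difference is within
    ``tolerance_mg`` (default 0.5 mg CBA).  ``oracle`` is injectable so the
    sensitivity of the harness itself can be exercised.
    """
    rows = []
    for i, patient in enumerate(panel.patients, start=1):
        demo, css, rrt = patient
        engine_loading = loading_dose(css, ideal_body_weight(demo.sex, demo.height_in),
                                      max_daily_cba=model.max_daily_cba).capped_cba
        engine_daily = daily_recommendation(demo, css, rrt, model).capped_cba
        oracle_loading, oracle_daily = oracle(patient, model)
        rows.append({
            "patient": i,
            "sex": demo.sex.value,
            "age": demo.age,
            "height_in": demo.height_in,
            "weight_kg": demo.weight_kg,
            "scr_mg_dl": demo.serum_creatinine,
            "css_mg_l": css,
            "rrt_mode": rrt.mode.value,
            "engine_loading_cba": engine_loading,
            "oracle_loading_cba": oracle_loading,
            "engine_daily_cba": engine_daily,
            "oracle_daily_cba": oracle_daily,
            "abs_diff_loading": abs(engine_loading - oracle_loading),
            "abs_diff_daily": abs(engine_daily - oracle_daily),
        })
    table = pd.DataFrame(rows)
    passed = bool(
        (table["abs_diff_loading"] <= tolerance_mg).all()
        and (table["abs_diff_daily"] <= tolerance_mg).all()
    )
    return ValidationReport(table=table, passed=passed, tolerance_mg=tolerance_mg)
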