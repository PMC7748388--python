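"""Core dosing algorithm for intravenous colistimethate.

The regimen has two parts, both expressed in mg of colistin base activity
(CBA) and targeting an average steady-state plasma colistin concentration
Css,avg chosen from a 0.5-4.0 mg/L grid (default 2.0 mg/L):

* loading dose (all patients):  ``CBA (mg) = Css,avg * 2.0 * IBW (kg)``
* maintenance daily dose: ``Css,avg * f(CrCl)`` where ``f`` is a configured
  CrCl-banded table of mg CBA/day per 1 mg/L of target (the published
  population-PK dosing table by default), plus a renal-replacement-therapy
  supplement of 10% of the baseline daily dose per hour of dialysis
  (IHD on a dialysis day, SLED, CRRT).

Either dose is capped at 300 mg CBA/day (9.0 million IU) with an
"Immediate Attention" warning; the uncapped value is retained for
transparency.  Daily doses are administered 12-hourly, the first regular
daily dose 12 hours after the loading dose.  The engine is fully
deterministic; doses are rounded to whole mg CBA only at display time and
then converted to million IU.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .physiology import PatientDemographics, creatinine_clearance, ideal_body_weight
from .units import DoseAmount, DoseUnit, ValidationError, dual_unit_render, round_mg

__all__ = [
    "CSS_GRID",
    "CSS_DEFAULT",
    "MAX_DAILY_CBA",
    "RRTMode",
    "RenalReplacement",
    "DosingModelConfig",
    "ConfigError",
    "DoseKind",
    "DoseRecommendation",
    "validate_css",
    "loading_dose",
    "baseline_daily_dose",
    "rrt_supplement",
    "daily_recommendation",
    "load_model_config",
    "default_model",
    "CAP_WARNING_HEADER",
    "CRRT_REMINDER",
    "SLED_REMINDER",
    "IHD_TIMING_NOTE",
    "LOADING_TIMING_NOTE",
]

#: selectable target Css,avg grid (mg/L): 0.5 to 4.0 in steps of 0.5
CSS_GRID = tuple(0.5 * k for k in range(1, 9))
CSS_DEFAULT = 2.0

#: maximum recommended loading or daily dose, mg CBA (= 9.0 million IU)
MAX_DAILY_CBA = 300.0

CAP_WARNING_HEADER = "Immediate Attention"
CRRT_REMINDER = "During CRRT, add 10% per 1 hour of CRRT to the baseline daily dose"
SLED_REMINDER = "During SLED, add 10% per 1 hour of SLED to the baseline daily dose"
IHD_TIMING_NOTE = "Add the supplemental dose after the dialysis session"
LOADING_TIMING_NOTE = (
    "Administer the first regular daily dose 12 hours after the loading dose"
)

#: fraction of the baseline daily dose supplemented per hour of dialysis
RRT_SUPPLEMENT_PER_HOUR = 0.10

#: printed IHD session lengths; other durations get the same 10%/h rule plus
#: a warning that they fall outside the studied range
IHD_STUDIED_HOURS = (2.0, 5.0)


class ConfigError(ValueError):
    """A dosing-model configuration is structurally invalid."""


class DoseKind(str, enum.Enum):
    LOADING = "loading"
    DAILY = "daily"


class RRTMode(str, enum.Enum):
    NONE = "none"
    IHD = "ihd"
    SLED = "sled"
    CRRT = "crrt"


def validate_css(value: float | None = None) -> float:
    """Validate a target Css,avg against the 0.5-4.0 mg/L step-0.5 grid.

    ``None`` yields the default of 2.0 mg/L.  Off-grid values raise a
    validation error listing the allowed values.
    """
    if value is None:
        return CSS_DEFAULT
    if any(math.isclose(value, g, rel_tol=0.0, abs_tol=1e-9) for g in CSS_GRID):
        return float(value)
    allowed = ", ".join(f"{g:g}" for g in CSS_GRID)
    raise ValidationError(
        "css", f"{value!r} is not a selectable target Css,avg; allowed values (mg/L): {allowed}"
    )


@dataclass(frozen=True)
class RenalReplacement:
    """Renal replacement therapy status.

    ``dialysis_day`` is meaningful for IHD only: on a non-dialysis day an IHD
    patient receives the baseline daily dose with no supplement.
    """

    mode: RRTMode = RRTMode.NONE
    session_hours: float = 0.0
    dialysis_day: bool = False

    def __post_init__(self) -> None:
        mode = RRTMode(self.mode)
        object.__setattr__(self, "mode", mode)
        h = self.session_hours
        if not isinstance(h, (int, float)) or not math.isfinite(h) or h < 0:
            raise ValidationError("session_hours", f"must be a non-negative number, got {h!r}")
        if mode is RRTMode.NONE and h != 0:
            raise ValidationError("session_hours", "must be 0 when no RRT is selected")
        if h == 0 and (mode in (RRTMode.SLED, RRTMode.CRRT) or (mode is RRTMode.IHD and self.dialysis_day)):
            raise ValidationError(
                "session_hours", f"must be positive for {mode.value} when a supplement applies"
            )

    @property
    def supplemented(self) -> bool:
        """Whether this RRT status earns a supplement on top of the baseline."""
        if self.mode in (RRTMode.SLED, RRTMode.CRRT):
            return True
        return self.mode is RRTMode.IHD and self.dialysis_day


@dataclass(frozen=True)
class DosingModelConfig:
    """CrCl-banded maintenance-dose table: mg CBA/day per 1 mg/L of target Css,avg.

    ``bands`` is an ordered sequence of ``(crcl_upper_bound, dose_per_unit_css)``
    pairs.  With ``interpolate=False`` (default) each band applies to
    ``CrCl < upper_bound`` (the last bound must be ``inf``); with
    ``interpolate=True`` the pairs are knots of a piecewise-linear function of
    CrCl, clamped flat outside the knot range.  Structure is validated here,
    at load time, so dosing calls never see a malformed table.
    """

    name: str
    bands: tuple[tuple[float, float], ...]
    interpolate: bool = False
    max_daily_cba: float = MAX_DAILY_CBA

    def __post_init__(self) -> None:
        if not (isinstance(self.max_daily_cba, (int, float)) and self.max_daily_cba > 0):
            raise ConfigError(f"max_daily_cba must be positive, got {self.max_daily_cba!r}")
        bands = tuple((float(b), float(d)) for b, d in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ConfigError("band table is empty")
        bounds = [b for b, _ in bands]
        doses = [d for _, d in bands]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigError(f"CrCl bounds must be strictly increasing, got {bounds}")
        if any(d < 0 for d in doses):
            raise ConfigError("dose_per_unit_css values must be non-negative")
        if any(d2 < d1 for d1, d2 in zip(doses, doses[1:])):
            raise ConfigError(
                f"dose_per_unit_css must be non-decreasing in CrCl, got {doses}"
            )
        if not self.interpolate:
            if bounds[0] <= 0:
                raise ConfigError("first CrCl upper bound must be positive")
            if not math.isinf(bounds[-1]):
                raise ConfigError(
                    "band table must cover CrCl in [0, inf): last upper bound must be inf"
                )
        else:
            if bounds[0] < 0 or math.isinf(bounds[-1]):
                raise ConfigError("interpolation knots must be finite and non-negative")

    def dose_per_unit_css(self, crcl: float) -> float:
        """mg CBA/day per 1 mg/L of target Css,avg at the given CrCl (mL/min)."""
        if not (isinstance(crcl, (int, float)) and math.isfinite(crcl) and crcl >= 0):
            raise ValidationError("crcl", f"must be a finite non-negative number, got {crcl!r}")
        if self.interpolate:
            bounds = [b for b, _ in self.bands]
            doses = [d for _, d in self.bands]
            if crcl <= bounds[0]:
                return doses[0]
            if crcl >= bounds[-1]:
                return doses[-1]
            for (x1, y1), (x2, y2) in zip(self.bands, self.bands[1:]):
                if x1 <= crcl <= x2:
                    return y1 + (y2 - y1) * (crcl - x1) / (x2 - x1)
            raise AssertionError("unreachable: knots cover the clamped range")
        for bound, dose in self.bands:
            if crcl < bound:
                return dose
        return self.bands[-1][1]


@dataclass(frozen=True)
class DoseRecommendation:
    """A computed loading or daily regimen, all amounts in mg CBA.

    ``total_cba`` is the pre-cap total (baseline + supplement for daily
    doses); ``capped_cba`` is the amount actually administered.  Amounts are
    kept at full precision; whole-mg rounding happens in rendering.
    """

    kind: DoseKind
    uncapped_cba: float
    capped_cba: float
    supplement_cba: float
    total_cba: float
    capped: bool
    per_12h_cba: float | None = None
    baseline_cba: float | None = None
    crcl_ml_min: float | None = None
    warnings: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert math.isclose(self.capped_cba, min(self.uncapped_cba, self.capped_cba))
        if self.capped:
            assert any(CAP_WARNING_HEADER in w for w in self.warnings)

    @property
    def rendered(self) -> str:
        """Administered dose in both units, e.g. ``292 mg CBA (8.8 million IU)``."""
        return dual_unit_render(DoseAmount(self.capped_cba, DoseUnit.MG_CBA))

    @property
    def per_12h_rendered(self) -> str | None:
        if self.per_12h_cba is None:
            return None
        return dual_unit_render(DoseAmount(self.per_12h_cba, DoseUnit.MG_CBA))

    def to_dict(self) -> dict:
        """JSON-serializable snapshot (used by the history store and --json)."""
        return {
            "kind": self.kind.value,
            "uncapped_cba": self.uncapped_cba,
            "capped_cba": self.capped_cba,
            "supplement_cba": self.supplement_cba,
            "total_cba": self.total_cba,
            "capped": self.capped,
            "per_12h_cba": self.per_12h_cba,
            "baseline_cba": self.baseline_cba,
            "crcl_ml_min": self.crcl_ml_min,
            "warnings": list(self.warnings),
            "notes": list(self.notes),
            "rendered": self.rendered,
        }


def _cap(uncapped: float, max_daily: float) -> tuple[float, bool, list[str]]:
    if uncapped > max_daily:
        warning = (
            f"{CAP_WARNING_HEADER}: calculated dose "
            f"{dual_unit_render(DoseAmount(uncapped, DoseUnit.MG_CBA))} exceeds the maximum "
            f"recommended {dual_unit_render(DoseAmount(max_daily, DoseUnit.MG_CBA))} and has "
            "been capped due to safety considerations"
        )
        return max_daily, True, [warning]
    return uncapped, False, []


def loading_dose(
    css: float, ibw_kg: float, *, max_daily_cba: float = MAX_DAILY_CBA
) -> DoseRecommendation:
    """Loading dose: ``Css,avg * 2.0 * IBW``, capped at the safety ceiling.

    Parameters
    ----------
    css : target Css,avg in mg/L, one of the 0.5-4.0 grid values.
    ibw_kg : Devine ideal body weight in kg (see :func:`ideal_body_weight`).
    """
    css = validate_css(css)
    if not (isinstance(ibw_kg, (int, float)) and math.isfinite(ibw_kg) and ibw_kg > 0):
        raise ValidationError("ibw_kg", f"must be a positive number, got {ibw_kg!r}")
    uncapped = css * 2.0 * ibw_kg
    capped, was_capped, warnings = _cap(uncapped, max_daily_cba)
    return DoseRecommendation(
        kind=DoseKind.LOADING,
        uncapped_cba=uncapped,
        capped_cba=capped,
        supplement_cba=0.0,
        total_cba=uncapped,
        capped=was_capped,
        warnings=tuple(warnings),
        notes=(LOADING_TIMING_NOTE,),
    )


def baseline_daily_dose(css: float, crcl: float, model: DosingModelConfig) -> float:
    """Baseline maintenance daily dose (mg CBA/day): ``Css,avg * f(CrCl)``.

    This is the pre-cap baseline that RRT supplements are computed against.
    """
    css = validate_css(css)
    return css * model.dose_per_unit_css(crcl)


def rrt_supplement(baseline_cba: float, rrt: RenalReplacement) -> tuple[float, list[str], list[str]]:
    """Supplemental dose for renal replacement therapy.

    Returns ``(supplement_mg_cba, warnings, notes)``.  The single rule is 10%
    of the baseline daily dose per hour of dialysis, which reproduces the
    published 2 h IHD -> 20% and 5 h IHD -> 50% points and the SLED/CRRT
    10%-per-hour rule.  No supplement without RRT or on an IHD non-dialysis
    day.
    """
    if not (isinstance(baseline_cba, (int, float)) and math.isfinite(baseline_cba) and baseline_cba >= 0):
        raise ValidationError("baseline_cba", f"must be non-negative, got {baseline_cba!r}")
    warnings: list[str] = []
    notes: list[str] = []
    if not rrt.supplemented:
        if rrt.mode is RRTMode.IHD:
            notes.append("Non-dialysis day of IHD: baseline daily dose only, no supplement")
        return 0.0, warnings, notes
    supplement = RRT_SUPPLEMENT_PER_HOUR * rrt.session_hours * baseline_cba
    if rrt.mode is RRTMode.IHD:
        notes.append(IHD_TIMING_NOTE)
        lo, hi = IHD_STUDIED_HOURS
        if not (lo <= rrt.session_hours <= hi):
            warnings.append(
                f"IHD session of {rrt.session_hours:g} h is outside the studied "
                f"{lo:g}-{hi:g} h range; the 10% per hour rule is extrapolated"
            )
    elif rrt.mode is RRTMode.SLED:
        notes.append(SLED_REMINDER)
    elif rrt.mode is RRTMode.CRRT:
        notes.append(CRRT_REMINDER)
    return supplement, warnings, notes


def daily_recommendation(
    demo: PatientDemographics,
    css: float,
    rrt: RenalReplacement,
    model: DosingModelConfig,
) -> DoseRecommendation:
    """Full maintenance-dose pipeline.

    CrCl (Cockcroft-Gault) -> baseline daily dose from the model's band table
    -> RRT supplement -> safety cap on the total -> 12-hourly split.  The
    per-12 h amount is half the capped total; whole-mg rounding is applied at
    display time, after which values are converted to million IU.
    """
    css = validate_css(css)
    warnings: list[str] = []
    notes: list[str] = []
    crcl = creatinine_clearance(demo)
    if crcl.clamped:
        warnings.append(
            "Cockcroft-Gault estimate clamped to 0 mL/min (age at or above 140 years)"
        )
    baseline = baseline_daily_dose(css, crcl.ml_min, model)
    supplement, supp_warnings, supp_notes = rrt_supplement(baseline, rrt)
    warnings.extend(supp_warnings)
    notes.extend(supp_notes)
    total = baseline + supplement
    capped, was_capped, cap_warnings = _cap(total, model.max_daily_cba)
    warnings.extend(cap_warnings)
    return DoseRecommendation(
        kind=DoseKind.DAILY,
        uncapped_cba=total,
        capped_cba=capped,
        supplement_cba=supplement,
        total_cba=total,
        capped=was_capped,
        per_12h_cba=capped / 2.0,
        baseline_cba=baseline,
        crcl_ml_min=crcl.ml_min,
        warnings=tuple(warnings),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# model-config I/O

def _config_from_mapping(data: dict, source: str) -> DosingModelConfig:
    try:
        raw_bands = data["bands"]
    except (KeyError, TypeError):
        raise ConfigError(f"{source}: missing 'bands' table") from None
    bands: list[tuple[float, float]] = []
    for entry in raw_bands:
        try:
            if isinstance(entry, dict):
                bound = entry["crcl_upper"]
                dose = entry["dose_per_unit_css"]
            else:
                bound, dose = entry
        except (KeyError, TypeError, ValueError):
            raise ConfigError(f"{source}: malformed band entry {entry!r}") from None
        if bound is None or (isinstance(bound, str) and bound.lower() in ("inf", ".inf")):
            bound = math.inf
        bands.append((float(bound), float(dose)))
    try:
        return DosingModelConfig(
            name=str(data.get("name", source)),
            bands=tuple(bands),
            interpolate=bool(data.get("interpolate", False)),
            max_daily_cba=float(data.get("max_daily_cba", MAX_DAILY_CBA)),
        )
    except ConfigError as exc:
        raise ConfigError(f"{source}: {exc}") from None


def load_model_config(path: str | Path) -> DosingModelConfig:
    """Load and schema-validate a YAML or JSON dosing-model config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _config_from_mapping(data, str(path))


def default_model() -> DosingModelConfig:
    """The bundled default maintenance-dose table (2017 population-PK guidance)."""
    text = resources.files("colidose.data").joinpath("nation2017.yaml").read_text()
    return _config_from_mapping(yaml.safe_load(text), "nation2017")
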