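"""Loading dose, maintenance baseline, RRT supplements, cap and schedule."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from colidose.dosing import (
    CAP_WARNING_HEADER,
    CRRT_REMINDER,
    CSS_GRID,
    SLED_REMINDER,
    ConfigError,
    DosingModelConfig,
    RenalReplacement,
    RRTMode,
    baseline_daily_dose,
    daily_recommendation,
    default_model,
    load_model_config,
    loading_dose,
    rrt_supplement,
    validate_css,
)
from colidose.physiology import PatientDemographics, Sex
from colidose.units import ValidationError

baselines = st.floats(min_value=1.0, max_value=400.0, allow_nan=False)


def demo(age=40.0, weight=72.0, scr=1.0, sex=Sex.MALE):
    return PatientDemographics(
        sex=sex, age=age, height_in=70.0, weight_kg=weight, serum_creatinine=scr
    )


# --- target-concentration grid ------------------------------------------------

def test_css_grid_default_and_bounds():
    assert validate_css(None) == 2.0
    assert CSS_GRID == (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    for value in CSS_GRID:
        assert validate_css(value) == value


@pytest.mark.parametrize("bad", [4.5, 1.25, 0.0, -2.0, 0.4999])
def test_css_off_grid_rejected_listing_allowed_values(bad):
    with pytest.raises(ValidationError, match="0.5"):
        validate_css(bad)


# --- loading dose -------------------------------------------------------------

@pytest.mark.parametrize(
    "css, ibw, expected",
    [(2.0, 73.0, 292.0), (0.5, 45.5, 45.5), (1.0, 50.0, 100.0)],
)
def test_loading_dose_equation(css, ibw, expected):
    rec = loading_dose(css, ibw)
    assert rec.capped_cba == pytest.approx(expected)
    assert not rec.capped
    assert rec.supplement_cba == 0.0
    assert any("12 hours after the loading dose" in n for n in rec.notes)


def test_loading_dose_capped_with_immediate_attention():
    rec = loading_dose(2.0, 91.4)  # 78-inch male: uncapped 365.6 mg
    assert rec.uncapped_cba == pytest.approx(365.6)
    assert rec.capped_cba == 300.0
    assert rec.capped
    assert any(CAP_WARNING_HEADER in w for w in rec.warnings)
    assert "9.0 million IU" in rec.rendered


@given(
    css=st.sampled_from(CSS_GRID),
    ibw1=st.floats(min_value=40.0, max_value=120.0),
    ibw2=st.floats(min_value=40.0, max_value=120.0),
)
def test_loading_dose_monotone_in_css_and_ibw(css, ibw1, ibw2):
    lo, hi = sorted((ibw1, ibw2))
    assert loading_dose(css, lo).capped_cba <= loading_dose(css, hi).capped_cba
    if css < 4.0:
        assert loading_dose(css, ibw1).capped_cba <= loading_dose(css + 0.5, ibw1).capped_cba


# --- baseline daily dose ------------------------------------------------------

def test_identity_config_forces_baseline(identity_model):
    assert baseline_daily_dose(2.0, 50.0, identity_model) == pytest.approx(100.0)


def test_baseline_linear_in_css(identity_model):
    one = baseline_daily_dose(1.0, 37.0, identity_model)
    assert baseline_daily_dose(2.0, 37.0, identity_model) == pytest.approx(2.0 * one)


def test_step_bands_select_by_crcl(step_model):
    assert baseline_daily_dose(1.0, 0.0, step_model) == 100.0
    assert baseline_daily_dose(1.0, 29.999, step_model) == 100.0
    assert baseline_daily_dose(1.0, 30.0, step_model) == 200.0
    assert baseline_daily_dose(1.0, 90.0, step_model) == 300.0


@pytest.mark.parametrize(
    "bands, interpolate",
    [
        (((50.0, 200.0), (30.0, 100.0)), False),  # bounds not increasing
        (((30.0, 200.0), (math.inf, 100.0)), False),  # doses decreasing
        (((30.0, 100.0), (90.0, 200.0)), False),  # does not cover [0, inf)
        ((), False),  # empty
        (((0.0, 0.0), (math.inf, 100.0)), True),  # infinite knot
    ],
)
def test_malformed_band_tables_rejected_at_load(bands, interpolate):
    with pytest.raises(ConfigError):
        DosingModelConfig(name="bad", bands=bands, interpolate=interpolate)


def test_default_model_is_monotone_and_capped_at_300():
    model = default_model()
    assert model.max_daily_cba == 300.0
    crcls = [0, 5, 15, 25, 35, 45, 55, 65, 75, 85, 95, 200]
    doses = [model.dose_per_unit_css(c) for c in crcls]
    assert doses == sorted(doses)
    assert doses[0] > 0


def test_model_config_yaml_round_trip(tmp_path, step_model):
    path = tmp_path / "model.yaml"
    path.write_text(
        "name: steps\ninterpolate: false\nmax_daily_cba: 300\n"
        "bands:\n"
        "  - {crcl_upper: 30, dose_per_unit_css: 100}\n"
        "  - {crcl_upper: 90, dose_per_unit_css: 200}\n"
        "  - {crcl_upper: .inf, dose_per_unit_css: 300}\n"
    )
    loaded = load_model_config(path)
    assert loaded.bands == step_model.bands


# --- RRT supplements ----------------------------------------------------------

@pytest.mark.parametrize(
    "rrt, fraction",
    [
        (RenalReplacement(RRTMode.IHD, 2.0, dialysis_day=True), 0.20),
        (RenalReplacement(RRTMode.IHD, 5.0, dialysis_day=True), 0.50),
        (RenalReplacement(RRTMode.IHD, 3.0, dialysis_day=False), 0.0),
        (RenalReplacement(RRTMode.NONE), 0.0),
        (RenalReplacement(RRTMode.SLED, 8.0), 0.80),
        (RenalReplacement(RRTMode.CRRT, 24.0), 2.40),
    ],
)
def test_supplement_fractions(rrt, fraction):
    supplement, _, _ = rrt_supplement(200.0, rrt)
    assert supplement == pytest.approx(fraction * 200.0)


@given(baseline=baselines, hours=st.floats(min_value=0.5, max_value=24.0))
def test_supplement_exact_ratios_for_any_baseline(baseline, hours):
    ihd2, _, _ = rrt_supplement(baseline, RenalReplacement(RRTMode.IHD, 2.0, dialysis_day=True))
    ihd5, _, _ = rrt_supplement(baseline, RenalReplacement(RRTMode.IHD, 5.0, dialysis_day=True))
    assert ihd2 == 0.20 * baseline
    assert ihd5 == 0.50 * baseline
    sled, _, _ = rrt_supplement(baseline, RenalReplacement(RRTMode.SLED, hours))
    assert sled == (0.10 * hours) * baseline


def test_supplement_reminder_texts():
    _, _, notes = rrt_supplement(100.0, RenalReplacement(RRTMode.CRRT, 24.0))
    assert CRRT_REMINDER in notes
    _, _, notes = rrt_supplement(100.0, RenalReplacement(RRTMode.SLED, 8.0))
    assert SLED_REMINDER in notes
    _, warnings, notes = rrt_supplement(100.0, RenalReplacement(RRTMode.IHD, 6.0, dialysis_day=True))
    assert any("after the dialysis session" in n for n in notes)
    assert warnings  # session length outside the studied 2-5 h range


def test_rrt_invariants_enforced():
    with pytest.raises(ValidationError, match="session_hours"):
        RenalReplacement(RRTMode.NONE, session_hours=2.0)
    with pytest.raises(ValidationError, match="session_hours"):
        RenalReplacement(RRTMode.CRRT, session_hours=0.0)
    with pytest.raises(ValidationError, match="session_hours"):
        RenalReplacement(RRTMode.IHD, session_hours=-1.0, dialysis_day=True)


# --- full daily pipeline ------------------------------------------------------

def test_daily_pipeline_splits_capped_total_per_12h(identity_model):
    # CrCl 75 with the identity config and css 1.0 -> baseline 75 + 50% IHD
    # supplement = 112.5 mg/day
    patient = demo(weight=54.0)  # CrCl = 100*54/72 = 75
    rec = daily_recommendation(
        patient, 1.0, RenalReplacement(RRTMode.IHD, 5.0, dialysis_day=True), identity_model
    )
    assert rec.crcl_ml_min == pytest.approx(75.0)
    assert rec.baseline_cba == pytest.approx(75.0)
    assert rec.supplement_cba == pytest.approx(37.5)
    assert rec.total_cba == pytest.approx(112.5)
    assert rec.per_12h_cba == pytest.approx(56.25)
    assert not rec.capped


def test_daily_pipeline_example_150_total(identity_model):
    # css 1.0 at CrCl 150 -> 150 mg/day -> 75 mg CBA per 12 h
    patient = demo(weight=108.0)
    rec = daily_recommendation(patient, 1.0, RenalReplacement(), identity_model)
    assert rec.total_cba == pytest.approx(150.0)
    assert rec.per_12h_cba == pytest.approx(75.0)
    assert "75 mg CBA" in rec.per_12h_rendered


def test_daily_pipeline_caps_total_with_warning(identity_model):
    # css 2.0 at CrCl 150 with 24 h CRRT: 300 baseline + 720 supplement
    patient = demo(weight=108.0)
    rec = daily_recommendation(
        patient, 2.0, RenalReplacement(RRTMode.CRRT, 24.0), identity_model
    )
    assert rec.uncapped_cba > 300.0
    assert rec.capped_cba == 300.0
    assert rec.capped
    assert rec.per_12h_cba == 150.0
    assert any(CAP_WARNING_HEADER in w for w in rec.warnings)
    assert "9.0 million IU" in rec.rendered


def test_daily_without_rrt_equals_baseline(step_model):
    rec = daily_recommendation(demo(), 1.0, RenalReplacement(), step_model)
    assert rec.supplement_cba == 0.0
    assert rec.total_cba == rec.baseline_cba


@given(
    css=st.sampled_from(CSS_GRID),
    weight=st.floats(min_value=40.0, max_value=150.0),
    hours=st.floats(min_value=1.0, max_value=24.0),
)
def test_daily_total_monotone_in_css_and_hours(css, weight, hours):
    model = DosingModelConfig(
        name="identity", bands=((0.0, 0.0), (1000.0, 1000.0)), interpolate=True
    )
    patient = demo(weight=weight)
    rec = daily_recommendation(patient, css, RenalReplacement(RRTMode.CRRT, hours), model)
    assert rec.capped_cba <= 300.0
    longer = daily_recommendation(
        patient, css, RenalReplacement(RRTMode.CRRT, hours + 1.0), model
    )
    assert longer.capped_cba >= rec.capped_cba
    if css < 4.0:
        higher = daily_recommendation(
            patient, css + 0.5, RenalReplacement(RRTMode.CRRT, hours), model
        )
        assert higher.capped_cba >= rec.capped_cba
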