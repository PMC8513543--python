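"""Transition counting, annual<->monthly conversion, incidence fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ktah_cea as k
from ktah_cea.estimation import (
    NoDataError,
    annual_to_monthly,
    fit_incidence_models,
    monthly_rows_from_counts,
    monthly_to_annual,
)
from ktah_cea.registry import RegistryTable
from ktah_cea.states import GROUPS, IDX_DEATH, IDX_REMAIN, MODALITIES
from ktah_cea.validation import recovery_report


def make_registry(rows):
    eps = pd.DataFrame(rows, columns=["patient_id", "modality", "start_month", "end_month", "end_reason"])
    demo = pd.DataFrame(
        {
            "patient_id": eps["patient_id"].unique(),
            "age_band": "45-64",
            "diabetic": False,
        }
    )
    return RegistryTable(episodes=eps, demographics=demo, calibration_window=(0, 4))


def test_no_events_yields_pure_exposure():
    reg = make_registry([("A", "CHD", 0, None, None), ("B", "LDKT", 0, None, None)])
    counts = k.count_annual_transitions(reg).counts
    events = counts[:, :, :IDX_REMAIN]
    assert events.sum() == 0
    # 60-month window: 1 first year + 3 pooled subsequent years each
    assert counts[MODALITIES.index("CHD"), 0, IDX_REMAIN] == 1
    assert counts[MODALITIES.index("CHD"), 1, IDX_REMAIN] == 3


def test_single_first_year_switch_counted_once():
    reg = make_registry(
        [("A", "CHD", 0, 6, "switch"), ("A", "LDKT", 6, None, None)]
    )
    counts = k.count_annual_transitions(reg).counts
    assert counts[MODALITIES.index("CHD"), 0, MODALITIES.index("LDKT")] == 1
    assert counts[MODALITIES.index("CHD"), 0].sum() == 1  # no remain for that spell


def test_subsequent_year_event_pooled_into_phase_two():
    reg = make_registry(
        [("A", "CHD", 0, 20, "death")]
    )
    counts = k.count_annual_transitions(reg).counts
    m = MODALITIES.index("CHD")
    assert counts[m, 0, IDX_REMAIN] == 1  # survived year 1
    assert counts[m, 1, IDX_DEATH] == 1  # died in spell-year 2


def test_events_after_spell_year_four_ignored():
    reg = make_registry([("A", "CHD", 0, 55, "death")])
    counts = k.count_annual_transitions(reg).counts
    m = MODALITIES.index("CHD")
    assert counts[m, 1, IDX_DEATH] == 0
    assert counts[m, 0, IDX_REMAIN] == 1
    assert counts[m, 1, IDX_REMAIN] == 3


def test_empty_registry_signals_no_data():
    reg = make_registry([("A", "CHD", 0, None, None)])
    reg.episodes = reg.episodes.iloc[:0]
    with pytest.raises(NoDataError):
        k.count_annual_transitions(reg)


def test_annual_to_monthly_inverts_compounding():
    annual = np.zeros(7)
    annual[MODALITIES.index("LDKT")] = 1 - 0.98**12
    monthly = annual_to_monthly(annual)
    assert monthly[MODALITIES.index("LDKT")] == pytest.approx(0.02, abs=1e-12)


def test_annual_to_monthly_preserves_cause_ratios():
    annual = np.array([0.2, 0.1, 0, 0, 0, 0, 0.0])
    monthly = annual_to_monthly(annual)
    assert monthly[0] / monthly[1] == pytest.approx(2.0, rel=1e-12)
    assert annual_to_monthly(np.zeros(7)).sum() == 0.0


def test_annual_to_monthly_degenerate_and_invalid():
    full = np.array([1.0, 0, 0, 0, 0, 0, 0.0])
    assert annual_to_monthly(full).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        annual_to_monthly(np.array([0.8, 0.4, 0, 0, 0, 0, 0.0]))


@given(
    st.lists(st.floats(min_value=0, max_value=0.2), min_size=7, max_size=7).filter(
        lambda v: sum(v) <= 1.0
    )
)
def test_round_trip_annual_monthly_property(events):
    """Compounding the monthly vector over 12 cycles reproduces the
    annual leaving probability to 1e-10."""
    annual = np.array(events)
    monthly = annual_to_monthly(annual)
    back = monthly_to_annual(monthly)
    np.testing.assert_allclose(back, annual, atol=1e-10)


def test_parameter_recovery_on_generated_registry(recovery_counts, truth):
    """Estimated annual and monthly transition probabilities on a
    ~10,000-patient registry sit within 3 binomial SE of ground truth."""
    report = recovery_report(recovery_counts, truth.monthly)
    assert report.exposures.min() > 100
    assert report.max_abs_annual_z < 3.0
    assert report.max_abs_monthly_z < 3.0


def test_estimated_rows_are_row_stochastic(recovery_counts):
    monthly, warnings = monthly_rows_from_counts(recovery_counts)
    assert warnings == []
    np.testing.assert_allclose(monthly.sum(axis=2), 1.0, atol=1e-12)
    assert (monthly >= 0).all()


def test_dirichlet_concentration_equals_counts_and_mean():
    counts = np.zeros((6, 2, 8))
    counts[0, 0, 1] = 3
    counts[0, 0, 7] = 7
    conc, no_data = k.dirichlet_concentration(k.AnnualTransitionCounts(counts))
    assert conc[0, 0, 1] == 3 and conc[0, 0, 7] == 7
    assert not no_data[0, 0] and no_data[1, 0]
    mean = conc[0, 0] / conc[0, 0].sum()
    assert mean[1] == pytest.approx(0.3)


def test_dirichlet_draws_match_moments():
    rng = np.random.default_rng(11)
    draws = rng.dirichlet([30, 70], size=5000)[:, 0]
    se = np.sqrt(0.3 * 0.7 / (100 + 1)) / np.sqrt(5000)
    assert abs(draws.mean() - 0.3) < 3 * se


# --- incidence fitting ---


def incidence_frame(series):
    rows = []
    for (age_band, diabetic, modality), counts in series.items():
        for year, c in enumerate(counts):
            rows.append((2008 + year, age_band, diabetic, modality, c))
    return pd.DataFrame(rows, columns=["year", "age_band", "diabetic", "modality", "count"])


def test_constant_series_forecasts_constant():
    df = incidence_frame({("45-64", False, "CHD"): [10, 10, 10, 10]})
    fc = fit_incidence_models(df)
    fit = fc.series[(k.DemographicGroup("45-64", False), "CHD")]
    np.testing.assert_allclose(fit.forecast_annual, 10.0, atol=1e-9)
    np.testing.assert_allclose(fit.monthly_inflow(), 10.0 / 12, atol=1e-9)


def test_sparse_series_uses_locf_of_last_value():
    df = incidence_frame({("45-64", False, "CHD"): [0, 0, 1, 0]})
    fc = fit_incidence_models(df)
    fit = fc.series[(k.DemographicGroup("45-64", False), "CHD")]
    assert fit.family == "locf"
    np.testing.assert_allclose(fit.forecast_annual, 0.0)


def test_noiseless_linear_series_recovered_exactly():
    counts = [100 + 5 * t for t in range(4)]
    df = incidence_frame({("45-64", False, "LDKT"): counts})
    fc = fit_incidence_models(df)
    fit = fc.series[(k.DemographicGroup("45-64", False), "LDKT")]
    assert fit.family == "linear"
    intercept, slope = fit.coefficients
    assert slope == pytest.approx(5.0, abs=1e-9)
    # forecast at t = 11 (8th forecast year) is 100 + 5*11 = 155
    assert fit.forecast_annual[7] == pytest.approx(155.0, abs=1e-8)


def test_exponential_series_prefers_log_linear_family():
    counts = [50 * 1.2**t for t in range(6)]
    df = incidence_frame({("45-64", False, "LDKT"): counts})
    fc = fit_incidence_models(df)
    fit = fc.series[(k.DemographicGroup("45-64", False), "LDKT")]
    assert fit.family == "exponential"
    a, b = fit.coefficients
    assert np.exp(b) == pytest.approx(1.2, rel=1e-9)


def test_negative_forecasts_clipped_to_zero():
    counts = [20, 15, 10, 5]
    df = incidence_frame({("45-64", False, "CAPD"): counts})
    fc = fit_incidence_models(df)
    fit = fc.series[(k.DemographicGroup("45-64", False), "CAPD")]
    assert fit.family == "linear"
    assert (fit.forecast_annual >= 0).all()
    assert fit.forecast_annual[-1] == 0.0


def test_forecast_requires_two_years():
    df = incidence_frame({("45-64", False, "CHD"): [10]})
    with pytest.raises(ValueError):
        fit_incidence_models(df)


def test_all_36_series_present_even_when_input_sparse():
    df = incidence_frame({("45-64", False, "CHD"): [10, 10]})
    fc = fit_incidence_models(df)
    assert len(fc.series) == 36
    inflow = fc.inflow_array(stratify=False)
    assert inflow.shape == (120, 1, 6)
    assert (inflow >= 0).all()
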