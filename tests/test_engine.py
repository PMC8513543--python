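"""Cohort engine: state space, stepping, discounting, accumulation."""

import numpy as np
import pytest

import ktah_cea as k
from ktah_cea.engine import CohortVector, accumulate_outcomes, discount_factor, step_cohort
from ktah_cea.params import ModelParameters
from ktah_cea.registry import monthly_rows_from_events
from tests.conftest import build_two_modality_params


def test_state_space_sizes():
    assert k.build_state_space(False).n_states == 79
    assert k.build_state_space(True).n_states == 469


def test_phase_boundary_at_twelve_months():
    space = k.build_state_space(False)
    assert space.phase("CHD", 12) == "first_year"
    assert space.phase("CHD", "13+") == "subsequent"
    assert space.phase("CHD", 1) == "first_year"


def test_identity_step_advances_tenure():
    monthly = monthly_rows_from_events({})  # pure remain
    occ = np.zeros((1, 6, 13))
    occ[0, 0, 0] = 5  # CHD tenure 1
    occ[0, 0, 11] = 2  # CHD tenure 12
    occ[0, 0, 12] = 3  # CHD "13+"
    v = step_cohort(CohortVector(occ), monthly, np.zeros((1, 6)))
    assert v.occupancy[0, 0, 1] == 5
    assert v.occupancy[0, 0, 12] == 2 + 3  # tenure-12 crosses into "13+"
    assert v.modality_totals()[0] == 10
    assert v.deaths == 0


def test_pure_inflow_enters_first_tenure_slot():
    monthly = monthly_rows_from_events({})
    v = step_cohort(
        CohortVector(np.zeros((1, 6, 13))), monthly, {"LDKT": 10}
    )
    assert v.occupancy[0, 5, 0] == 10
    assert v.live_total == 10


def test_step_expectation_arithmetic():
    """100 long-tenure CHD patients, 2% to LDKT and 1% death per month."""
    monthly = monthly_rows_from_events(
        {("CHD", "subsequent"): {"LDKT": 0.02, "death": 0.01}}
    )
    occ = np.zeros((1, 6, 13))
    occ[0, 0, 12] = 100
    v = step_cohort(CohortVector(occ), monthly, np.zeros((1, 6)))
    assert v.occupancy[0, 0, 12] == pytest.approx(97.0)
    assert v.occupancy[0, 5, 0] == pytest.approx(2.0)
    assert v.deaths == pytest.approx(1.0)


def test_negative_inflow_rejected():
    monthly = monthly_rows_from_events({})
    with pytest.raises(ValueError):
        step_cohort(CohortVector(np.zeros((1, 6, 13))), monthly, -np.ones((1, 6)))


@pytest.mark.parametrize(
    "rate, cycle, expected",
    [
        (0.04, 0, 1.0),
        (0.04, 12, 1 / 1.04),
        (0.015, 120, 1.015**-10),
    ],
)
def test_discount_factor_closed_form(rate, cycle, expected):
    assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)


def _fixed_patient_params(modality_idx, months, discount=True):
    monthly = monthly_rows_from_events({})
    initial = np.zeros((1, 6, 13))
    initial[0, modality_idx, 12] = 1.0
    econ = k.economic_inputs_from_reference()
    if not discount:
        econ.cost_discount_rate = 0.0
        econ.qaly_discount_rate = 0.0
    return ModelParameters(
        monthly=monthly, inflow=np.zeros((months, 1, 6)), initial=initial, econ=econ
    )


def test_one_patient_ldkt_year_accrues_printed_annual_values():
    """One long-tenure LDKT patient for 12 undiscounted months costs the
    printed 22,716 EUR and yields 0.81 QALYs."""
    params = _fixed_patient_params(5, 12, discount=False)
    res = k.run_model(params)
    assert res.outcomes.total_cost == pytest.approx(22_716.0, rel=1e-12)
    assert res.outcomes.total_qalys == pytest.approx(0.81, rel=1e-12)


def test_120_cycle_discounted_cost_matches_geometric_sum():
    params = _fixed_patient_params(0, 120)
    res = k.run_model(params)
    t = np.arange(120)
    expected = (98_914.0 / 12) * (1.04 ** (-t / 12)).sum()
    assert res.outcomes.total_cost == pytest.approx(expected, rel=1e-9)


def test_empty_cohort_yields_zero_series():
    monthly = monthly_rows_from_events({})
    params = ModelParameters(
        monthly=monthly,
        inflow=np.zeros((24, 1, 6)),
        initial=np.zeros((1, 6, 13)),
        econ=k.economic_inputs_from_reference(),
    )
    res = k.run_model(params)
    assert res.outcomes.total_cost == 0.0
    assert res.outcomes.total_qalys == 0.0


def test_conservation_every_cycle(estimated_params):
    res = k.run_model(estimated_params)
    assert res.trace.conservation_error() < 1e-6


def test_tenure_cohort_reaches_subsequent_phase_at_cycle_13(toy_params):
    """A cohort entering one modality with no further events reaches the
    "13+" slot exactly at cycle 13."""
    monthly = monthly_rows_from_events({})
    inflow = np.zeros((15, 1, 6))
    inflow[0, 0, 0] = 100  # enter CHD at cycle 1
    params = ModelParameters(
        monthly=monthly,
        inflow=inflow,
        initial=np.zeros((1, 6, 13)),
        econ=k.economic_inputs_from_reference(),
    )
    res = k.run_model(params)
    occ = res.trace.occupancy
    assert occ[12, 0, 0, 11] == 100  # tenure 12 at cycle 12
    assert occ[12, 0, 0, 12] == 0
    assert occ[13, 0, 0, 12] == 100  # "13+" exactly at cycle 13


def test_zero_discount_cost_is_exact_occupancy_sum(toy_params):
    toy_params.econ.cost_discount_rate = 0.0
    toy_params.econ.qaly_discount_rate = 0.0
    res = k.run_model(toy_params)
    occ = res.trace.occupancy[:-1]  # start-of-cycle occupancy
    monthly_cost = np.zeros((6, 13))
    monthly_cost[:, :12] = toy_params.econ.annual_cost[:, 0][:, None] / 12
    monthly_cost[:, 12] = toy_params.econ.annual_cost[:, 1] / 12
    expected = float(np.einsum("tgms,ms->", occ, monthly_cost))
    assert res.outcomes.total_cost == pytest.approx(expected, rel=1e-12)


def test_yearly_outputs_are_non_cumulative(toy_params):
    res = k.run_model(toy_params)
    # recompute year 2 from cycles 13..24 alone
    trace = res.trace
    sub = k.CohortTrace(
        occupancy=trace.occupancy[12:],
        cumulative_deaths=trace.cumulative_deaths[12:],
        cumulative_inflow=trace.cumulative_inflow[12:],
    )
    out = accumulate_outcomes(sub, toy_params.econ)
    # discounting exponents restart, so rescale by the 12-cycle factor
    scale_c = discount_factor(toy_params.econ.cost_discount_rate, 12)
    scale_q = discount_factor(toy_params.econ.qaly_discount_rate, 12)
    assert res.outcomes.yearly_costs[1] == pytest.approx(
        out.yearly_costs[0] * scale_c, rel=1e-10
    )
    assert res.outcomes.yearly_qalys[1] == pytest.approx(
        out.yearly_qalys[0] * scale_q, rel=1e-10
    )


def test_cohort_matches_microsimulation_oracle():
    """Expected occupancies, costs and QALYs from the cohort engine match
    an individual-level microsimulation within 3 Monte-Carlo SE on the
    two-modality toy configuration."""
    params = build_two_modality_params(
        horizon=24, initial_chd=10_000, initial_ldkt=10_000, inflow_chd=50
    )
    cohort = k.run_model(params)
    micro = k.run_microsim(params, seed=7)
    n = micro.n_individuals

    se_cost = micro.individual_costs.std() * np.sqrt(n)
    se_qaly = micro.individual_qalys.std() * np.sqrt(n)
    assert abs(micro.total_cost - cohort.outcomes.total_cost) < 3 * se_cost
    assert abs(micro.total_qalys - cohort.outcomes.total_qalys) < 3 * se_qaly

    # per-modality occupancy at the final cycle, binomial SE on counts
    for m in (0, 5):
        exp = cohort.trace.occupancy[-1, 0, m].sum()
        obs = micro.occupancy[-1, m].sum()
        p = exp / n
        se = np.sqrt(n * p * (1 - p))
        assert abs(obs - exp) < 3 * se
    # deaths
    exp_d = cohort.trace.cumulative_deaths[-1]
    obs_d = micro.cumulative_deaths[-1]
    p = exp_d / n
    assert abs(obs_d - exp_d) < 3 * np.sqrt(n * p * (1 - p))


def test_trace_frame_exports_cycle_indexed_totals(toy_params):
    res = k.run_model(toy_params)
    df = res.trace.to_frame()
    assert list(df["cycle"]) == list(range(25))
    assert "CHD" in df.columns and "death" in df.columns
    out = res.outcomes.to_frame()
    assert list(out["month"]) == [12, 24]
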