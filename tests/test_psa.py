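"""Probabilistic sensitivity analysis and CEA summaries."""

import numpy as np
import pytest

import ktah_cea as k
from ktah_cea.psa import (
    ParameterPriors,
    beta_from_moments,
    draw_parameters,
    gamma_from_moments,
    icer,
    run_psa,
    summarize,
)
from tests.conftest import build_two_modality_params


def test_beta_moment_matching_closed_form():
    a, b = beta_from_moments(0.5, 0.25)
    assert a == pytest.approx(1.5) and b == pytest.approx(1.5)
    a, b = beta_from_moments(0.56, 0.033)
    assert a / (a + b) == pytest.approx(0.56, rel=1e-12)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert np.sqrt(var) == pytest.approx(0.033, rel=1e-9)


def test_beta_degenerate_limit_concentrates_at_mean():
    a, b = beta_from_moments(0.56, 1e-6)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert var < 1e-11


def test_beta_infeasible_variance_rejected():
    with pytest.raises(ValueError):
        beta_from_moments(0.5, 0.6)
    with pytest.raises(ValueError):
        beta_from_moments(1.2, 0.1)


def test_gamma_moment_matching_closed_form():
    shape, scale = gamma_from_moments(2811.0, 281.0)
    assert shape == pytest.approx(100.0712, abs=1e-3)
    assert scale == pytest.approx(28.0900, abs=1e-3)
    assert shape * scale == pytest.approx(2811.0, rel=1e-12)
    shape, scale = gamma_from_moments(98_914.0, 367.0)
    assert shape * scale == pytest.approx(98_914.0, rel=1e-12)
    with pytest.raises(ValueError):
        gamma_from_moments(-1.0, 1.0)


def test_draws_are_deterministic_given_seed(toy_params):
    priors = ParameterPriors.from_reference()
    d1 = draw_parameters(toy_params, priors, np.random.default_rng(5))
    d2 = draw_parameters(toy_params, priors, np.random.default_rng(5))
    np.testing.assert_array_equal(d1.monthly, d2.monthly)
    np.testing.assert_array_equal(d1.econ.annual_cost, d2.econ.annual_cost)
    assert d1.effect_multiplier == d2.effect_multiplier


def test_drawn_utility_mean_matches_reference(toy_params):
    """5,000 CHD-utility draws average to the printed 0.56 within
    3 SE/sqrt(N)."""
    priors = ParameterPriors.from_reference()
    rng = np.random.default_rng(17)
    draws = np.array(
        [draw_parameters(toy_params, priors, rng).econ.utility[0, 0] for _ in range(5000)]
    )
    tol = 3 * 0.033 / np.sqrt(5000)
    assert abs(draws.mean() - 0.56) < tol


def test_drawn_rows_remain_row_stochastic(estimated_params):
    priors = ParameterPriors.from_reference()
    rng = np.random.default_rng(3)
    for _ in range(20):
        d = draw_parameters(estimated_params, priors, rng)
        np.testing.assert_allclose(d.monthly.sum(axis=2), 1.0, atol=1e-9)
        assert (d.monthly >= 0).all()


def test_run_psa_bookkeeping(toy_params):
    psa = run_psa(toy_params, [k.base_case(), k.optimistic()], n_draws=2, seed=1)
    assert psa.costs.shape == (2, 2)
    assert psa.n_draws == 2
    with pytest.raises(ValueError):
        run_psa(toy_params, [k.base_case()], n_draws=1, seed=1)
    with pytest.raises(ValueError):
        run_psa(toy_params, [k.optimistic()], n_draws=2, seed=1)  # no base case


def test_zero_effect_scenario_increments_are_identically_zero(toy_params):
    from ktah_cea.scenarios import ScenarioSpec

    null = ScenarioSpec(label="custom", ldkt_effect_fraction=0.0)
    psa = run_psa(toy_params, [k.base_case(), null], n_draws=5, seed=2)
    np.testing.assert_array_equal(psa.costs[:, 0], psa.costs[:, 1])
    np.testing.assert_array_equal(psa.qalys[:, 0], psa.qalys[:, 1])


def test_positive_effect_gains_qalys_on_toy_config():
    params = build_two_modality_params(horizon=36, inflow_chd=200.0)
    psa = run_psa(params, [k.base_case(), k.optimistic()], n_draws=60, seed=4)
    dq = psa.qalys[:, 1] - psa.qalys[:, 0]
    assert dq.mean() > 3 * dq.std() / np.sqrt(len(dq))


def test_full_run_determinism(toy_params):
    a = run_psa(toy_params, [k.base_case(), k.optimistic()], n_draws=4, seed=9)
    b = run_psa(toy_params, [k.base_case(), k.optimistic()], n_draws=4, seed=9)
    np.testing.assert_array_equal(a.costs, b.costs)
    np.testing.assert_array_equal(a.yearly_qalys, b.yearly_qalys)


@pytest.mark.parametrize(
    "dc, dq, expected",
    [
        (-100.0, 1.0, "dominant"),
        (-100.0, -1.0, "tradeoff"),
        (100.0, 1.0, "tradeoff"),
        (100.0, -1.0, "dominated"),
        (0.0, 1.0, "tradeoff"),
        (0.0, -1.0, "tradeoff"),
        (-100.0, 0.0, "undefined"),
        (100.0, 0.0, "undefined"),
        (0.0, 0.0, "undefined"),
    ],
)
def test_icer_sign_grid(dc, dq, expected):
    res = icer(dc, dq)
    assert res.classification == expected
    if expected == "undefined":
        assert res.ratio is None
    else:
        assert res.ratio == pytest.approx(dc / dq)


def test_icer_on_reference_savings_is_dominant():
    res = icer(-107_823_949.0, 1_408.0)
    assert res.classification == "dominant"
    assert res.ratio == pytest.approx(-76_580, abs=1.0)


def test_percentile_interval_of_normal_draws():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(5000)
    lo, hi = np.percentile(x, [2.5, 97.5])
    assert lo == pytest.approx(-1.96, abs=0.1)
    assert hi == pytest.approx(1.96, abs=0.1)


def test_summarize_identical_draws_gives_zero_width_interval(toy_params):
    psa = run_psa(toy_params, [k.base_case(), k.optimistic()], n_draws=3, seed=6)
    psa.costs[:, 0] = 100.0
    psa.qalys[:, 0] = 10.0
    summary = summarize(psa)
    row = summary.scenario_table.set_index("scenario").loc["base_case"]
    assert row["mean_cost"] == 100.0
    assert row["cost_lo"] == row["cost_hi"] == 100.0


def test_dominant_toy_cloud_sits_in_dominance_quadrant():
    """A comparison constructed to be dominant places nearly the whole
    CE cloud in the gain-QALYs / save-costs quadrant."""
    params = build_two_modality_params(horizon=36, inflow_chd=200.0)
    params.econ.annual_cost[5] = 1000.0  # LDKT nearly free: dominance by construction
    spec = k.optimistic()
    psa = run_psa(params, [k.base_case(), spec], n_draws=100, seed=8)
    summary = summarize(psa)
    cloud = summary.comparisons[0].ce_plane
    frac = ((cloud["delta_qaly"] > 0) & (cloud["delta_cost"] < 0)).mean()
    assert frac >= 0.99
    assert summary.comparisons[0].dominant


def test_deterministic_run_inside_psa_intervals(toy_params):
    det = k.run_model(toy_params)
    psa = run_psa(toy_params, [k.base_case()], n_draws=200, seed=10)
    lo_c, hi_c = np.percentile(psa.costs[:, 0], [2.5, 97.5])
    lo_q, hi_q = np.percentile(psa.qalys[:, 0], [2.5, 97.5])
    assert lo_c < det.outcomes.total_cost < hi_c
    assert lo_q < det.outcomes.total_qalys < hi_q


def test_psa_means_converge_to_deterministic_as_ses_vanish(toy_params):
    """With all SEs scaled by 1e-3 (the toy configuration carries no
    transition uncertainty), PSA means collapse onto the deterministic
    run."""
    priors = ParameterPriors.from_reference()
    priors.utility_se = priors.utility_se * 1e-3
    priors.cost_rows = [
        (name, cells, mean, se * 1e-3) for name, cells, mean, se in priors.cost_rows
    ]
    priors.effect_relative_se = 1e-3
    priors.intervention_cost_se = priors.intervention_cost_se * 1e-3
    det = k.run_model(toy_params)
    psa = run_psa(toy_params, [k.base_case()], n_draws=40, seed=12, priors=priors)
    assert psa.costs[:, 0].mean() == pytest.approx(det.outcomes.total_cost, rel=1e-3)
    assert psa.qalys[:, 0].mean() == pytest.approx(det.outcomes.total_qalys, rel=1e-3)
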