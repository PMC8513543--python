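"""Probabilistic sensitivity analysis and cost-effectiveness summaries.

Parameter uncertainty is propagated by Monte Carlo: utilities are beta
distributed, costs gamma distributed (both moment-matched to the
printed mean/SE), transition rows Dirichlet distributed with the annual
counts as concentrations (drawn annually, then converted to monthly),
the effect size carries a 20% relative SE (mean-one gamma multiplier,
which keeps it positive) and the intervention unit cost a 10% SE. The
same parameter draw is evaluated under every scenario (common random
numbers), so per-draw increments isolate the intervention effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import run_model
from .estimation import annual_to_monthly
from .fixtures import (
    EFFECT_RELATIVE_SE,
    INTERVENTION_COST,
    INTERVENTION_COST_SE,
    ReferenceParameters,
    load_reference_parameters,
)
from .params import EconomicInputs, ModelParameters
from .scenarios import ScenarioSpec, apply_intervention
from .states import IDX_REMAIN, MODALITIES, N_DESTINATIONS, N_MODALITIES, PHASES

# ---------------------------------------------------------------------------
# Moment matching


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) matching a mean and SE.

    nu = mean(1-mean)/se^2 - 1; alpha = mean*nu; beta = (1-mean)*nu.
    Requires 0 < mean < 1 and se^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly in (0, 1)")
    if se <= 0 or se * se >= mean * (1.0 - mean):
        raise ValueError("infeasible beta variance")
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and SE:
    shape = (mean/se)^2, scale = se^2/mean."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    return (mean / se) ** 2, se * se / mean


# ---------------------------------------------------------------------------
# Priors and draws


@dataclass
class ParameterPriors:
    """Distributions of every uncertain parameter block.

    Cost rows follow the printed table: one gamma per row, dialysis rows
    covering both phases jointly. Transition rows use the annual-count
    Dirichlet concentrations carried by the parameters; rows flagged
    no-data stay at their point estimate.
    """

    utility_mean: np.ndarray  # (6,)
    utility_se: np.ndarray  # (6,)
    cost_rows: list[tuple[str, tuple[tuple[int, int], ...], float, float]]
    # each: (name, ((modality, phase) cells sharing the draw), mean, se)
    intervention_cost_mean: float = INTERVENTION_COST
    intervention_cost_se: float = INTERVENTION_COST_SE
    effect_relative_se: float = EFFECT_RELATIVE_SE

    @classmethod
    def from_reference(cls, ref: ReferenceParameters | None = None) -> "ParameterPriors":
        ref = ref or load_reference_parameters()
        rows: list[tuple[str, tuple[tuple[int, int], ...], float, float]] = []
        for m, name in enumerate(MODALITIES):
            if (name, None) in ref.cost_row_ses:  # one row for both phases
                rows.append(
                    (
                        name,
                        ((m, 0), (m, 1)),
                        ref.annual_costs[(name, "first_year")],
                        ref.cost_row_ses[(name, None)],
                    )
                )
            else:
                for p, phase in enumerate(PHASES):
                    rows.append(
                        (
                            f"{name}-{phase}",
                            ((m, p),),
                            ref.annual_costs[(name, phase)],
                            ref.cost_row_ses[(name, phase)],
                        )
                    )
        return cls(
            utility_mean=np.array([ref.utilities[m] for m in MODALITIES]),
            utility_se=np.array([ref.utility_ses[m] for m in MODALITIES]),
            cost_rows=rows,
            intervention_cost_mean=ref.intervention_cost,
            intervention_cost_se=ref.intervention_cost_se,
        )


@dataclass
class ParameterDraw:
    """One realization of all uncertain blocks."""

    econ: EconomicInputs
    monthly: np.ndarray
    effect_multiplier: float
    intervention_unit_cost: float


def draw_parameters(
    base: ModelParameters, priors: ParameterPriors, rng: np.random.Generator
) -> ParameterDraw:
    """Draw one joint parameter realization.

    Utilities and cost rows are drawn independently; each transition
    origin/phase row is drawn from its Dirichlet (annual scale) and
    converted to monthly. Deterministic given the generator state.
    """
    util = np.empty(N_MODALITIES)
    for m in range(N_MODALITIES):
        a, b = beta_from_moments(priors.utility_mean[m], priors.utility_se[m])
        util[m] = rng.beta(a, b)
    utility = np.repeat(util[:, None], 2, axis=1)

    cost = base.econ.annual_cost.copy()
    for _, cells, mean, se in priors.cost_rows:
        shape, scale = gamma_from_moments(mean, se)
        value = rng.gamma(shape, scale)
        for m, p in cells:
            cost[m, p] = value

    monthly = base.monthly.copy()
    if base.dirichlet is not None:
        no_data = (
            base.dirichlet_no_data
            if base.dirichlet_no_data is not None
            else base.dirichlet.sum(axis=2) <= 0
        )
        for m in range(N_MODALITIES):
            for p in range(2):
                if no_data[m, p]:
                    continue
                conc = base.dirichlet[m, p]
                support = conc > 0
                annual = np.zeros(N_DESTINATIONS)
                annual[support] = rng.dirichlet(conc[support])
                events = annual_to_monthly(annual[:IDX_REMAIN])
                monthly[m, p, :IDX_REMAIN] = events
                monthly[m, p, IDX_REMAIN] = 1.0 - events.sum()

    shape_eff = 1.0 / priors.effect_relative_se**2
    effect_multiplier = rng.gamma(shape_eff, 1.0 / shape_eff)
    shape_c, scale_c = gamma_from_moments(
        priors.intervention_cost_mean, priors.intervention_cost_se
    )
    unit_cost = rng.gamma(shape_c, scale_c)

    econ = EconomicInputs(
        annual_cost=cost,
        utility=utility,
        cost_discount_rate=base.econ.cost_discount_rate,
        qaly_discount_rate=base.econ.qaly_discount_rate,
    )
    return ParameterDraw(
        econ=econ,
        monthly=monthly,
        effect_multiplier=effect_multiplier,
        intervention_unit_cost=unit_cost,
    )


def _scenario_for_draw(spec: ScenarioSpec, draw: ParameterDraw) -> ScenarioSpec:
    if spec.ldkt_effect_fraction == 0.0:
        return spec
    scaled = min(1.0, spec.ldkt_effect_fraction * draw.effect_multiplier)
    return replace(
        spec,
        ldkt_effect_fraction=scaled,
        intervention_unit_cost=draw.intervention_unit_cost,
    )


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PSAResult:
    """Per-draw, per-scenario discounted totals (and per-year series)."""

    scenario_labels: list[str]
    costs: np.ndarray  # (n_draws, n_scenarios)
    qalys: np.ndarray
    yearly_costs: np.ndarray  # (n_draws, n_scenarios, n_years)
    yearly_qalys: np.ndarray
    seed: int
    n_draws: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.costs).all() or not np.isfinite(self.qalys).all():
            raise ValueError("PSA totals must be finite")
        if (self.costs < 0).any():
            raise ValueError("costs must be nonnegative")

    def scenario_index(self, label: str) -> int:
        return self.scenario_labels.index(label)


def run_psa(
    params: ModelParameters,
    scenarios: list[ScenarioSpec],
    n_draws: int = 5000,
    seed: int = 0,
    priors: ParameterPriors | None = None,
    horizon: int | None = None,
) -> PSAResult:
    """Monte Carlo PSA: evaluate every scenario under each of ``n_draws``
    joint parameter draws (common random numbers across scenarios)."""
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2 for interval estimation")
    labels = [s.label for s in scenarios]
    if "base_case" not in labels:
        raise ValueError("scenario list must include base_case")
    priors = priors or ParameterPriors.from_reference()
    H = horizon if horizon is not None else params.horizon
    n_years = H // 12 + (1 if H % 12 else 0)
    n_s = len(scenarios)
    costs = np.empty((n_draws, n_s))
    qalys = np.empty((n_draws, n_s))
    yearly_costs = np.empty((n_draws, n_s, n_years))
    yearly_qalys = np.empty((n_draws, n_s, n_years))

    streams = np.random.SeedSequence(seed).spawn(n_draws)
    for i in range(n_draws):
        rng = np.random.default_rng(streams[i])
        draw = draw_parameters(params, priors, rng)
        drawn_base = replace(
            params,
            monthly=draw.monthly,
            econ=draw.econ,
            monthly_alt=None,
            inflow_alt=None,
            cost_stream=None,
        )
        for j, spec in enumerate(scenarios):
            run_params = apply_intervention(drawn_base, _scenario_for_draw(spec, draw))
            res = run_model(run_params, horizon=H)
            costs[i, j] = res.outcomes.total_cost
            qalys[i, j] = res.outcomes.total_qalys
            yearly_costs[i, j] = res.outcomes.yearly_costs
            yearly_qalys[i, j] = res.outcomes.yearly_qalys
    return PSAResult(
        scenario_labels=labels,
        costs=costs,
        qalys=qalys,
        yearly_costs=yearly_costs,
        yearly_qalys=yearly_qalys,
        seed=seed,
        n_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# ICER and summaries


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio with quadrant classification."""

    ratio: float | None
    classification: str  # dominant | dominated | tradeoff | undefined


def icer(delta_cost: float, delta_qaly: float) -> ICERResult:
    """ICER = dCost/dQALY; dominant iff dC < 0 and dQ > 0, dominated iff
    dC > 0 and dQ < 0, undefined (no ratio) when dQ = 0."""
    if delta_qaly == 0:
        return ICERResult(ratio=None, classification="undefined")
    if delta_cost < 0 and delta_qaly > 0:
        cls = "dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        cls = "dominated"
    else:
        cls = "tradeoff"
    return ICERResult(ratio=delta_cost / delta_qaly, classification=cls)


@dataclass
class ComparisonSummary:
    """Incremental summary of one scenario against its comparator."""

    scenario: str
    comparator: str
    mean_delta_cost: float
    mean_delta_qaly: float
    icer_ratio_of_means: ICERResult
    icer_mean_of_ratios: float | None
    deterministic_icer: ICERResult | None
    dominant: bool
    per_year: pd.DataFrame  # month, delta_cost, delta_qaly, icer
    ce_plane: pd.DataFrame  # draw, delta_qaly, delta_cost


@dataclass
class CEASummary:
    """Scenario-level means/intervals plus incremental comparisons."""

    scenario_table: pd.DataFrame
    comparisons: list[ComparisonSummary] = field(default_factory=list)


def _interval(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def summarize(
    psa: PSAResult,
    comparisons: list[tuple[str, str]] | None = None,
    deterministic: dict[str, tuple[float, float]] | None = None,
) -> CEASummary:
    """Summarize a PSA: per-scenario means and 95% percentile intervals,
    and per-comparison incremental tables, ICERs (ratio-of-mean-
    increments headline, mean-of-ratios alongside) and the CE plane.

    ``deterministic`` optionally maps scenario label -> (total cost,
    total QALYs) of the point-estimate run, from which deterministic
    ICERs are computed.
    """
    rows = []
    for j, label in enumerate(psa.scenario_labels):
        c_lo, c_hi = _interval(psa.costs[:, j])
        q_lo, q_hi = _interval(psa.qalys[:, j])
        rows.append(
            {
                "scenario": label,
                "mean_cost": float(psa.costs[:, j].mean()),
                "cost_lo": c_lo,
                "cost_hi": c_hi,
                "mean_qalys": float(psa.qalys[:, j].mean()),
                "qalys_lo": q_lo,
                "qalys_hi": q_hi,
            }
        )
    scenario_table = pd.DataFrame(rows)

    comps: list[ComparisonSummary] = []
    if comparisons is None:
        comparisons = [
            (label, "base_case")
            for label in psa.scenario_labels
            if label != "base_case"
        ]
    for scenario, comparator in comparisons:
        j, k = psa.scenario_index(scenario), psa.scenario_index(comparator)
        d_cost = psa.costs[:, j] - psa.costs[:, k]
        d_qaly = psa.qalys[:, j] - psa.qalys[:, k]
        mean_dc, mean_dq = float(d_cost.mean()), float(d_qaly.mean())
        valid = d_qaly != 0
        mean_of_ratios = float((d_cost[valid] / d_qaly[valid]).mean()) if valid.any() else None
        dy_cost = psa.yearly_costs[:, j] - psa.yearly_costs[:, k]
        dy_qaly = psa.yearly_qalys[:, j] - psa.yearly_qalys[:, k]
        per_year = pd.DataFrame(
            {
                "month": 12 * np.arange(1, dy_cost.shape[1] + 1),
                "delta_cost": dy_cost.mean(axis=0),
                "delta_qaly": dy_qaly.mean(axis=0),
            }
        )
        per_year["icer"] = [
            icer(dc, dq).ratio for dc, dq in zip(per_year["delta_cost"], per_year["delta_qaly"])
        ]
        det = None
        if deterministic and scenario in deterministic and comparator in deterministic:
            det = icer(
                deterministic[scenario][0] - deterministic[comparator][0],
                deterministic[scenario][1] - deterministic[comparator][1],
            )
        ce_plane = pd.DataFrame(
            {"draw": np.arange(psa.n_draws), "delta_qaly": d_qaly, "delta_cost": d_cost}
        )
        comps.append(
            ComparisonSummary(
                scenario=scenario,
                comparator=comparator,
                mean_delta_cost=mean_dc,
                mean_delta_qaly=mean_dq,
                icer_ratio_of_means=icer(mean_dc, mean_dq),
                icer_mean_of_ratios=mean_of_ratios,
                deterministic_icer=det,
                dominant=(mean_dq > 0 and mean_dc < 0),
                per_year=per_year,
                ce_plane=ce_plane,
            )
        )
    return CEASummary(scenario_table=scenario_table, comparisons=comps)
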