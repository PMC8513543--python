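"""Dynamic cohort Markov engine.

The cohort is propagated in expectation over monthly cycles. Occupancy
lives on a (groups, modality, tenure) grid: tenure slots 1-12 are the
first-year tunnel, slot "13+" collects everyone beyond the first year.
Each cycle, remainers advance one tenure slot (capped at "13+"),
modality switchers re-enter the destination's tenure-1 slot, deaths
leave to the absorbing Death state, and incident patients enter the
tenure-1 slot of their starting modality.

Costs and QALYs accrue on start-of-cycle occupancy, at 1/12 of the
annual value of the state's modality/phase, discounted with the smooth
monthly factor (1 + r)^(-t/12). There is no half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import EconomicInputs, ModelParameters
from .states import (  # noqa: F401  (re-exported: the state space lives with the engine)
    FIRST_YEAR_MONTHS,
    IDX_DEATH,
    IDX_REMAIN,
    MODALITIES,
    N_MODALITIES,
    N_TENURE,
    StateSpace,
    build_state_space,
    phase_of_tenure,
)


@dataclass
class CohortVector:
    """Nonnegative expected occupancy on the (G, 6, 13) live grid plus
    the absorbing Death count."""

    occupancy: np.ndarray
    deaths: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim == 2:
            self.occupancy = self.occupancy[None, ...]
        if self.occupancy.shape[1:] != (N_MODALITIES, N_TENURE):
            raise ValueError("occupancy must have shape (G, 6, 13)")
        if not np.isfinite(self.occupancy).all() or (self.occupancy < 0).any():
            raise ValueError("occupancy must be finite and nonnegative")

    @property
    def live_total(self) -> float:
        return float(self.occupancy.sum())

    def modality_totals(self) -> np.ndarray:
        return self.occupancy.sum(axis=(0, 2))


@dataclass(frozen=True)
class _CompiledRows:
    """Pre-split transition rows for fast stepping."""

    stay: np.ndarray  # (6, 2) remain probability
    switch: np.ndarray  # (2, 6, 6) origin -> destination, diagonal zero
    death: np.ndarray  # (6, 2)


def _compile(monthly: np.ndarray) -> _CompiledRows:
    switch = np.stack([monthly[:, 0, :N_MODALITIES], monthly[:, 1, :N_MODALITIES]])
    return _CompiledRows(
        stay=monthly[:, :, IDX_REMAIN],
        switch=switch,
        death=monthly[:, :, IDX_DEATH],
    )


def _step(occ: np.ndarray, rows: _CompiledRows, inflow: np.ndarray) -> tuple[np.ndarray, float]:
    """One cycle. ``occ`` (G, 6, 13), ``inflow`` (G, 6)."""
    new = np.zeros_like(occ)
    stay_f = rows.stay[:, 0][None, :, None]  # (1, 6, 1)
    stay_s = rows.stay[:, 1][None, :]
    # remainers advance one tenure slot; "13+" retains itself
    new[:, :, 1:] = occ[:, :, : N_TENURE - 1] * stay_f
    new[:, :, N_TENURE - 1] += occ[:, :, N_TENURE - 1] * stay_s
    fy = occ[:, :, : FIRST_YEAR_MONTHS].sum(axis=2)  # (G, 6)
    sy = occ[:, :, N_TENURE - 1]
    # switchers enter the destination's first tenure slot
    new[:, :, 0] += fy @ rows.switch[0] + sy @ rows.switch[1] + inflow
    deaths = float((fy * rows.death[:, 0]).sum() + (sy * rows.death[:, 1]).sum())
    if new.min() < -1e-9:  # must be impossible under row-stochastic inputs
        raise RuntimeError("negative occupancy produced by step")
    np.clip(new, 0.0, None, out=new)
    return new, deaths


def step_cohort(
    v: CohortVector, monthly: np.ndarray, inflow: np.ndarray | dict[str, float]
) -> CohortVector:
    """Advance the cohort one cycle under monthly transition rows.

    ``inflow`` is per-modality incident counts, as a (G, 6) array or a
    {modality: count} mapping (unstratified).
    """
    from .registry import validate_monthly_rows

    validate_monthly_rows(np.asarray(monthly, dtype=float))
    occ = v.occupancy
    if isinstance(inflow, dict):
        arr = np.zeros((occ.shape[0], N_MODALITIES))
        for name, count in inflow.items():
            arr[:, MODALITIES.index(name)] = count
        inflow = arr
    inflow = np.asarray(inflow, dtype=float)
    if (inflow < 0).any():
        raise ValueError("inflow must be nonnegative")
    new, deaths = _step(occ, _compile(np.asarray(monthly, dtype=float)), inflow)
    return CohortVector(occupancy=new, deaths=v.deaths + deaths)


@dataclass
class CohortTrace:
    """Occupancy per cycle 0..H plus cumulative deaths and inflow."""

    occupancy: np.ndarray  # (H+1, G, 6, 13)
    cumulative_deaths: np.ndarray  # (H+1,)
    cumulative_inflow: np.ndarray  # (H+1,)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def live_totals(self) -> np.ndarray:
        return self.occupancy.sum(axis=(1, 2, 3))

    def conservation_error(self) -> float:
        """Max relative violation of: initial + inflow = live + deaths."""
        totals = self.live_totals()
        lhs = totals[0] + self.cumulative_inflow
        rhs = totals + self.cumulative_deaths
        scale = max(1.0, float(lhs.max()))
        return float(np.abs(lhs - rhs).max() / scale)

    def to_frame(self) -> pd.DataFrame:
        """Long per-cycle frame: modality totals, deaths, inflow."""
        mod_totals = self.occupancy.sum(axis=(1, 3))  # (H+1, 6)
        df = pd.DataFrame(mod_totals, columns=list(MODALITIES))
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        df["death"] = self.cumulative_deaths
        df["cumulative_inflow"] = self.cumulative_inflow
        return df


def discount_factor(annual_rate: float, cycle: int | np.ndarray) -> float | np.ndarray:
    """Smooth monthly discount multiplier (1 + r)^(-cycle/12)."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(cycle) / 12.0)


@dataclass
class OutcomeSeries:
    """Per-model-year (non-cumulative) discounted costs and QALYs."""

    yearly_costs: np.ndarray
    yearly_qalys: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.yearly_costs.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.yearly_qalys.sum())

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(1, len(self.yearly_costs) + 1)
        return pd.DataFrame(
            {"month": years * 12, "cost": self.yearly_costs, "qalys": self.yearly_qalys}
        )


def _state_value_grid(values: np.ndarray) -> np.ndarray:
    """(6, 2) per-phase annual values -> (6, 13) per tenure slot."""
    grid = np.empty((N_MODALITIES, N_TENURE))
    grid[:, :FIRST_YEAR_MONTHS] = values[:, 0][:, None]
    grid[:, FIRST_YEAR_MONTHS:] = values[:, 1][:, None]
    return grid


def accumulate_outcomes(
    trace: CohortTrace,
    econ: EconomicInputs,
    extra_cost_stream: np.ndarray | None = None,
) -> OutcomeSeries:
    """Discounted costs and QALYs from a cohort trace.

    Accrual uses start-of-cycle occupancy: cycle t (t = 0..H-1)
    contributes occupancy(t) x annual value / 12, discounted at
    (1+r)^(-t/12). The intervention cost stream entry for cycle t+1 is
    discounted with the same exponent t/12 and added to costs. Yearly
    outputs are per-year, not cumulative.
    """
    horizon = trace.horizon
    if extra_cost_stream is not None:
        extra_cost_stream = np.asarray(extra_cost_stream, dtype=float)
        if extra_cost_stream.shape != (horizon,):
            raise ValueError("extra_cost_stream length must equal the trace horizon")
    occ = trace.occupancy[:horizon]  # start-of-cycle occupancy for cycles 1..H
    cost_grid = _state_value_grid(econ.annual_cost) / 12.0
    util_grid = _state_value_grid(econ.utility) / 12.0
    per_cycle_cost = np.einsum("tgms,ms->t", occ, cost_grid)
    per_cycle_qaly = np.einsum("tgms,ms->t", occ, util_grid)
    if extra_cost_stream is not None:
        per_cycle_cost = per_cycle_cost + extra_cost_stream
    t = np.arange(horizon)
    disc_cost = per_cycle_cost * discount_factor(econ.cost_discount_rate, t)
    disc_qaly = per_cycle_qaly * discount_factor(econ.qaly_discount_rate, t)
    n_years = horizon // 12 + (1 if horizon % 12 else 0)
    yearly_costs = np.zeros(n_years)
    yearly_qalys = np.zeros(n_years)
    for y in range(n_years):
        sl = slice(12 * y, min(12 * (y + 1), horizon))
        yearly_costs[y] = disc_cost[sl].sum()
        yearly_qalys[y] = disc_qaly[sl].sum()
    return OutcomeSeries(yearly_costs=yearly_costs, yearly_qalys=yearly_qalys)


@dataclass
class ModelResult:
    """Trace plus outcomes of one deterministic run."""

    trace: CohortTrace
    outcomes: OutcomeSeries


def run_model(params: ModelParameters, horizon: int | None = None) -> ModelResult:
    """Run the dynamic cohort model for ``horizon`` cycles (default: the
    inflow horizon) and accumulate discounted outcomes."""
    H = horizon if horizon is not None else params.horizon
    if H < 1 or H > params.horizon:
        raise ValueError(f"horizon must be in 1..{params.horizon}")
    occ = params.initial.copy()
    trace = np.empty((H + 1,) + occ.shape)
    trace[0] = occ
    deaths = np.zeros(H + 1)
    inflow_cum = np.zeros(H + 1)
    pre = _compile(params.monthly)
    post = _compile(params.monthly_alt) if params.monthly_alt is not None else pre
    for t in range(1, H + 1):
        rows = post if (params.monthly_alt is not None and t >= params.effect_start_cycle) else pre
        inflow = params.inflow_at(t)
        occ, d = _step(occ, rows, inflow)
        trace[t] = occ
        deaths[t] = deaths[t - 1] + d
        inflow_cum[t] = inflow_cum[t - 1] + inflow.sum()
    cohort_trace = CohortTrace(
        occupancy=trace, cumulative_deaths=deaths, cumulative_inflow=inflow_cum
    )
    stream = None if params.cost_stream is None else params.cost_stream[:H]
    outcomes = accumulate_outcomes(cohort_trace, params.econ, stream)
    return ModelResult(trace=cohort_trace, outcomes=outcomes)
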