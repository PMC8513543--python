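"""Intervention scenarios as parameter transformations.

The home-based education programme is modelled purely as an increase in
living-donor kidney transplantation (LDKT): a fraction

    extra_ldkt = eligible_fraction x completion_fraction x ldkt_effect_fraction

of incident patients receives an extra LDKT. Two thirds of that effect
is pre-emptive (incident patients start in LDKT instead of their
original modality); the remaining third is an added dialysis-to-LDKT
monthly transition mass, spread evenly over a 24-month window and
applied to the dialysis first-year rows with proportional
renormalization of all other destinations. State utilities and costs
are untouched; the intervention's own cost is charged per completer in
the cycle of entry. Everything starts after the first six cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import fixtures as fx
from .params import ModelParameters
from .states import DIALYSIS_INDICES, IDX_LDKT, N_MODALITIES


@dataclass(frozen=True)
class ScenarioSpec:
    """One implementation scenario of the education programme."""

    label: str
    ldkt_effect_fraction: float
    eligible_fraction: float = fx.ELIGIBLE_FRACTION
    completion_fraction: float = fx.COMPLETION_FRACTION
    preemptive_share: float = fx.PREEMPTIVE_SHARE
    effect_start_cycle: int = fx.EFFECT_START_CYCLE
    intervention_unit_cost: float = fx.INTERVENTION_COST
    dialysis_to_ldkt_window_months: int = 24

    def __post_init__(self) -> None:
        for name in (
            "ldkt_effect_fraction",
            "eligible_fraction",
            "completion_fraction",
            "preemptive_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_start_cycle < 1:
            raise ValueError("effect_start_cycle must be >= 1")
        if self.label == "base_case" and self.ldkt_effect_fraction != 0.0:
            raise ValueError("base_case must have zero LDKT effect")

    @property
    def extra_ldkt_per_incident(self) -> float:
        """Extra LDKTs per incident patient (the effect size)."""
        return self.eligible_fraction * self.completion_fraction * self.ldkt_effect_fraction

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "ldkt_effect_fraction": self.ldkt_effect_fraction,
            "eligible_fraction": self.eligible_fraction,
            "completion_fraction": self.completion_fraction,
            "preemptive_share": self.preemptive_share,
            "effect_start_cycle": self.effect_start_cycle,
            "intervention_unit_cost": self.intervention_unit_cost,
            "dialysis_to_ldkt_window_months": self.dialysis_to_ldkt_window_months,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        return cls(**data)


def base_case() -> ScenarioSpec:
    return ScenarioSpec(label="base_case", ldkt_effect_fraction=0.0)


def optimistic() -> ScenarioSpec:
    """35% of completers undergo an LDKT."""
    return ScenarioSpec(label="optimistic", ldkt_effect_fraction=fx.OPTIMISTIC_LDKT_FRACTION)


def pessimistic() -> ScenarioSpec:
    """18% of completers undergo an LDKT."""
    return ScenarioSpec(label="pessimistic", ldkt_effect_fraction=fx.PESSIMISTIC_LDKT_FRACTION)


PRESETS = {"base_case": base_case, "optimistic": optimistic, "pessimistic": pessimistic}


def renormalize_with_ldkt_boost(p: np.ndarray, delta: float) -> np.ndarray:
    """Add LDKT probability mass and proportionally lower the rest.

    ``p`` is a destination probability vector (LDKT at index 5, any
    number of further destinations) summing to 1. The LDKT entry gains
    ``delta``; every other entry is scaled by (1 - p_L - delta)/(1 - p_L)
    so the vector still sums to 1.
    """
    p = np.asarray(p, dtype=float)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    p_l = float(p[IDX_LDKT])
    if p_l + delta > 1 + 1e-12:
        raise ValueError("LDKT probability would exceed 1")
    if delta == 0:
        return p.copy()
    if p_l >= 1:
        raise ValueError("cannot boost a row already fully LDKT")
    out = p * ((1.0 - p_l - delta) / (1.0 - p_l))
    out[IDX_LDKT] = p_l + delta
    return out


def apply_intervention(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Transform base-case parameters into an intervention scenario.

    From ``effect_start_cycle`` onward, (a) the pre-emptive share of the
    effect reallocates incident inflow from non-LDKT starting modalities
    to LDKT (proportionally, conserving total inflow), and (b) the rest
    becomes added dialysis-to-LDKT monthly transition mass on the four
    dialysis first-year rows. A per-cycle intervention cost stream
    (charged per completer among incident patients) is attached. A
    zero-effect spec returns parameters equal to the input.
    """
    extra = spec.extra_ldkt_per_incident
    if extra == 0.0:
        return params.copy()

    inflow_alt = params.inflow.copy()
    start_idx = spec.effect_start_cycle - 1
    rows = inflow_alt[start_idx:]  # (cycles, G, 6) view
    totals = rows.sum(axis=2)
    non_ldkt = rows.sum(axis=2) - rows[:, :, IDX_LDKT]
    move = extra * spec.preemptive_share * totals
    move = np.minimum(move, non_ldkt)  # cannot reallocate more than exists
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(non_ldkt > 0, 1.0 - move / np.where(non_ldkt > 0, non_ldkt, 1.0), 1.0)
    for m in range(N_MODALITIES):
        if m == IDX_LDKT:
            continue
        rows[:, :, m] *= scale
    rows[:, :, IDX_LDKT] += move

    monthly_alt = params.monthly.copy()
    delta = extra * (1.0 - spec.preemptive_share) / spec.dialysis_to_ldkt_window_months
    for m in DIALYSIS_INDICES:
        monthly_alt[m, 0] = renormalize_with_ldkt_boost(monthly_alt[m, 0], delta)

    stream = intervention_cost_stream(params.inflow.sum(axis=(1, 2)), spec)
    return replace(
        params,
        monthly_alt=monthly_alt,
        inflow_alt=inflow_alt,
        effect_start_cycle=spec.effect_start_cycle,
        cost_stream=stream,
    )


def intervention_cost_stream(monthly_incidence: np.ndarray, spec: ScenarioSpec) -> np.ndarray:
    """Per-cycle intervention cost (EUR): incident patients x eligible
    fraction x completion fraction x unit cost, zero before the effect
    start cycle and always zero under a zero-effect spec."""
    monthly_incidence = np.asarray(monthly_incidence, dtype=float)
    if (monthly_incidence < 0).any():
        raise ValueError("incidence must be nonnegative")
    stream = np.zeros_like(monthly_incidence)
    if spec.extra_ldkt_per_incident == 0.0:
        return stream
    start_idx = spec.effect_start_cycle - 1
    stream[start_idx:] = (
        monthly_incidence[start_idx:]
        * spec.eligible_fraction
        * spec.completion_fraction
        * spec.intervention_unit_cost
    )
    return stream
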