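"""Published reference parameters for the Dutch KRT programme evaluation.

Point estimates and standard errors of the health-state utilities (EQ-5D
meta-analysis values), annual therapy costs (2018 euros, claims-based),
the baseline prevalent population on 1 January 2018, the intervention
scenario constants, and the headline deterministic totals of the original
nationwide evaluation. These ship verbatim so that worked examples and
priors can be built without access to the (non-public) Dutch Renal
Registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .states import MODALITIES

#: Prevalent patients per modality on 1-1-2018 (N = 16,917).
BASELINE_PREVALENCE: dict[str, int] = {
    "CHD": 5516,
    "HHD": 238,
    "CAPD": 402,
    "CCPD": 517,
    "DDKT": 4817,
    "LDKT": 5427,
}

#: EQ-5D utility weight per modality (annual QALY weight) and SE.
UTILITIES: dict[str, float] = {
    "CHD": 0.56,
    "HHD": 0.56,
    "CAPD": 0.58,
    "CCPD": 0.58,
    "DDKT": 0.81,
    "LDKT": 0.81,
}
UTILITY_SES: dict[str, float] = {
    "CHD": 0.033,
    "HHD": 0.033,
    "CAPD": 0.043,
    "CCPD": 0.043,
    "DDKT": 0.046,
    "LDKT": 0.046,
}

#: Annual therapy cost rows, EUR/year. Dialysis rows cover the first and
#: subsequent years jointly; transplant costs differ by phase.
ANNUAL_COSTS: dict[tuple[str, str], float] = {
    ("CHD", "first_year"): 98_914.0,
    ("CHD", "subsequent"): 98_914.0,
    ("HHD", "first_year"): 92_967.0,
    ("HHD", "subsequent"): 92_967.0,
    ("CAPD", "first_year"): 82_824.0,
    ("CAPD", "subsequent"): 82_824.0,
    ("CCPD", "first_year"): 96_043.0,
    ("CCPD", "subsequent"): 96_043.0,
    ("DDKT", "first_year"): 106_210.0,
    ("DDKT", "subsequent"): 23_212.0,
    ("LDKT", "first_year"): 78_297.0,
    ("LDKT", "subsequent"): 22_716.0,
}

#: One SE per printed cost row; dialysis rows are a single parameter.
COST_ROW_SES: dict[tuple[str, str | None], float] = {
    ("CHD", None): 367.0,
    ("HHD", None): 958.0,
    ("CAPD", None): 1935.0,
    ("CCPD", None): 1124.0,
    ("DDKT", "first_year"): 1009.0,
    ("DDKT", "subsequent"): 162.0,
    ("LDKT", "first_year"): 980.0,
    ("LDKT", "subsequent"): 149.0,
}

INTERVENTION_COST: float = 2811.0
INTERVENTION_COST_SE: float = 281.0  # 10% relative SE

#: Scenario constants of the home-based education programme.
ELIGIBLE_FRACTION: float = 0.35
COMPLETION_FRACTION: float = 0.425
OPTIMISTIC_LDKT_FRACTION: float = 0.35
PESSIMISTIC_LDKT_FRACTION: float = 0.18
PREEMPTIVE_SHARE: float = 2.0 / 3.0
EFFECT_START_CYCLE: int = 7  # effect enters after the first six cycles
EFFECT_RELATIVE_SE: float = 0.20

COST_DISCOUNT_RATE: float = 0.04
QALY_DISCOUNT_RATE: float = 0.015

#: Headline deterministic 10-year totals of the original evaluation
#: (total discounted cost in EUR and total discounted QALYs per scenario).
REFERENCE_DETERMINISTIC_TOTALS: dict[str, dict[str, float]] = {
    "base_case": {"cost": 7_836_028_014.0, "qalys": 136_927.0},
    "optimistic": {"cost": 7_728_204_065.0, "qalys": 138_335.0},
    "pessimistic": {"cost": 7_773_028_092.0, "qalys": 137_779.0},
}

#: Demographic composition used when prevalence or incidence must be split
#: over the six groups. The 15/85 diabetic split is the published baseline
#: characteristic; the age split is a plausible fixture consistent with a
#: mean age of 61, not a published breakdown.
DIABETIC_FRACTION: float = 0.15
AGE_BAND_WEIGHTS: dict[str, float] = {"0-44": 0.15, "45-64": 0.40, "65+": 0.45}


@dataclass(frozen=True)
class ReferenceParameters:
    """Bundle of the printed reference values."""

    prevalence: dict[str, int] = field(default_factory=lambda: dict(BASELINE_PREVALENCE))
    utilities: dict[str, float] = field(default_factory=lambda: dict(UTILITIES))
    utility_ses: dict[str, float] = field(default_factory=lambda: dict(UTILITY_SES))
    annual_costs: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(ANNUAL_COSTS)
    )
    cost_row_ses: dict[tuple[str, str | None], float] = field(
        default_factory=lambda: dict(COST_ROW_SES)
    )
    intervention_cost: float = INTERVENTION_COST
    intervention_cost_se: float = INTERVENTION_COST_SE
    eligible_fraction: float = ELIGIBLE_FRACTION
    completion_fraction: float = COMPLETION_FRACTION
    optimistic_ldkt_fraction: float = OPTIMISTIC_LDKT_FRACTION
    pessimistic_ldkt_fraction: float = PESSIMISTIC_LDKT_FRACTION
    preemptive_share: float = PREEMPTIVE_SHARE
    effect_start_cycle: int = EFFECT_START_CYCLE
    cost_discount_rate: float = COST_DISCOUNT_RATE
    qaly_discount_rate: float = QALY_DISCOUNT_RATE

    @property
    def total_prevalence(self) -> int:
        return sum(self.prevalence.values())

    def cost_row_se(self, modality: str, phase: str) -> float:
        """SE of the cost row governing (modality, phase)."""
        if (modality, None) in self.cost_row_ses:
            return self.cost_row_ses[(modality, None)]
        return self.cost_row_ses[(modality, phase)]


def load_reference_parameters() -> ReferenceParameters:
    """Return the printed reference parameter bundle.

    Values are returned verbatim; all six modalities are guaranteed
    present in every per-modality mapping.
    """
    ref = ReferenceParameters()
    for m in MODALITIES:
        assert m in ref.prevalence and m in ref.utilities
    return ref
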