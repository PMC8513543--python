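"""Model parameter containers and their YAML serialization.

``ModelParameters`` is everything one deterministic run needs: monthly
transition rows, monthly incident inflow, the initial prevalent cohort,
economic inputs and discount rates, plus (optionally) the
intervention-adjusted transition/inflow arrays that take over from the
effect start cycle and a per-cycle intervention cost stream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .estimation import AnnualTransitionCounts, dirichlet_concentration, monthly_rows_from_counts
from .fixtures import (
    AGE_BAND_WEIGHTS,
    COST_DISCOUNT_RATE,
    DIABETIC_FRACTION,
    QALY_DISCOUNT_RATE,
    ReferenceParameters,
    load_reference_parameters,
)
from .registry import validate_monthly_rows
from .states import (
    GROUPS,
    MODALITIES,
    MODALITY_INDEX,
    N_GROUPS,
    N_MODALITIES,
    N_TENURE,
    PHASES,
)


@dataclass
class EconomicInputs:
    """Annual costs (EUR/year) and utilities per modality x phase, plus
    annual discount rates. Death carries zero cost and zero utility."""

    annual_cost: np.ndarray  # (6, 2)
    utility: np.ndarray  # (6, 2)
    cost_discount_rate: float = COST_DISCOUNT_RATE
    qaly_discount_rate: float = QALY_DISCOUNT_RATE

    def __post_init__(self) -> None:
        self.annual_cost = np.asarray(self.annual_cost, dtype=float)
        self.utility = np.asarray(self.utility, dtype=float)
        if self.annual_cost.shape != (N_MODALITIES, 2) or self.utility.shape != (N_MODALITIES, 2):
            raise ValueError("annual_cost and utility must have shape (6, 2)")
        if (self.annual_cost < 0).any():
            raise ValueError("costs must be nonnegative")
        if (self.utility < 0).any() or (self.utility > 1).any():
            raise ValueError("utilities must lie in [0, 1]")
        if self.cost_discount_rate < 0 or self.qaly_discount_rate < 0:
            raise ValueError("discount rates must be nonnegative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EconomicInputs):
            return NotImplemented
        return (
            np.array_equal(self.annual_cost, other.annual_cost)
            and np.array_equal(self.utility, other.utility)
            and self.cost_discount_rate == other.cost_discount_rate
            and self.qaly_discount_rate == other.qaly_discount_rate
        )


def economic_inputs_from_reference(
    ref: ReferenceParameters | None = None,
) -> EconomicInputs:
    """Economic inputs from the published reference parameter set."""
    ref = ref or load_reference_parameters()
    cost = np.zeros((N_MODALITIES, 2))
    util = np.zeros((N_MODALITIES, 2))
    for m, name in enumerate(MODALITIES):
        for p, phase in enumerate(PHASES):
            cost[m, p] = ref.annual_costs[(name, phase)]
            util[m, p] = ref.utilities[name]
    return EconomicInputs(
        annual_cost=cost,
        utility=util,
        cost_discount_rate=ref.cost_discount_rate,
        qaly_discount_rate=ref.qaly_discount_rate,
    )


def initial_occupancy(
    prevalence: dict[str, float] | None = None, stratify: bool = False
) -> np.ndarray:
    """Initial cohort (G, 6, 13): prevalent patients sit in the "13+"
    (subsequent-year) tenure slot of their modality. Stratified runs
    split each modality count over the six groups by the documented
    demographic weights."""
    if prevalence is None:
        prevalence = dict(load_reference_parameters().prevalence)
    n_groups = N_GROUPS if stratify else 1
    occ = np.zeros((n_groups, N_MODALITIES, N_TENURE))
    if stratify:
        weights = np.array(
            [
                AGE_BAND_WEIGHTS[g.age_band]
                * (DIABETIC_FRACTION if g.diabetic else 1 - DIABETIC_FRACTION)
                for g in GROUPS
            ]
        )
        weights = weights / weights.sum()
    else:
        weights = np.array([1.0])
    for name, count in prevalence.items():
        occ[:, MODALITY_INDEX[name], N_TENURE - 1] = count * weights
    return occ


@dataclass
class ModelParameters:
    """Inputs of one model run.

    ``monthly`` governs all cycles; when ``monthly_alt``/``inflow_alt``
    are present they take over from ``effect_start_cycle`` onward
    (intervention scenarios). ``inflow`` rows are cycles 1..H.
    """

    monthly: np.ndarray  # (6, 2, 8)
    inflow: np.ndarray  # (H, G, 6)
    initial: np.ndarray  # (G, 6, 13)
    econ: EconomicInputs
    monthly_alt: np.ndarray | None = None
    inflow_alt: np.ndarray | None = None
    effect_start_cycle: int = 7
    cost_stream: np.ndarray | None = None  # (H,), EUR per cycle, undiscounted
    dirichlet: np.ndarray | None = None  # (6, 2, 8) annual-count concentrations
    dirichlet_no_data: np.ndarray | None = None  # (6, 2) mask
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.monthly = np.asarray(self.monthly, dtype=float)
        self.inflow = np.asarray(self.inflow, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        validate_monthly_rows(self.monthly)
        if self.monthly_alt is not None:
            self.monthly_alt = np.asarray(self.monthly_alt, dtype=float)
            validate_monthly_rows(self.monthly_alt)
        if self.inflow.ndim != 3 or self.inflow.shape[2] != N_MODALITIES:
            raise ValueError("inflow must have shape (H, G, 6)")
        if (self.inflow < 0).any():
            raise ValueError("inflow must be nonnegative")
        if self.initial.shape != (self.inflow.shape[1], N_MODALITIES, N_TENURE):
            raise ValueError("initial occupancy shape must match inflow groups")
        if (self.initial < 0).any():
            raise ValueError("occupancy must be nonnegative")
        if self.effect_start_cycle < 1:
            raise ValueError("effect_start_cycle must be >= 1")

    @property
    def horizon(self) -> int:
        return self.inflow.shape[0]

    @property
    def n_groups(self) -> int:
        return self.inflow.shape[1]

    def inflow_at(self, cycle: int) -> np.ndarray:
        """Incident inflow (G, 6) applied at ``cycle`` (1-based)."""
        src = self.inflow
        if self.inflow_alt is not None and cycle >= self.effect_start_cycle:
            src = self.inflow_alt
        return src[cycle - 1]

    def monthly_at(self, cycle: int) -> np.ndarray:
        if self.monthly_alt is not None and cycle >= self.effect_start_cycle:
            return self.monthly_alt
        return self.monthly

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelParameters):
            return NotImplemented

        def eq(a, b) -> bool:
            if a is None or b is None:
                return (a is None) == (b is None)
            return np.array_equal(np.asarray(a), np.asarray(b))

        return (
            eq(self.monthly, other.monthly)
            and eq(self.inflow, other.inflow)
            and eq(self.initial, other.initial)
            and self.econ == other.econ
            and eq(self.monthly_alt, other.monthly_alt)
            and eq(self.inflow_alt, other.inflow_alt)
            and self.effect_start_cycle == other.effect_start_cycle
            and eq(self.cost_stream, other.cost_stream)
        )


def estimate_parameters(
    registry,
    econ: EconomicInputs | None = None,
    horizon_years: int = 10,
    stratify: bool = False,
    locf_min_nonzero: int = 3,
    prevalence: dict[str, float] | None = None,
) -> ModelParameters:
    """Full estimation pipeline: registry -> run-ready parameters."""
    from .estimation import count_annual_transitions, fit_incidence_models
    from .registry import count_annual_incidence

    counts = count_annual_transitions(registry)
    monthly, warnings = monthly_rows_from_counts(counts)
    conc, no_data = dirichlet_concentration(counts)
    forecast = fit_incidence_models(
        count_annual_incidence(registry),
        horizon_years=horizon_years,
        locf_min_nonzero=locf_min_nonzero,
    )
    return ModelParameters(
        monthly=monthly,
        inflow=forecast.inflow_array(stratify=stratify),
        initial=initial_occupancy(prevalence, stratify=stratify),
        econ=econ or economic_inputs_from_reference(),
        dirichlet=conc,
        dirichlet_no_data=no_data,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# YAML round trip


def _opt(arr: np.ndarray | None):
    return None if arr is None else np.asarray(arr).tolist()


def params_to_dict(params: ModelParameters) -> dict:
    return {
        "monthly": params.monthly.tolist(),
        "inflow": params.inflow.tolist(),
        "initial": params.initial.tolist(),
        "monthly_alt": _opt(params.monthly_alt),
        "inflow_alt": _opt(params.inflow_alt),
        "effect_start_cycle": params.effect_start_cycle,
        "cost_stream": _opt(params.cost_stream),
        "dirichlet": _opt(params.dirichlet),
        "dirichlet_no_data": _opt(params.dirichlet_no_data),
        "econ": {
            "annual_cost": params.econ.annual_cost.tolist(),
            "utility": params.econ.utility.tolist(),
            "cost_discount_rate": params.econ.cost_discount_rate,
            "qaly_discount_rate": params.econ.qaly_discount_rate,
        },
        "modalities": list(MODALITIES),
    }


def params_from_dict(data: dict) -> ModelParameters:
    econ = EconomicInputs(
        annual_cost=np.array(data["econ"]["annual_cost"]),
        utility=np.array(data["econ"]["utility"]),
        cost_discount_rate=float(data["econ"]["cost_discount_rate"]),
        qaly_discount_rate=float(data["econ"]["qaly_discount_rate"]),
    )

    def arr(key):
        v = data.get(key)
        return None if v is None else np.array(v)

    return ModelParameters(
        monthly=np.array(data["monthly"]),
        inflow=np.array(data["inflow"]),
        initial=np.array(data["initial"]),
        econ=econ,
        monthly_alt=arr("monthly_alt"),
        inflow_alt=arr("inflow_alt"),
        effect_start_cycle=int(data.get("effect_start_cycle", 7)),
        cost_stream=arr("cost_stream"),
        dirichlet=arr("dirichlet"),
        dirichlet_no_data=None if data.get("dirichlet_no_data") is None
        else np.array(data["dirichlet_no_data"], dtype=bool),
    )


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def load_parameters(path) -> ModelParameters:
    with open(path, encoding="utf-8") as fh:
        return params_from_dict(yaml.safe_load(fh))
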