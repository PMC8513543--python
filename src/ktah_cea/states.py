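"""State-space vocabulary for the kidney replacement therapy (KRT) model.

Six treatment modalities, six demographic groups (three age bands crossed
with diabetic status), and a two-phase tenure split: transition behaviour
in the first year on a modality differs from subsequent years, so every
modality carries 12 monthly tunnel slots plus one "13+" slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

#: Treatment modalities. Death is an absorbing model state, not a modality.
MODALITIES: tuple[str, ...] = ("CHD", "HHD", "CAPD", "CCPD", "DDKT", "LDKT")
DIALYSIS_MODALITIES: tuple[str, ...] = ("CHD", "HHD", "CAPD", "CCPD")
TRANSPLANT_MODALITIES: tuple[str, ...] = ("DDKT", "LDKT")

MODALITY_INDEX: dict[str, int] = {m: i for i, m in enumerate(MODALITIES)}
N_MODALITIES = len(MODALITIES)
IDX_LDKT = MODALITY_INDEX["LDKT"]
DIALYSIS_INDICES: tuple[int, ...] = tuple(MODALITY_INDEX[m] for m in DIALYSIS_MODALITIES)

#: Destination axis of a transition row: the six modalities, then death,
#: then "remain" (stay on the origin modality for another month).
DESTINATIONS: tuple[str, ...] = MODALITIES + ("death", "remain")
IDX_DEATH = len(MODALITIES)
IDX_REMAIN = len(MODALITIES) + 1
N_DESTINATIONS = len(DESTINATIONS)

#: Tenure slots per modality: months 1..12 (first year) and "13+".
N_TENURE = 13
FIRST_YEAR_MONTHS = 12

PHASES: tuple[str, str] = ("first_year", "subsequent")
PHASE_INDEX = {"first_year": 0, "subsequent": 1}

AGE_BANDS: tuple[str, ...] = ("0-44", "45-64", "65+")


class DemographicGroup(NamedTuple):
    """One of the six mutually exclusive patient groups."""

    age_band: str
    diabetic: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.age_band}/{'diabetic' if self.diabetic else 'non-diabetic'}"


GROUPS: tuple[DemographicGroup, ...] = tuple(
    DemographicGroup(age, diab) for age in AGE_BANDS for diab in (True, False)
)
GROUP_INDEX: dict[DemographicGroup, int] = {g: i for i, g in enumerate(GROUPS)}
N_GROUPS = len(GROUPS)


def phase_of_tenure(tenure_month: int | str) -> str:
    """Phase of a tenure slot: months 1-12 are ``first_year``, "13+" is
    ``subsequent``."""
    if tenure_month == "13+" or (isinstance(tenure_month, int) and tenure_month >= 13):
        return "subsequent"
    if isinstance(tenure_month, int) and 1 <= tenure_month <= FIRST_YEAR_MONTHS:
        return "first_year"
    raise ValueError(f"invalid tenure slot: {tenure_month!r}")


@dataclass(frozen=True)
class StateSpace:
    """Live states are modality x tenure slot, optionally replicated per
    demographic group, plus a single absorbing Death state."""

    stratified: bool

    @property
    def groups(self) -> tuple[DemographicGroup, ...]:
        return GROUPS if self.stratified else ()

    @property
    def n_group_axes(self) -> int:
        return N_GROUPS if self.stratified else 1

    @property
    def n_live(self) -> int:
        return self.n_group_axes * N_MODALITIES * N_TENURE

    @property
    def n_states(self) -> int:
        return self.n_live + 1  # + absorbing Death

    def phase(self, modality: str, tenure_month: int | str) -> str:
        if modality not in MODALITY_INDEX:
            raise KeyError(modality)
        return phase_of_tenure(tenure_month)


def build_state_space(stratify_by_group: bool = False) -> StateSpace:
    """6 modalities x 13 tenure slots (+ Death); 79 states unstratified,
    469 when replicated over the 6 demographic groups."""
    return StateSpace(stratified=bool(stratify_by_group))
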