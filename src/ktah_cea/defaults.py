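"""Default synthetic generating process for the registry emulator.

The real national registry rates are not public; these monthly rates and
incidence trends are a synthetic stand-in chosen once to be
order-of-magnitude realistic for a Western-European KRT programme:
dialysis mortality around 10-15%/year, transplant mortality a few
percent per year, roughly 2,000 incident patients per year with a slowly
rising living-donor share and a slowly declining in-centre hemodialysis
share. They define the study conditions for all synthetic experiments
and are not tuned to reproduce any published total.
"""

from __future__ import annotations

from .registry import (
    GroundTruth,
    IncidenceTrend,
    default_group_weights,
    monthly_rows_from_events,
)
from .states import GROUPS, MODALITIES, DemographicGroup

#: Monthly event probabilities per (origin, phase); remainder is "remain".
DEFAULT_MONTHLY_EVENTS: dict[tuple[str, str], dict[str, float]] = {
    ("CHD", "first_year"): {
        "HHD": 0.002, "CAPD": 0.003, "CCPD": 0.003,
        "DDKT": 0.006, "LDKT": 0.007, "death": 0.013,
    },
    ("CHD", "subsequent"): {
        "HHD": 0.001, "CAPD": 0.001, "CCPD": 0.001,
        "DDKT": 0.004, "LDKT": 0.004, "death": 0.011,
    },
    ("HHD", "first_year"): {
        "CHD": 0.008, "CAPD": 0.001, "CCPD": 0.001,
        "DDKT": 0.006, "LDKT": 0.008, "death": 0.008,
    },
    ("HHD", "subsequent"): {
        "CHD": 0.005, "CAPD": 0.0005, "CCPD": 0.0005,
        "DDKT": 0.004, "LDKT": 0.005, "death": 0.007,
    },
    ("CAPD", "first_year"): {
        "CHD": 0.010, "HHD": 0.001, "CCPD": 0.006,
        "DDKT": 0.007, "LDKT": 0.008, "death": 0.009,
    },
    ("CAPD", "subsequent"): {
        "CHD": 0.008, "HHD": 0.0005, "CCPD": 0.004,
        "DDKT": 0.005, "LDKT": 0.005, "death": 0.008,
    },
    ("CCPD", "first_year"): {
        "CHD": 0.010, "HHD": 0.001, "CAPD": 0.004,
        "DDKT": 0.007, "LDKT": 0.008, "death": 0.009,
    },
    ("CCPD", "subsequent"): {
        "CHD": 0.008, "HHD": 0.0005, "CAPD": 0.003,
        "DDKT": 0.005, "LDKT": 0.005, "death": 0.008,
    },
    ("DDKT", "first_year"): {
        "CHD": 0.004, "HHD": 0.0003, "CAPD": 0.0005, "CCPD": 0.0005,
        "LDKT": 0.0005, "death": 0.003,
    },
    ("DDKT", "subsequent"): {
        "CHD": 0.003, "HHD": 0.0002, "CAPD": 0.0003, "CCPD": 0.0003,
        "LDKT": 0.0003, "death": 0.002,
    },
    ("LDKT", "first_year"): {
        "CHD": 0.003, "HHD": 0.0003, "CAPD": 0.0004, "CCPD": 0.0004,
        "DDKT": 0.0004, "death": 0.002,
    },
    ("LDKT", "subsequent"): {
        "CHD": 0.002, "HHD": 0.0002, "CAPD": 0.0003, "CCPD": 0.0003,
        "DDKT": 0.0003, "death": 0.0015,
    },
}

#: Starting-modality shares of incident patients and per-year relative
#: drift (linear, as a fraction of the base count per calendar year).
TOTAL_ANNUAL_INCIDENCE: float = 2000.0
START_SHARES: dict[str, float] = {
    "CHD": 0.55, "HHD": 0.01, "CAPD": 0.10, "CCPD": 0.08, "DDKT": 0.06, "LDKT": 0.20,
}
ANNUAL_DRIFT: dict[str, float] = {
    "CHD": -0.010, "HHD": 0.0, "CAPD": -0.005, "CCPD": 0.0, "DDKT": 0.005, "LDKT": 0.030,
}


def default_incidence_trends(
    total_per_year: float = TOTAL_ANNUAL_INCIDENCE,
) -> dict[tuple[DemographicGroup, str], IncidenceTrend]:
    weights = default_group_weights()
    trends = {}
    for g in GROUPS:
        for m in MODALITIES:
            base = total_per_year * weights[g] * START_SHARES[m]
            trends[(g, m)] = IncidenceTrend(
                "linear", intercept=base, slope=base * ANNUAL_DRIFT[m]
            )
    return trends


def default_ground_truth(total_per_year: float = TOTAL_ANNUAL_INCIDENCE) -> GroundTruth:
    """The default synthetic generating process (see module docstring)."""
    return GroundTruth(
        monthly=monthly_rows_from_events(DEFAULT_MONTHLY_EVENTS),
        incidence=default_incidence_trends(total_per_year),
        group_weights=default_group_weights(),
    )
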