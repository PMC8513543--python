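"""Transition and incidence estimation from a registry table.

Annual transition counts follow the evaluation's convention: first-year
probabilities come from the first 12 months of each modality spell,
subsequent-year probabilities pool spell-years 2-4 (spell-months 12-47);
later spell-years contribute nothing. Raw annual counts double as
Dirichlet concentrations for the probabilistic sensitivity analysis, and
annual probabilities are converted to the monthly cycle length by
constant-hazard compounding of the total leaving probability with
proportional cause-specific allocation.

Incidence is forecast per (demographic group, modality): linear and
log-linear (exponential) least-squares fits on annual incident counts,
family chosen by residual sum of squares, with last-observation-carried-
forward for sparse series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import RegistryTable
from .states import (
    FIRST_YEAR_MONTHS,
    GROUP_INDEX,
    GROUPS,
    IDX_DEATH,
    IDX_REMAIN,
    MODALITIES,
    MODALITY_INDEX,
    N_DESTINATIONS,
    N_GROUPS,
    N_MODALITIES,
    DemographicGroup,
)

#: Pooling window for subsequent-year rates: spell-years 2, 3 and 4.
SUBSEQUENT_SPELL_YEARS = (2, 3, 4)


class NoDataError(ValueError):
    """Raised when an estimate is requested from an empty count cell."""


@dataclass
class AnnualTransitionCounts:
    """Annual event counts per (origin modality, phase).

    ``counts[m, p, d]`` holds events from origin ``m`` in phase ``p``
    (0 = first year, 1 = subsequent) to destination ``d`` on the
    8-element destination axis (6 modalities, death, remain). Remain
    counts may be fractional because censored spell-years contribute
    partial exposure.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_MODALITIES, 2, N_DESTINATIONS):
            raise ValueError("counts must have shape (6, 2, 8)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def annual_probabilities(self) -> np.ndarray:
        """Empirical annual probability vectors; rows with no data are NaN."""
        totals = self.totals()[..., None]
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals > 0, self.counts / totals, np.nan)
        return probs


def count_annual_transitions(registry: RegistryTable) -> AnnualTransitionCounts:
    """Tabulate annual transition events and exposure from a registry.

    Each modality spell contributes at most one event (at the spell's
    end, attributed to the spell-year in which it falls) plus one remain
    count per fully survived spell-year; censored partial years add
    fractional remain exposure. Only spell-year 1 (first year) and
    spell-years 2-4 (pooled subsequent) are used.
    """
    eps = registry.episodes
    if len(eps) == 0:
        raise NoDataError("registry contains no episodes")
    counts = np.zeros((N_MODALITIES, 2, N_DESTINATIONS))
    horizon = registry.horizon_month

    eps = eps.sort_values(["patient_id", "start_month"])
    next_modality = eps.groupby("patient_id")["modality"].shift(-1)

    for (_, row), nxt in zip(eps.iterrows(), next_modality):
        m = MODALITY_INDEX[row["modality"]]
        start = int(row["start_month"])
        end = row["end_month"]
        open_episode = end is None or (isinstance(end, float) and math.isnan(end))
        length = (horizon if open_episode else int(end)) - start
        reason = None if open_episode else row["end_reason"]
        if reason == "switch":
            if not isinstance(nxt, str):
                raise ValueError("switch episode without a successor episode")
            dest = MODALITY_INDEX[nxt]
            event = True
        elif reason == "death":
            dest = IDX_DEATH
            event = True
        else:  # censored or open
            dest = None
            event = False

        for spell_year in (1,) + SUBSEQUENT_SPELL_YEARS:
            phase = 0 if spell_year == 1 else 1
            y0, y1 = 12 * (spell_year - 1), 12 * spell_year
            if length <= y0:
                break
            if event:
                if length <= y1:
                    counts[m, phase, dest] += 1
                    break
                counts[m, phase, IDX_REMAIN] += 1
            else:
                if length >= y1:
                    counts[m, phase, IDX_REMAIN] += 1
                else:
                    counts[m, phase, IDX_REMAIN] += (length - y0) / 12.0
                    break
    return AnnualTransitionCounts(counts)


def annual_to_monthly(annual_events: np.ndarray) -> np.ndarray:
    """Convert an annual cause-specific event vector to monthly.

    The total monthly leaving probability q solves 1-(1-q)^12 = A where
    A is the total annual leaving probability; cause-specific shares are
    preserved proportionally. A = 1 gives the degenerate q = 1; A > 1 is
    rejected.
    """
    annual_events = np.asarray(annual_events, dtype=float)
    if (annual_events < -1e-15).any():
        raise ValueError("annual event probabilities must be nonnegative")
    total = float(annual_events.sum())
    if total > 1 + 1e-12:
        raise ValueError(f"total annual leaving probability {total} exceeds 1")
    if total <= 0:
        return np.zeros_like(annual_events)
    q = 1.0 if total >= 1 else 1.0 - (1.0 - total) ** (1.0 / 12.0)
    return annual_events * (q / total)


def monthly_to_annual(monthly_events: np.ndarray) -> np.ndarray:
    """Inverse of :func:`annual_to_monthly` (12-cycle compounding)."""
    monthly_events = np.asarray(monthly_events, dtype=float)
    q = float(monthly_events.sum())
    if q <= 0:
        return np.zeros_like(monthly_events)
    total = 1.0 - (1.0 - q) ** 12
    return monthly_events * (total / q)


def monthly_rows_from_counts(counts: AnnualTransitionCounts) -> tuple[np.ndarray, list[str]]:
    """Monthly (6, 2, 8) transition rows from annual counts.

    Origin/phase cells without data fall back to a pure-remain row and
    are reported in the warnings list. Every returned row sums to 1.
    """
    monthly = np.zeros((N_MODALITIES, 2, N_DESTINATIONS))
    warnings: list[str] = []
    probs = counts.annual_probabilities()
    for m in range(N_MODALITIES):
        for p in range(2):
            row = probs[m, p]
            if np.isnan(row).any():
                monthly[m, p, IDX_REMAIN] = 1.0
                warnings.append(
                    f"no data for origin {MODALITIES[m]} phase "
                    f"{'first_year' if p == 0 else 'subsequent'}; using pure-remain row"
                )
                continue
            events = annual_to_monthly(row[:IDX_REMAIN])
            monthly[m, p, :IDX_REMAIN] = events
            monthly[m, p, IDX_REMAIN] = 1.0 - events.sum()
    return monthly, warnings


def dirichlet_concentration(counts: AnnualTransitionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet concentration vectors per origin/phase.

    Concentrations are the raw annual counts (destinations + remain), so
    the implied Dirichlet mean equals the empirical annual probability
    vector. Returns (concentration array, no-data mask); drawing from a
    flagged cell is the caller's error.
    """
    conc = counts.counts.copy()
    no_data = counts.totals() <= 0
    return conc, no_data


# ---------------------------------------------------------------------------
# Incidence forecasting


@dataclass
class SeriesFit:
    """Fitted annual-incidence trend for one (group, modality) series."""

    family: str  # linear | exponential | locf
    coefficients: tuple[float, ...]
    observed: np.ndarray  # annual counts over the calibration window
    forecast_annual: np.ndarray  # next `horizon_years` annual counts, clipped >= 0

    def monthly_inflow(self) -> np.ndarray:
        """Monthly inflow over the forecast horizon (annual count / 12)."""
        return np.repeat(self.forecast_annual, 12) / 12.0


@dataclass
class IncidenceForecast:
    """All 36 fitted (group, modality) series plus monthly inflow."""

    series: dict[tuple[DemographicGroup, str], SeriesFit]
    horizon_years: int = 10

    def __post_init__(self) -> None:
        expected = {(g, m) for g in GROUPS for m in MODALITIES}
        if set(self.series) != expected:
            raise ValueError("incidence forecast must cover all 36 (group, modality) series")
        for fit in self.series.values():
            if (fit.forecast_annual < 0).any():
                raise ValueError("forecast inflow must be nonnegative")

    def inflow_array(self, stratify: bool = False) -> np.ndarray:
        """Monthly inflow of shape (horizon_cycles, G, 6); G = 1 pools groups."""
        cycles = 12 * self.horizon_years
        out = np.zeros((cycles, N_GROUPS, N_MODALITIES))
        for (g, m), fit in self.series.items():
            out[:, GROUP_INDEX[g], MODALITY_INDEX[m]] += fit.monthly_inflow()
        if stratify:
            return out
        return out.sum(axis=1, keepdims=True)


def _fit_one_series(
    years: np.ndarray, counts: np.ndarray, horizon_years: int, locf_min_nonzero: int
) -> SeriesFit:
    t = years - years.min()
    t_future = np.arange(t.max() + 1, t.max() + 1 + horizon_years)
    nonzero = int((counts > 0).sum())
    if nonzero < locf_min_nonzero:
        last = float(counts[-1])
        return SeriesFit("locf", (last,), counts, np.full(horizon_years, max(0.0, last)))

    slope, intercept = np.polyfit(t, counts, 1)
    rss_linear = float(((np.polyval([slope, intercept], t) - counts) ** 2).sum())
    best = ("linear", (float(intercept), float(slope)),
            np.clip(np.polyval([slope, intercept], t_future), 0.0, None), rss_linear)

    if (counts > 0).all():
        b, a = np.polyfit(t, np.log(counts), 1)  # log y = a + b t
        pred = np.exp(a + b * t)
        rss_exp = float(((pred - counts) ** 2).sum())
        if rss_exp < rss_linear:  # ties go to linear
            best = ("exponential", (float(a), float(b)),
                    np.clip(np.exp(a + b * t_future), 0.0, None), rss_exp)

    family, coef, forecast, _ = best
    return SeriesFit(family, coef, counts, forecast)


def fit_incidence_models(
    annual_incident_counts: pd.DataFrame,
    horizon_years: int = 10,
    locf_min_nonzero: int = 3,
) -> IncidenceForecast:
    """Fit and forecast the 36 annual incidence series.

    ``annual_incident_counts`` needs columns year, age_band, diabetic,
    modality, count; missing (group, modality) combinations are treated
    as all-zero series (LOCF of zero). Requires >= 2 calibration years.
    """
    df = annual_incident_counts
    years = np.sort(df["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least 2 calibration years for incidence regression")
    series: dict[tuple[DemographicGroup, str], SeriesFit] = {}
    indexed = df.set_index(["age_band", "diabetic", "modality"]).sort_index()
    for g in GROUPS:
        for m in MODALITIES:
            key = (g.age_band, g.diabetic, m)
            if key in indexed.index:
                sub = indexed.loc[[key]].set_index("year")["count"]
                counts = np.array([float(sub.get(y, 0.0)) for y in years])
            else:
                counts = np.zeros(len(years))
            series[(g, m)] = _fit_one_series(years, counts, horizon_years, locf_min_nonzero)
    return IncidenceForecast(series=series, horizon_years=horizon_years)
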