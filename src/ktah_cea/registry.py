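"""Registry-style synthetic patient histories.

The Dutch Renal Registry that parameterised the original evaluation is
not public, so this module generates event tables with the same shape:
one row per treatment episode (patient, modality, start month, end month,
end reason), demographics per patient, and a multi-year calibration
window. Ground-truth monthly transition rates and annual incidence trends
are known by construction, which is what makes parameter-recovery tests
possible.

Calendar time is expressed as integer month indices from 0; calendar year
``y`` of the window covers months ``12*y .. 12*y+11``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fixtures import AGE_BAND_WEIGHTS, DIABETIC_FRACTION
from .states import (
    FIRST_YEAR_MONTHS,
    GROUPS,
    IDX_DEATH,
    IDX_REMAIN,
    MODALITIES,
    MODALITY_INDEX,
    N_DESTINATIONS,
    N_MODALITIES,
    DemographicGroup,
)

END_REASONS = ("switch", "death", "censored")

REGISTRY_COLUMNS = (
    "patient_id",
    "age_band",
    "diabetic",
    "modality",
    "start_month",
    "end_month",
    "end_reason",
)


@dataclass(frozen=True)
class TreatmentEpisode:
    """One contiguous spell on a modality.

    The episode occupies months ``[start_month, end_month)``; the event
    named by ``end_reason`` happens at the transition into ``end_month``.
    ``end_month=None`` denotes an open episode.
    """

    patient_id: str
    modality: str
    start_month: int
    end_month: int | None
    end_reason: str | None

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_INDEX:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.end_month is not None:
            if self.end_reason not in END_REASONS:
                raise ValueError(f"closed episode needs an end reason, got {self.end_reason!r}")
            if self.end_month < self.start_month:
                raise ValueError("end_month < start_month")

    @property
    def length(self) -> int | None:
        return None if self.end_month is None else self.end_month - self.start_month


@dataclass(frozen=True)
class IncidenceTrend:
    """Annual incident-count trend for one (group, modality) series.

    ``kind`` is ``linear`` (intercept + slope*t) or ``exponential``
    (intercept * growth**t), with t = years since the window start.
    Negative linear values are clipped to zero.
    """

    kind: str
    intercept: float
    slope: float = 0.0  # linear: per-year increment; exponential: growth factor

    def __call__(self, year_index: int) -> float:
        if self.kind == "linear":
            return max(0.0, self.intercept + self.slope * year_index)
        if self.kind == "exponential":
            return max(0.0, self.intercept * self.slope**year_index)
        raise ValueError(f"unknown trend kind {self.kind!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Known generating process for a synthetic registry.

    ``monthly`` has shape (6, 2, 8): per (origin modality, phase) a
    probability vector over the 8 destinations (6 modalities, death,
    remain). Diagonal (origin->origin) entries must be zero. Incidence
    trends are per (group, modality); group weights govern demographics
    at entry.
    """

    monthly: np.ndarray
    incidence: dict[tuple[DemographicGroup, str], IncidenceTrend]
    group_weights: dict[DemographicGroup, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "monthly", np.asarray(self.monthly, dtype=float))
        validate_monthly_rows(self.monthly)

    def trend(self, group: DemographicGroup, modality: str) -> IncidenceTrend:
        return self.incidence.get((group, modality), IncidenceTrend("linear", 0.0))

    def with_monthly(self, monthly: np.ndarray) -> "GroundTruth":
        return replace(self, monthly=np.asarray(monthly, dtype=float))


def validate_monthly_rows(monthly: np.ndarray) -> None:
    """Reject invalid monthly transition arrays before any simulation."""
    if monthly.shape != (N_MODALITIES, 2, N_DESTINATIONS):
        raise ValueError(f"monthly rates must have shape (6, 2, 8), got {monthly.shape}")
    if not np.isfinite(monthly).all() or (monthly < -1e-15).any():
        raise ValueError("monthly rates must be finite and nonnegative")
    sums = monthly.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("each monthly row must sum to 1 (remain included)")
    for m in range(N_MODALITIES):
        if (monthly[m, :, m] > 1e-12).any():
            raise ValueError(f"origin->origin probability must be zero ({MODALITIES[m]})")


def monthly_rows_from_events(
    events: dict[tuple[str, str], dict[str, float]],
) -> np.ndarray:
    """Build a (6, 2, 8) monthly array from sparse event specifications.

    ``events`` maps (origin modality, phase) to {destination: monthly
    probability}; destinations are modality codes or ``"death"``. The
    remain probability is the complement. Unspecified rows are pure
    remain.
    """
    monthly = np.zeros((N_MODALITIES, 2, N_DESTINATIONS))
    monthly[:, :, IDX_REMAIN] = 1.0
    for (origin, phase), dests in events.items():
        m = MODALITY_INDEX[origin]
        p = 0 if phase == "first_year" else 1
        row = np.zeros(N_DESTINATIONS)
        for dest, prob in dests.items():
            j = IDX_DEATH if dest == "death" else MODALITY_INDEX[dest]
            if j == m:
                raise ValueError("origin->origin probability must be zero")
            row[j] = prob
        leaving = row.sum()
        if leaving > 1 + 1e-12:
            raise ValueError(f"monthly leaving probability > 1 for {origin}/{phase}")
        row[IDX_REMAIN] = max(0.0, 1.0 - leaving)
        monthly[m, p] = row
    return monthly


@dataclass
class RegistryTable:
    """Event table emulating a national KRT registry."""

    episodes: pd.DataFrame  # patient_id, modality, start_month, end_month, end_reason
    demographics: pd.DataFrame  # patient_id, age_band, diabetic
    calibration_window: tuple[int, int]  # [first_year, last_year] inclusive

    def __post_init__(self) -> None:
        first, last = self.calibration_window
        if last - first + 1 < 2:
            raise ValueError("calibration window must span at least 2 years")

    @property
    def n_years(self) -> int:
        first, last = self.calibration_window
        return last - first + 1

    @property
    def horizon_month(self) -> int:
        return 12 * self.n_years

    @property
    def n_patients(self) -> int:
        return self.demographics["patient_id"].nunique()

    def group_of(self, patient_id: str) -> DemographicGroup:
        row = self.demographics.loc[self.demographics["patient_id"] == patient_id].iloc[0]
        return DemographicGroup(row["age_band"], bool(row["diabetic"]))

    def to_frame(self) -> pd.DataFrame:
        """Flat per-episode frame with demographics merged in."""
        df = self.episodes.merge(self.demographics, on="patient_id", how="left")
        return df[list(REGISTRY_COLUMNS)]

    def to_csv(self, path) -> None:
        df = self.to_frame().copy()
        df["end_month"] = df["end_month"].astype("Int64")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, calibration_window: tuple[int, int] | None = None) -> "RegistryTable":
        try:
            df = pd.read_csv(path, dtype={"patient_id": str})
        except pd.errors.ParserError as exc:  # surface the offending line
            raise ValueError(f"malformed registry CSV {path}: {exc}") from exc
        missing = set(REGISTRY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
        df["end_month"] = pd.to_numeric(df["end_month"], errors="coerce")
        df["diabetic"] = df["diabetic"].astype(bool)
        episodes = df[["patient_id", "modality", "start_month", "end_month", "end_reason"]].copy()
        demographics = (
            df[["patient_id", "age_band", "diabetic"]].drop_duplicates("patient_id").reset_index(drop=True)
        )
        if calibration_window is None:
            last_month = int(
                np.nanmax([df["end_month"].max(), df["start_month"].max()])
            )
            calibration_window = (0, max(1, (last_month - 1) // 12))
        return cls(episodes=episodes, demographics=demographics, calibration_window=calibration_window)


def default_group_weights() -> dict[DemographicGroup, float]:
    """Entry weights over the six groups: published 15/85 diabetic split
    crossed with the documented age-band fixture."""
    return {
        g: AGE_BAND_WEIGHTS[g.age_band]
        * (DIABETIC_FRACTION if g.diabetic else 1.0 - DIABETIC_FRACTION)
        for g in GROUPS
    }


def _simulate_patient(
    monthly_cum: np.ndarray,
    start_modality: int,
    entry_month: int,
    horizon: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int | None, str]]:
    """Simulate one patient's history month by month.

    Returns (modality, start, end, reason) tuples. ``monthly_cum`` is the
    (6, 2, 8) array of cumulative probabilities over destinations.
    """
    spells: list[tuple[int, int, int | None, str]] = []
    m = start_modality
    spell_start = entry_month
    tenure = 1
    t = entry_month
    while True:
        if t + 1 >= horizon:
            # window ends after this month: censor the open spell
            spells.append((m, spell_start, horizon, "censored"))
            return spells
        phase = 0 if tenure <= FIRST_YEAR_MONTHS else 1
        u = rng.random()
        dest = int(np.searchsorted(monthly_cum[m, phase], u, side="right"))
        t += 1
        if dest == IDX_REMAIN or dest > IDX_REMAIN:
            tenure += 1
            continue
        if dest == IDX_DEATH:
            spells.append((m, spell_start, t, "death"))
            return spells
        # modality switch
        spells.append((m, spell_start, t, "switch"))
        m = dest
        spell_start = t
        tenure = 1


def generate_registry(
    truth: GroundTruth,
    n_years: int,
    seed: int,
    first_year: int = 0,
) -> RegistryTable:
    """Simulate a registry under a known generating process.

    Incident patients arrive per the annual incidence trends (Poisson
    counts, entry month uniform within the year); each history then
    evolves month by month under the ground-truth monthly rows until
    death or the end of the calibration window (censoring). Deterministic
    given ``seed``.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2 (calibration window spans >= 2 years)")
    validate_monthly_rows(truth.monthly)
    rng = np.random.default_rng(seed)
    horizon = 12 * n_years
    monthly_cum = np.cumsum(truth.monthly, axis=2)

    episode_rows: list[tuple] = []
    demo_rows: list[tuple] = []
    pid = 0
    for year in range(n_years):
        for group in GROUPS:
            for modality in MODALITIES:
                lam = truth.trend(group, modality)(year)
                if lam <= 0:
                    continue
                n_new = int(rng.poisson(lam))
                if n_new == 0:
                    continue
                entries = rng.integers(12 * year, 12 * (year + 1), size=n_new)
                for entry in entries:
                    patient = f"P{pid:07d}"
                    pid += 1
                    demo_rows.append((patient, group.age_band, group.diabetic))
                    spells = _simulate_patient(
                        monthly_cum, MODALITY_INDEX[modality], int(entry), horizon, rng
                    )
                    for m_idx, s, e, reason in spells:
                        episode_rows.append((patient, MODALITIES[m_idx], s, e, reason))

    episodes = pd.DataFrame(
        episode_rows, columns=["patient_id", "modality", "start_month", "end_month", "end_reason"]
    )
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "age_band", "diabetic"])
    return RegistryTable(
        episodes=episodes,
        demographics=demographics,
        calibration_window=(first_year, first_year + n_years - 1),
    )


def validate_registry(registry: RegistryTable) -> list[str]:
    """Report structural violations; an empty report means the table is valid.

    Checks: closed episodes have nonnegative duration and a known end
    reason; per-patient episodes are non-overlapping and contiguous; no
    episode starts after a death; every episode's patient has
    demographics.
    """
    report: list[str] = []
    demo_ids = set(registry.demographics["patient_id"])
    eps = registry.episodes
    missing = set(eps["patient_id"]) - demo_ids
    for pid in sorted(missing):
        report.append(f"patient {pid}: missing demographics")
    for pid, grp in eps.groupby("patient_id", sort=True):
        grp = grp.sort_values("start_month")
        prev_end: float | None = None
        dead = False
        for _, row in grp.iterrows():
            start, end, reason = row["start_month"], row["end_month"], row["end_reason"]
            closed = not (end is None or (isinstance(end, float) and math.isnan(end)))
            if dead:
                report.append(f"patient {pid}: episode starts after death (month {start})")
            if closed:
                if end < start:
                    report.append(f"patient {pid}: negative episode duration at month {start}")
                if reason not in END_REASONS:
                    report.append(f"patient {pid}: unknown end reason {reason!r}")
                if reason == "death":
                    dead = True
            if prev_end is not None:
                if start < prev_end:
                    report.append(f"patient {pid}: overlapping episodes at month {start}")
                elif start > prev_end:
                    report.append(f"patient {pid}: gap between episodes at month {start}")
            prev_end = end if closed else math.inf
    return report


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "monthly": truth.monthly.tolist(),
        "incidence": [
            {
                "age_band": g.age_band,
                "diabetic": g.diabetic,
                "modality": m,
                "kind": trend.kind,
                "intercept": trend.intercept,
                "slope": trend.slope,
            }
            for (g, m), trend in truth.incidence.items()
        ],
        "group_weights": [
            {"age_band": g.age_band, "diabetic": g.diabetic, "weight": w}
            for g, w in truth.group_weights.items()
        ],
    }


def truth_from_dict(data: dict) -> GroundTruth:
    incidence = {
        (DemographicGroup(r["age_band"], bool(r["diabetic"])), r["modality"]): IncidenceTrend(
            r["kind"], r["intercept"], r["slope"]
        )
        for r in data["incidence"]
    }
    weights = {
        DemographicGroup(r["age_band"], bool(r["diabetic"])): r["weight"]
        for r in data.get("group_weights", [])
    }
    return GroundTruth(
        monthly=np.array(data["monthly"]), incidence=incidence, group_weights=weights
    )


def save_ground_truth(truth: GroundTruth, path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth_to_dict(truth), fh, sort_keys=False)


def load_ground_truth(path) -> GroundTruth:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return truth_from_dict(yaml.safe_load(fh))


def count_annual_incidence(registry: RegistryTable) -> pd.DataFrame:
    """Annual incident patients per (calendar year, group, modality).

    A patient is incident in the calendar year of their first episode,
    attributed to the modality they started on. All year x group x
    modality combinations of the calibration window are present (zero
    filled).
    """
    first_year, last_year = registry.calibration_window
    eps = registry.episodes.sort_values("start_month").drop_duplicates("patient_id")
    df = eps.merge(registry.demographics, on="patient_id", how="left")
    df["year"] = first_year + df["start_month"] // 12
    counts = (
        df.groupby(["year", "age_band", "diabetic", "modality"]).size().rename("count").reset_index()
    )
    full = pd.MultiIndex.from_product(
        [
            range(first_year, last_year + 1),
            list(dict.fromkeys(g.age_band for g in GROUPS)),
            [True, False],
            list(MODALITIES),
        ],
        names=["year", "age_band", "diabetic", "modality"],
    )
    counts = (
        counts.set_index(["year", "age_band", "diabetic", "modality"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    return counts
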