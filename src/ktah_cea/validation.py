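"""Recovery diagnostics: estimated vs ground-truth transition rates.

Used by tests and the reproduction script to check that estimation on a
synthetic registry recovers the generating monthly/annual probabilities
within binomial Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import AnnualTransitionCounts, monthly_rows_from_counts, monthly_to_annual
from .states import IDX_REMAIN, N_MODALITIES


def annual_truth_from_monthly(monthly: np.ndarray) -> np.ndarray:
    """(6, 2, 8) annual probability rows implied by monthly truth rows:
    constant-hazard compounding over 12 cycles with proportional cause
    shares; the remain entry is the 12-month stay probability."""
    annual = np.zeros_like(monthly)
    for m in range(N_MODALITIES):
        for p in range(2):
            events = monthly_to_annual(monthly[m, p, :IDX_REMAIN])
            annual[m, p, :IDX_REMAIN] = events
            annual[m, p, IDX_REMAIN] = 1.0 - events.sum()
    return annual


@dataclass
class RecoveryReport:
    """Z-scores of estimated annual and monthly probabilities vs truth."""

    annual_z: np.ndarray  # (6, 2, 8), NaN where truth prob is 0 or no exposure
    monthly_z: np.ndarray
    exposures: np.ndarray  # (6, 2) total annual counts

    @property
    def max_abs_annual_z(self) -> float:
        return float(np.nanmax(np.abs(self.annual_z)))

    @property
    def max_abs_monthly_z(self) -> float:
        return float(np.nanmax(np.abs(self.monthly_z)))

    def within(self, n_se: float = 3.0) -> bool:
        return (
            self.max_abs_annual_z <= n_se and self.max_abs_monthly_z <= n_se
        )


def recovery_report(
    counts: AnnualTransitionCounts, truth_monthly: np.ndarray
) -> RecoveryReport:
    """Compare estimates from annual counts against ground truth.

    Annual z-scores use the binomial SE sqrt(a(1-a)/N) at the true
    annual probability a with N the origin/phase exposure. Monthly
    z-scores use the first-order (delta-method) SE obtained by scaling
    the annual SE with the monthly/annual probability ratio. Cells with
    zero true probability or zero exposure are NaN.
    """
    truth_annual = annual_truth_from_monthly(truth_monthly)
    est_annual = counts.annual_probabilities()
    est_monthly, _ = monthly_rows_from_counts(counts)
    exposures = counts.totals()

    annual_z = np.full_like(truth_annual, np.nan)
    monthly_z = np.full_like(truth_annual, np.nan)
    for m in range(N_MODALITIES):
        for p in range(2):
            n = exposures[m, p]
            if n <= 0:
                continue
            for d in range(truth_annual.shape[2]):
                a = truth_annual[m, p, d]
                if a <= 0 or a >= 1:
                    continue
                se_a = np.sqrt(a * (1 - a) / n)
                annual_z[m, p, d] = (est_annual[m, p, d] - a) / se_a
                if d != IDX_REMAIN:
                    ratio = truth_monthly[m, p, d] / a
                    se_m = se_a * ratio
                    monthly_z[m, p, d] = (est_monthly[m, p, d] - truth_monthly[m, p, d]) / se_m
    return RecoveryReport(annual_z=annual_z, monthly_z=monthly_z, exposures=exposures)
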