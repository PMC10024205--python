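"""Workforce-supply projection.

Translates loan-repayment/scholarship budget scenarios into serving dentist
full-time-equivalents in shortage areas per year, then into dentist-density
changes and their effects on preventive-care utilization and caries risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

AWARD_TYPES = ("scholarship", "loan_repayment", "students_to_service")


@dataclass
class NhscProgram:
    """Award pipeline constants (packaged defaults are documented assumptions)."""

    baseline_awards: dict = field(
        default_factory=lambda: {"scholarship": 20.0, "loan_repayment": 260.0,
                                 "students_to_service": 20.0}
    )
    commitment_years: dict = field(
        default_factory=lambda: {"scholarship": 2, "loan_repayment": 2,
                                 "students_to_service": 3}
    )
    default_rate: float = 0.05        # fraction of awardees never serving
    retention_continuation: float = 0.85  # annual post-commitment continuation
    retention_years: int = 8          # length of the post-commitment tail
    partial_allocation_weight: float = 1.0  # relative FTE weight of partial-HPSA strata

    def validate(self) -> None:
        for t, a in self.baseline_awards.items():
            if a < 0:
                raise ConfigurationError(f"negative baseline awards for {t}")
        for t, c in self.commitment_years.items():
            if c < 1:
                raise ConfigurationError(f"commitment for {t} must be >= 1 year")
        for name in ("default_rate", "retention_continuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} outside [0,1]: {v}")

    def service_profile(self, award_type: str, extension: int = 0) -> np.ndarray:
        """Expected FTE per original award, by year since award.

        Commitment years contribute (1 - default); each post-commitment year k
        contributes (1 - default) * continuation**(k+1), for the configured
        retention horizon.
        """
        c = self.commitment_years[award_type] + extension
        keep = 1.0 - self.default_rate
        tail = [keep * self.retention_continuation ** (k + 1)
                for k in range(self.retention_years)]
        return np.array([keep] * c + tail)

    def fte_years_per_award(self, award_type: str, extension: int = 0) -> float:
        return float(self.service_profile(award_type, extension).sum())


def project_awards(prog: NhscProgram, growth: float, years: int) -> dict:
    """Awards per year by type under compound annual budget growth.

    Year ``t`` carries ``baseline * (1 + growth) ** t`` awards of each type
    (budget shares by type are held constant, and cost per award is fixed, so
    budget growth maps one-to-one onto award growth).
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    if growth <= -1.0:
        raise ConfigurationError("growth must be > -100%")
    prog.validate()
    factor = (1.0 + growth) ** np.arange(years)
    return {t: prog.baseline_awards[t] * factor for t in AWARD_TYPES}


def awards_to_fte(awards: dict, prog: NhscProgram, extension: int = 0,
                  years: int | None = None) -> np.ndarray:
    """Serving FTE per calendar year implied by an award stream.

    Each award cohort serves its commitment (net of defaults) and then decays
    through the retention tail; yearly FTE is the sum over active cohorts
    (a convolution of the award stream with the service profile), truncated at
    ``years`` (default: length of the award stream).
    """
    streams = {t: np.asarray(a, dtype=float) for t, a in awards.items()}
    horizon = years if years is not None else max(len(a) for a in streams.values())
    fte = np.zeros(horizon)
    for t, a in streams.items():
        if (a < 0).any():
            raise ConfigurationError(f"negative awards in stream for {t}")
        profile = prog.service_profile(t, extension)
        conv = np.convolve(a, profile)[:horizon]
        fte[:len(conv)] += conv
    return fte


def fte_ledger_total(awards: dict, prog: NhscProgram, extension: int = 0) -> float:
    """Total (untruncated) FTE-years implied by an award stream.

    Equals sum over cohorts of awards x (1 - default) x (commitment +
    retention tail); used to check conservation of the FTE ledger.
    """
    return float(sum(np.sum(a) * prog.fte_years_per_award(t, extension)
                     for t, a in awards.items()))


def density_delta(fte, population: float):
    """Dentists per 1000 children implied by an FTE count (scalar or per-year)."""
    if population <= 0:
        raise ConfigurationError("population must be > 0")
    return 1000.0 * np.asarray(fte, dtype=float) / population


def allocate_density(fte, whole_population: float, partial_population: float,
                     partial_weight: float = 0.5) -> dict:
    """Split an FTE stream across whole/partial shortage strata.

    FTE are allocated in proportion to child population, with partial-county
    strata down-weighted by ``partial_weight``; returns per-1000-children
    density deltas by stratum level.
    """
    if whole_population <= 0 and partial_population <= 0:
        raise ConfigurationError("shortage-area population must be > 0")
    denom = whole_population + partial_weight * partial_population
    fte = np.asarray(fte, dtype=float)
    d_whole = 1000.0 * fte / denom
    return {"whole": d_whole, "partial": partial_weight * d_whole}


@dataclass
class SupplyEffect:
    """Effect of dentist density on utilization and caries risk."""

    #: percentage-point utilization increase per +1 dentist per 10 000 children
    utilization_slope_pp: float = 1.67
    #: caries odds ratio per +1 dentist per 1000 children
    caries_or: float = 0.46

    def validate(self) -> None:
        if self.caries_or <= 0:
            raise ConfigurationError("caries odds ratio must be > 0")


def apply_supply_effect(delta, eff: SupplyEffect, baseline_utilization):
    """Map a density delta (per 1000 children) to outcomes.

    Returns ``(utilization, caries log-odds shift)``: utilization gains
    ``slope x (delta x 10)`` percentage points (clamped to [0, 1]; the x10
    converts per-1000 to per-10 000), and the odds ratio is raised to the
    fractional density power, i.e. shift = delta x ln(OR).
    """
    eff.validate()
    delta = np.asarray(delta, dtype=float)
    if (delta < 0).any():
        raise ConfigurationError("density delta must be >= 0")
    util = np.clip(np.asarray(baseline_utilization, dtype=float)
                   + eff.utilization_slope_pp / 100.0 * (delta * 10.0), 0.0, 1.0)
    shift = delta * math.log(eff.caries_or)
    return util, shift
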