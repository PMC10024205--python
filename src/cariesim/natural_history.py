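"""Annual-cycle disease dynamics and calibration.

Each simulated year an individual may accrue at most one new carious tooth
event; new events are treated or go untreated depending on whether the
individual used preventive care that year; prevalent untreated caries can
progress to abscess and tooth loss; all-cause mortality is applied last.

Event order within a cycle is fixed for reproducibility:
  (1) utilization draw, (2) new-caries draw, (3) treated/untreated
  assignment, (4) complication draws on prevalent untreated caries,
  (5) mortality, then ages advance by one year.

Calibration fits one log-odds adjustment per age group so that the pooled
cross-sectional caries prevalence observed over the simulated horizon matches
configured age-band targets, using common random numbers so each
one-dimensional search is deterministic and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import (TAG_ABSCESS, TAG_CARIES, TAG_MORTALITY, TAG_TOOTHLOSS,
                   TAG_TREATMENT, TAG_UTILIZATION, uniforms)
from .errors import CalibrationError, ConfigurationError
from .popsynth import (AGE_GROUPS, HPSA_LEVELS, INCOMES, MEASURE_BANDS, RACES,
                       RESIDENCES, SEXES, Population)

#: annual caries risk applies through this age; older cohort members accrue
#: no new events (the model covers childhood/adolescent onset only).
MAX_RISK_AGE = 19


@dataclass
class RiskModel:
    """Additive logistic model of annual caries risk plus progression hazards."""

    intercept: dict = field(
        default_factory=lambda: {"0-5": 0.0, "6-12": 0.0, "13-19": 0.0}
    )
    #: log-odds of annual caries risk by single year of age (0..19).  The
    #: packaged shape concentrates incidence around school entry and flattens
    #: through adolescence, consistent with a stationary cross-sectional
    #: prevalence profile; per-age-group calibration shifts it additively.
    age_logit: list = field(
        default_factory=lambda: [-3.87, -3.87, -2.86, -2.77, -2.65, -1.65,
                                 -3.90, -4.05, -4.35, -5.00, -5.40, -5.80,
                                 -6.30, -4.20, -4.20, -4.20, -4.20, -4.20,
                                 -4.20, -4.20]
    )
    sex_logit: dict = field(default_factory=lambda: {"female": 0.0, "male": 0.05})
    race_logit: dict = field(
        default_factory=lambda: {"hispanic": 0.34, "nh_black": 0.19, "nh_white": 0.0}
    )
    income_logit: dict = field(
        default_factory=lambda: {"low": 0.40, "middle": 0.18, "high": 0.0}
    )
    residence_logit: dict = field(default_factory=lambda: {"urban": 0.0, "rural": 0.07})
    hpsa_logit: dict = field(
        default_factory=lambda: {"none": 0.0, "partial": 0.03, "whole": 0.06}
    )
    #: fitted per-age-group adjustment, additive on the log-odds scale
    calibration: dict = field(
        default_factory=lambda: {g: 0.0 for g in AGE_GROUPS}
    )
    calibrated: bool = False
    #: extra log-odds of a new carious event for individuals with prior
    #: caries experience (past caries is the strongest predictor of future
    #: caries); drives repeat decayed-tooth events without affecting the
    #: first-event hazard that calibration pins down.
    prior_caries_logit: float = 2.3
    p_untreated_no_util: float = 0.55
    p_untreated_util: float = 0.10
    p_abscess: float = 0.20      # per cycle, given prevalent untreated caries
    p_toothloss: float = 0.07    # per cycle, given prevalent untreated caries
    #: annual all-cause mortality: list of [max_age_inclusive, rate] bands
    mortality_bands: list = field(
        default_factory=lambda: [[0, 0.0056], [4, 0.00025], [14, 0.00015],
                                 [19, 0.0006], [200, 0.0009]]
    )

    def validate(self) -> None:
        for name in ("p_untreated_no_util", "p_untreated_util", "p_abscess", "p_toothloss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} outside [0,1]: {v}")
        for _, rate in self.mortality_bands:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"mortality rate outside [0,1]: {rate}")

    def mortality_rate(self, age: np.ndarray) -> np.ndarray:
        bands = np.array([b[0] for b in self.mortality_bands])
        rates = np.array([b[1] for b in self.mortality_bands])
        idx = np.searchsorted(bands, np.asarray(age), side="left")
        return rates[np.minimum(idx, len(rates) - 1)]


def caries_probability(pop: Population, rm: RiskModel,
                       supply_log_or=0.0) -> np.ndarray:
    """Annual per-individual caries probability.

    ``supply_log_or`` is a per-individual (or scalar) log-odds shift from the
    workforce supply model; negative values are protective.  Individuals past
    :data:`MAX_RISK_AGE` have probability zero.
    """
    g = pop.age_group_idx
    lo = (np.array(rm.age_logit)[np.clip(pop.age, 0, MAX_RISK_AGE)]
          + np.array([rm.intercept[k] for k in AGE_GROUPS])[g]
          + np.array([rm.calibration[k] for k in AGE_GROUPS])[g]
          + np.array([rm.sex_logit[k] for k in SEXES])[pop.codes["sex"]]
          + np.array([rm.race_logit[k] for k in RACES])[pop.codes["race"]]
          + np.array([rm.income_logit[k] for k in INCOMES])[pop.codes["income"]]
          + np.array([rm.residence_logit[k] for k in RESIDENCES])[pop.codes["residence"]]
          + np.array([rm.hpsa_logit[k] for k in HPSA_LEVELS])[pop.codes["hpsa"]]
          + rm.prior_caries_logit * pop.ever_caries
          + supply_log_or)
    p = expit(lo)
    return np.where(pop.age > MAX_RISK_AGE, 0.0, p)


def annual_caries_prob(pop: Population, rm: RiskModel, supply_log_or=0.0) -> np.ndarray:
    """Alias of :func:`caries_probability` (operation-level name)."""
    return caries_probability(pop, rm, supply_log_or)


@dataclass
class CycleEvents:
    """Per-individual event indicators for one annual cycle (for costing)."""

    utilized: np.ndarray
    new_events: np.ndarray        # bool: accrued a new carious event
    new_treated: np.ndarray       # bool: new event treated immediately
    conversions: np.ndarray       # bool: prevalent untreated converted to treated
    abscesses: np.ndarray         # bool: abscess episode this cycle
    extractions: np.ndarray       # bool: tooth lost this cycle
    died: np.ndarray              # bool: death this cycle


def step_disease(pop: Population, rm: RiskModel, util_prob: np.ndarray,
                 supply_log_or, cycle: int, seed: int) -> CycleEvents:
    """Advance the population one annual cycle in place and report events.

    ``util_prob`` is the per-individual probability of using preventive care
    this cycle (baseline plus any supply-driven increase); ``supply_log_or``
    shifts the caries log-odds.  Random draws come from counter-based streams
    keyed by (seed, event slot, cycle) and indexed by individual, so runs over
    the same population are exactly paired across scenarios.
    """
    n = pop.n
    alive0 = pop.alive.copy()

    # (1) utilization; a visit treats any prevalent untreated caries
    utilized = alive0 & (uniforms(seed, TAG_UTILIZATION, cycle, n) < util_prob)
    conversions = utilized & pop.untreated
    pop.untreated[conversions] = False

    # (2) new carious event
    p = caries_probability(pop, rm, supply_log_or)
    new = alive0 & (uniforms(seed, TAG_CARIES, cycle, n) < p)
    pop.caries_events[new] += 1

    # (3) treated vs untreated for the new event
    p_untr = np.where(utilized, rm.p_untreated_util, rm.p_untreated_no_util)
    new_untreated = new & (uniforms(seed, TAG_TREATMENT, cycle, n) < p_untr)
    new_treated = new & ~new_untreated
    pop.untreated |= new_untreated

    # (4) complications on prevalent untreated caries, gated so that counters
    #     never exceed accrued carious events
    untr = alive0 & pop.untreated
    absc = (untr & (uniforms(seed, TAG_ABSCESS, cycle, n) < rm.p_abscess)
            & (pop.abscess_count < pop.caries_events))
    pop.abscess_count[absc] += 1
    lost = (untr & (uniforms(seed, TAG_TOOTHLOSS, cycle, n) < rm.p_toothloss)
            & (pop.teeth_lost < pop.caries_events))
    pop.teeth_lost[lost] += 1

    # (5) mortality, then aging
    died = alive0 & (uniforms(seed, TAG_MORTALITY, cycle, n) < rm.mortality_rate(pop.age))
    pop.alive[died] = False
    pop.age[alive0] += 1

    return CycleEvents(utilized=utilized, new_events=new, new_treated=new_treated,
                       conversions=conversions, abscesses=absc, extractions=lost,
                       died=died)


# ---------------------------------------------------------------------------
# Prevalence measurement and calibration
# ---------------------------------------------------------------------------

def band_index(age: np.ndarray) -> np.ndarray:
    """Measurement-band index per individual, -1 if outside all bands."""
    age = np.asarray(age)
    out = np.full(age.shape, -1, dtype=np.int8)
    for i, (_, (lo, hi)) in enumerate(MEASURE_BANDS.items()):
        out[(age >= lo) & (age <= hi)] = i
    return out


class _BandAccumulator:
    """Weighted person-time caries prevalence pooled over annual snapshots."""

    def __init__(self):
        k = len(MEASURE_BANDS)
        self.case = np.zeros(k)
        self.total = np.zeros(k)

    def add(self, pop: Population) -> None:
        b = band_index(pop.age)
        m = pop.alive & (b >= 0)
        if not m.any():
            return
        np.add.at(self.total, b[m], pop.weight[m])
        np.add.at(self.case, b[m], pop.weight[m] * pop.ever_caries[m])

    def prevalence(self) -> dict:
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = np.where(self.total > 0, self.case / self.total, np.nan)
        return dict(zip(MEASURE_BANDS, prev))


def simulate_band_prevalence(pop: Population, rm: RiskModel, horizon: int,
                             disease_seed: int) -> dict:
    """Status-quo run returning pooled cross-sectional band prevalences.

    Snapshots are taken at baseline and after each of the ``horizon`` cycles;
    the same counter-based streams as scenario runs are used, so a status-quo
    scenario with the same seeds reproduces this trajectory exactly.
    """
    work = pop.copy()
    acc = _BandAccumulator()
    acc.add(work)
    for t in range(horizon):
        step_disease(work, rm, work.util_prob, 0.0, t, disease_seed)
        acc.add(work)
    return acc.prevalence()


@dataclass
class CalibrationSettings:
    horizon: int = 10
    disease_seed: int = 2022
    tolerance: float = 0.0025    # absolute prevalence
    max_iter: int = 40           # bisection iterations per age group
    bracket: tuple = (-6.0, 6.0)


def calibrate(rm: RiskModel, targets: dict, pop: Population,
              settings: CalibrationSettings | None = None):
    """Fit per-age-group log-odds adjustments to age-band prevalence targets.

    Returns ``(fitted RiskModel, report)`` where the report is a data frame
    with one row per age group (target, achieved, multiplier, iterations).
    The groups are solved sequentially from youngest to oldest: the pooled
    prevalence of a band depends only on the adjustments of its own and
    younger groups, so the problem is triangular and each stage is a monotone
    one-dimensional bisection under common random numbers.
    """
    settings = settings or CalibrationSettings()
    for g, t in targets.items():
        if not 0.0 < t < 1.0:
            raise ConfigurationError(f"calibration target for {g} outside (0,1): {t}")
    if not pop.baseline_assigned:
        raise ConfigurationError("population must have baseline states assigned")

    import copy

    fitted = copy.deepcopy(rm)
    rows = []
    band_names = list(MEASURE_BANDS)

    for gi, g in enumerate(AGE_GROUPS):
        if g not in targets:
            raise ConfigurationError(f"missing calibration target for age group {g}")
        target = targets[g]
        lo, hi = settings.bracket

        def achieved(mult: float) -> float:
            fitted.calibration[g] = mult
            prev = simulate_band_prevalence(pop, fitted, settings.horizon,
                                            settings.disease_seed)
            return prev[band_names[gi]]

        f_lo, f_hi = achieved(lo), achieved(hi)
        best_mult, best_val, iters = None, None, 0
        for cand, val in ((lo, f_lo), (hi, f_hi)):
            if best_val is None or abs(val - target) < abs(best_val - target):
                best_mult, best_val = cand, val
        if not (f_lo - target) * (f_hi - target) <= 0:
            raise CalibrationError(
                f"target {target:.4f} for {g} not bracketed: "
                f"[{f_lo:.4f}, {f_hi:.4f}] over multipliers {settings.bracket}",
                best_residual=abs(best_val - target),
            )
        while iters < settings.max_iter and abs(best_val - target) > settings.tolerance:
            mid = 0.5 * (lo + hi)
            f_mid = achieved(mid)
            iters += 1
            if abs(f_mid - target) < abs(best_val - target):
                best_mult, best_val = mid, f_mid
            if (f_lo - target) * (f_mid - target) <= 0:
                hi, f_hi = mid, f_mid
            else:
                lo, f_lo = mid, f_mid
        if abs(best_val - target) > settings.tolerance:
            raise CalibrationError(
                f"no convergence for {g} after {iters} iterations",
                best_residual=abs(best_val - target),
            )
        fitted.calibration[g] = best_mult
        rows.append({"age_group": g, "target": target, "achieved": best_val,
                     "multiplier": best_mult, "iterations": iters})

    fitted.calibrated = True
    report = pd.DataFrame(rows)
    return fitted, report
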