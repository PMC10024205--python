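"""Scenario orchestration: annual cycles, weighted aggregation, increments.

A scenario run applies workforce-derived utilization and caries-risk shifts
to shortage-area individuals only, accrues discounted costs and QALYs per
cycle, and aggregates outcomes weighted to the configured child population.
Incremental comparisons require both runs to share the same population and
seeds (common random numbers), verified via a population fingerprint.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import cycle_costs, cycle_qaly, program_cost
from .errors import ConfigurationError, NotCalibratedError, PopulationMismatchError
from .natural_history import _BandAccumulator, step_disease
from .popsynth import DIMENSIONS, Population
from .workforce import (allocate_density, apply_supply_effect, awards_to_fte,
                        project_awards)


@dataclass
class ScenarioConfig:
    label: str = "status_quo"
    budget_growth: float = 0.0        # annual fraction; 0 = status quo
    commitment_extension: int = 0     # additional service years per award
    horizon: int = 10
    start_year: int = 2022
    discount_rate: float | None = None  # falls back to EconParams.discount_rate
    disease_seed: int = 2022

    def validate(self) -> None:
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.budget_growth < 0:
            raise ConfigurationError("budget growth must be >= 0 for modeled scenarios")
        if self.commitment_extension < 0:
            raise ConfigurationError("commitment extension must be >= 0")


@dataclass
class ScenarioResult:
    label: str
    horizon: int
    fingerprint: str
    #: pooled cross-sectional caries prevalence by measurement band
    prevalence_bands: dict
    #: end-of-horizon ever-caries prevalence (weighted, among alive)
    prevalence_hpsa_end: float
    prevalence_non_hpsa_end: float
    prevalence_overall_end: float
    #: carious tooth events accrued during the horizon, scaled to persons
    cum_events_total: float
    cum_events_hpsa: float
    disc_treatment_cost_total: float
    disc_treatment_cost_hpsa: float
    disc_program_cost: float
    disc_qalys_total: float
    disc_qalys_hpsa: float
    per_year: pd.DataFrame = field(repr=False, default=None)
    per_stratum: pd.DataFrame = field(repr=False, default=None)

    @property
    def total_cost_hpsa(self) -> float:
        """Health-care plus program cost attributed to shortage-area children."""
        return self.disc_treatment_cost_hpsa + self.disc_program_cost

    @property
    def total_cost(self) -> float:
        return self.disc_treatment_cost_total + self.disc_program_cost


def _weighted_prevalence(pop: Population, mask: np.ndarray) -> float:
    """Ever-caries prevalence among alive cohort members still of child age."""
    m = mask & pop.alive & (pop.age <= 19)
    w = pop.weight[m]
    if w.sum() == 0:
        return float("nan")
    return float(np.average(pop.ever_caries[m], weights=w))


def run_scenario(pop: Population, params, sc: ScenarioConfig) -> ScenarioResult:
    """Simulate one scenario over the horizon and aggregate weighted outcomes.

    ``pop`` must have baseline states assigned; it is not mutated (the run
    operates on a copy).  The workforce effect is the density *difference*
    between the scenario's award stream and the flat status-quo stream, so a
    zero-growth, zero-extension scenario reduces exactly to the status quo.
    """
    sc.validate()
    params.validate()
    if not params.risk.calibrated:
        raise NotCalibratedError(
            "risk model is not calibrated; run calibration first or load "
            "calibrated parameters")
    if not pop.baseline_assigned:
        raise ConfigurationError("population must have baseline states assigned")

    rate = sc.discount_rate if sc.discount_rate is not None else params.econ.discount_rate
    h = sc.horizon
    fingerprint = pop.fingerprint()
    work = pop.copy()

    # workforce: incremental FTE of this scenario over the flat status quo
    base_awards = project_awards(params.program, 0.0, h)
    scen_awards = project_awards(params.program, sc.budget_growth, h)
    fte_scen = awards_to_fte(scen_awards, params.program, sc.commitment_extension, years=h)
    fte_base = awards_to_fte(base_awards, params.program, 0, years=h)
    d_fte = np.maximum(fte_scen - fte_base, 0.0)

    demo = params.demographics
    pops = demo.stratum_populations()
    hpsa_col = demo.strata["hpsa"].to_numpy()
    pop_whole = float(pops[hpsa_col == "whole"].sum())
    pop_partial = float(pops[hpsa_col == "partial"].sum())
    density = allocate_density(d_fte, pop_whole, pop_partial,
                               params.program.partial_allocation_weight)
    # per-level per-year log-odds shift and utilization gain
    log_or = math.log(params.supply_effect.caries_or)
    level_shift = np.zeros((3, h))   # rows: none, partial, whole
    level_util_add = np.zeros((3, h))
    for li, level in ((1, "partial"), (2, "whole")):
        _, shift = apply_supply_effect(density[level], params.supply_effect, 0.0)
        level_shift[li] = shift
        level_util_add[li] = (params.supply_effect.utilization_slope_pp / 100.0
                              * density[level] * 10.0)

    w = work.weight
    hpsa_mask = work.is_hpsa
    hpsa_idx = work.hpsa_idx

    acc = _BandAccumulator()
    acc.add(work)
    disc_cost = np.zeros(work.n)
    disc_qaly = np.zeros(work.n)
    events_cum = np.zeros(work.n)
    rows = []
    for t in range(h):
        util_prob = np.clip(work.util_prob + level_util_add[hpsa_idx, t], 0.0, 1.0)
        shift = level_shift[hpsa_idx, t]
        ev = step_disease(work, params.risk, util_prob, shift, t, sc.disease_seed)

        cost_t = cycle_costs(params.econ, utilized=ev.utilized,
                             treated_events=ev.new_treated,
                             conversions=ev.conversions,
                             abscesses=ev.abscesses, extractions=ev.extractions)
        treated_only = work.ever_caries & ~work.untreated
        qaly_t = cycle_qaly(params.econ, alive=work.alive,
                            untreated=work.untreated, treated_only=treated_only,
                            abscess_episode=ev.abscesses,
                            tooth_loss=work.teeth_lost > 0)
        df = 1.0 / (1.0 + rate) ** t
        disc_cost += cost_t * df
        disc_qaly += qaly_t * df
        events_cum += ev.new_events
        acc.add(work)
        rows.append({
            "year": sc.start_year + t,
            "fte_increment": d_fte[t],
            "density_whole": density["whole"][t],
            "prevalence_overall": _weighted_prevalence(work, np.ones(work.n, bool)),
            "prevalence_hpsa": _weighted_prevalence(work, hpsa_mask),
            "new_events_persons": float((w * ev.new_events)[:].sum()),
            "disc_cost_persons": float((w * cost_t).sum() * df),
            "disc_qalys_persons": float((w * qaly_t).sum() * df),
        })

    # program cost amortized over service commitments and truncated at the
    # horizon, so scenario costs and in-horizon service years line up
    commitments = {t: c + sc.commitment_extension
                   for t, c in params.program.commitment_years.items()}
    prog_cost = program_cost(scen_awards, params.econ, rate,
                             commitment_years=commitments, horizon=h)

    # per-stratum end-of-horizon summary (Fig-2-style disparities analogue)
    strat_df = work.strata[list(DIMENSIONS)].copy()
    strat_w = np.zeros(len(strat_df))
    strat_case = np.zeros(len(strat_df))
    alive = work.alive
    np.add.at(strat_w, work.stratum_idx[alive], w[alive])
    np.add.at(strat_case, work.stratum_idx[alive],
              (w * work.ever_caries)[alive])
    with np.errstate(invalid="ignore", divide="ignore"):
        strat_df["weight"] = strat_w
        strat_df["prevalence_end"] = np.where(strat_w > 0, strat_case / strat_w, np.nan)

    return ScenarioResult(
        label=sc.label,
        horizon=h,
        fingerprint=fingerprint,
        prevalence_bands=acc.prevalence(),
        prevalence_hpsa_end=_weighted_prevalence(work, hpsa_mask),
        prevalence_non_hpsa_end=_weighted_prevalence(work, ~hpsa_mask),
        prevalence_overall_end=_weighted_prevalence(work, np.ones(work.n, bool)),
        cum_events_total=float((w * events_cum).sum()),
        cum_events_hpsa=float((w * events_cum)[hpsa_mask].sum()),
        disc_treatment_cost_total=float((w * disc_cost).sum()),
        disc_treatment_cost_hpsa=float((w * disc_cost)[hpsa_mask].sum()),
        disc_program_cost=prog_cost,
        disc_qalys_total=float((w * disc_qaly).sum()),
        disc_qalys_hpsa=float((w * disc_qaly)[hpsa_mask].sum()),
        per_year=pd.DataFrame(rows),
        per_stratum=strat_df,
    )


@dataclass
class IncrementalResult:
    """Scenario-minus-baseline outcomes among shortage-area children."""

    label: str
    delta_prevalence_pp: float    # percentage points
    delta_events: float           # carious tooth events (persons)
    delta_qalys: float
    delta_cost: float
    icer: float | str             # $/QALY, or 'dominant' / 'dominated'
    nmb: float                    # net monetary benefit at the given WTP
    wtp: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def incremental(result: ScenarioResult, baseline: ScenarioResult,
                wtp: float = 50_000.0) -> IncrementalResult:
    """Element-wise scenario-minus-baseline differences with ICER and NMB.

    Both results must come from the same population under common random
    numbers; mismatched fingerprints raise an error.
    """
    if result.fingerprint != baseline.fingerprint:
        raise PopulationMismatchError(
            "scenario and baseline were run on different populations")
    dq = result.disc_qalys_hpsa - baseline.disc_qalys_hpsa
    dc = result.total_cost_hpsa - baseline.total_cost_hpsa
    if dq > 0 and dc < 0:
        icer: float | str = "dominant"
    elif dq < 0 and dc > 0:
        icer = "dominated"
    elif dq == 0:
        icer = float("nan")
    else:
        icer = dc / dq
    return IncrementalResult(
        label=result.label,
        delta_prevalence_pp=100.0 * (result.prevalence_hpsa_end
                                     - baseline.prevalence_hpsa_end),
        delta_events=result.cum_events_hpsa - baseline.cum_events_hpsa,
        delta_qalys=dq,
        delta_cost=dc,
        icer=icer,
        nmb=wtp * dq - dc,
        wtp=wtp,
    )


def results_table(increments: list[IncrementalResult]) -> pd.DataFrame:
    """Headline table: one row per scenario, in print units."""
    return pd.DataFrame([{
        "scenario": r.label,
        "delta_prevalence_pp": r.delta_prevalence_pp,
        "delta_incidence_millions": r.delta_events / 1e6,
        "delta_qalys_thousands": r.delta_qalys / 1e3,
        "delta_cost_millions": r.delta_cost / 1e6,
        "icer": r.icer,
        "nmb": r.nmb,
    } for r in increments])
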