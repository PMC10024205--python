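"""One-way (tornado) and probabilistic sensitivity analysis, with CEAC.

All analyses compare an intervention scenario against the status quo under
common random numbers.  The probabilistic analysis draws parameter sets from
the configured distributions; within each draw the paired runs share disease
seeds while each draw gets a fresh seed, separating parameter uncertainty
from stochastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .config import ParamDistribution, ParameterSet
from .engine import ScenarioConfig, incremental, run_scenario
from .errors import ConfigurationError
from .popsynth import Population

DEFAULT_WTP_GRID = tuple(range(0, 150_001, 10_000))  # $/QALY


def _paired_increment(params: ParameterSet, pop: Population, sc: ScenarioConfig,
                      wtp: float = 50_000.0):
    base_sc = replace(sc, label="status_quo", budget_growth=0.0,
                      commitment_extension=0)
    base = run_scenario(pop, params, base_sc)
    res = run_scenario(pop, params, sc)
    return incremental(res, base, wtp=wtp)


def one_way(params: ParameterSet, pop: Population, sc: ScenarioConfig,
            distributions: list[ParamDistribution] | None = None,
            outcome: str = "delta_cost", wtp: float = 50_000.0) -> pd.DataFrame:
    """Tornado table: each parameter swept to its low/high bound in turn.

    All other parameters stay at central values; every evaluation reruns the
    paired scenario comparison under common random numbers.  Rows are sorted
    by the absolute spread of the designated outcome.
    """
    if distributions is None:
        by_path = {d.path: d for d in params.psa_distributions}
        try:
            distributions = [by_path[p] for p in params.oneway_parameters]
        except KeyError as e:
            raise ConfigurationError(f"no distribution configured for {e}") from e
    rows = []
    for dist in distributions:
        lo, hi = dist.bounds()
        rec = {"parameter": dist.path, "central": dist.central, "low": lo, "high": hi}
        for tag, value in (("low", lo), ("high", hi)):
            inc = _paired_increment(params.with_value(dist.path, value), pop, sc, wtp)
            rec[f"delta_cost_{tag}"] = inc.delta_cost
            rec[f"delta_qalys_{tag}"] = inc.delta_qalys
            rec[f"{outcome}_{tag}"] = getattr(inc, outcome)
        rec["spread"] = rec[f"{outcome}_high"] - rec[f"{outcome}_low"]
        rows.append(rec)
    table = pd.DataFrame(rows)
    return table.reindex(table["spread"].abs().sort_values(ascending=False).index)


@dataclass
class PsaSummary:
    """Point estimates with 95% credible intervals plus the CEAC."""

    outcomes: pd.DataFrame      # index: outcome; columns: mean, lo2.5, hi97.5
    ceac: pd.DataFrame          # columns: wtp, probability
    draws: pd.DataFrame = field(repr=False, default=None)

    def interval(self, outcome: str) -> tuple[float, float, float]:
        row = self.outcomes.loc[outcome]
        return float(row["mean"]), float(row["lo2.5"]), float(row["hi97.5"])


def psa(params: ParameterSet, pop: Population, sc: ScenarioConfig,
        n_draws: int = 1000, master_seed: int = 0,
        wtp_grid=DEFAULT_WTP_GRID, wtp: float = 50_000.0,
        common_disease_seed: bool = False) -> PsaSummary:
    """Probabilistic sensitivity analysis over ``n_draws`` parameter samples.

    Each draw samples every configured distribution, reruns the paired
    status-quo/intervention comparison with a draw-specific disease seed, and
    records the incremental outcomes; summaries are percentile-based.
    ``common_disease_seed`` freezes disease randomness across draws, so with
    degenerate distributions every draw is identical (zero interval width).
    """
    if n_draws < 2:
        raise ConfigurationError("n_draws must be >= 2")
    if not params.psa_distributions:
        raise ConfigurationError("no PSA distributions configured")
    records = []
    for i in range(n_draws):
        ss = np.random.SeedSequence([int(master_seed), i])
        rng = np.random.Generator(np.random.PCG64(ss))
        drawn = params.copy()
        for dist in params.psa_distributions:
            drawn.set_path(dist.path, dist.sample(rng))
        sc_i = sc if common_disease_seed else replace(
            sc, disease_seed=derive_seed(master_seed, i))
        inc = _paired_increment(drawn, pop, sc_i, wtp)
        records.append({"draw": i,
                        "delta_prevalence_pp": inc.delta_prevalence_pp,
                        "delta_events": inc.delta_events,
                        "delta_qalys": inc.delta_qalys,
                        "delta_cost": inc.delta_cost})
    draws = pd.DataFrame(records).set_index("draw")
    outcomes = pd.DataFrame({
        "mean": draws.mean(),
        "lo2.5": draws.quantile(0.025),
        "hi97.5": draws.quantile(0.975),
    })
    ceac_df = ceac(draws, wtp_grid)
    return PsaSummary(outcomes=outcomes, ceac=ceac_df, draws=draws)


def ceac(draws: pd.DataFrame, wtp_grid=DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Probability the intervention has positive net monetary benefit per WTP.

    At each willingness-to-pay ``w`` the probability is the fraction of draws
    with ``w * delta_qalys - delta_cost > 0``.
    """
    if len(draws) == 0:
        raise ConfigurationError("empty draw set")
    dq = draws["delta_qalys"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    rows = [{"wtp": float(w), "probability": float(np.mean(w * dq - dc > 0))}
            for w in wtp_grid]
    return pd.DataFrame(rows)
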