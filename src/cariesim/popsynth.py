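"""Synthetic population generation.

Builds seeded populations of simulated children with the joint demographic
structure the analysis assumes (age group x sex x race/ethnicity x income x
urban/rural x shortage-area status), assigns sampling weights so that stratum
populations are conserved exactly, and seeds baseline oral-health states.

The packaged default demographic configuration encodes plausible stratum
proportions documented as assumptions; it is not an estimate from survey
microdata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from ._rng import TAG_BASELINE, TAG_POPULATION, TAG_RESIDUAL, stream
from .errors import ConfigurationError

# Categorical dimensions, in canonical order.
AGE_GROUPS = ("0-5", "6-12", "13-19")
AGE_GROUP_BOUNDS = {"0-5": (0, 5), "6-12": (6, 12), "13-19": (13, 19)}
SEXES = ("female", "male")
RACES = ("hispanic", "nh_black", "nh_white")
INCOMES = ("low", "middle", "high")  # <130% FPL, 130-300%, >300%
RESIDENCES = ("urban", "rural")
HPSA_LEVELS = ("none", "partial", "whole")

DIMENSIONS = ("age_group", "sex", "race", "income", "residence", "hpsa")
_CATEGORIES = {
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "race": RACES,
    "income": INCOMES,
    "residence": RESIDENCES,
    "hpsa": HPSA_LEVELS,
}

# Age bands used for prevalence measurement/validation.  The youngest band
# starts at age 2 (clinical caries assessment is not meaningful below that).
MEASURE_BANDS = {"0-5": (2, 5), "6-12": (6, 12), "13-19": (13, 19)}


def age_group_of(age: np.ndarray) -> np.ndarray:
    """Map integer ages to age-group indices (ages 20+ stay in the last group)."""
    return np.searchsorted([5, 12], np.asarray(age), side="left").astype(np.int8)


@dataclass
class DemographicConfig:
    """Stratum definitions with population proportions and totals.

    ``strata`` is a data frame with one row per stratum: the six categorical
    columns in :data:`DIMENSIONS` plus a ``proportion`` column summing to one
    over all rows.  ``total_child_population`` scales proportions to persons;
    ``hpsa_child_population`` is the configured total of children living in
    whole- or partial-shortage-area strata and must agree with the proportions.
    """

    strata: pd.DataFrame
    total_child_population: float
    hpsa_child_population: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in DIMENSIONS + ("proportion",) if c not in self.strata.columns]
        if missing:
            raise ConfigurationError(f"strata table missing columns: {missing}")
        props = self.strata["proportion"].to_numpy(dtype=float)
        neg = np.flatnonzero(props < 0)
        if neg.size:
            key = self._key(int(neg[0]))
            raise ConfigurationError(f"negative proportion for stratum {key}")
        total = props.sum()
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"stratum proportions sum to {total!r}, expected 1")
        keys = self.strata[list(DIMENSIONS)].apply(tuple, axis=1)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate stratum key {dup}")
        for dim in DIMENSIONS:
            bad = set(self.strata[dim]) - set(_CATEGORIES[dim])
            if bad:
                raise ConfigurationError(f"unknown {dim} categories {sorted(bad)}")
        if self.hpsa_child_population <= 0:
            raise ConfigurationError("hpsa_child_population must be > 0")
        if self.total_child_population <= 0:
            raise ConfigurationError("total_child_population must be > 0")
        hpsa_mask = self.strata["hpsa"].isin(("partial", "whole")).to_numpy()
        implied = float(props[hpsa_mask].sum() * self.total_child_population)
        if abs(implied - self.hpsa_child_population) > 0.005 * self.hpsa_child_population:
            raise ConfigurationError(
                "hpsa_child_population inconsistent with stratum proportions: "
                f"configured {self.hpsa_child_population:.4g}, implied {implied:.4g}"
            )

    def _key(self, i: int) -> tuple:
        return tuple(self.strata.iloc[i][list(DIMENSIONS)])

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def stratum_populations(self) -> np.ndarray:
        return self.strata["proportion"].to_numpy(dtype=float) * self.total_child_population

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "total_child_population": float(self.total_child_population),
            "hpsa_child_population": float(self.hpsa_child_population),
            "strata": self.strata.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicConfig":
        return cls(
            strata=pd.DataFrame(d["strata"]),
            total_child_population=float(d["total_child_population"]),
            hpsa_child_population=float(d["hpsa_child_population"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class UtilizationModel:
    """Baseline probability of a preventive dental visit in a given year."""

    base: float = 0.45
    income_adjustment: dict = field(
        default_factory=lambda: {"low": -0.08, "middle": 0.0, "high": 0.07}
    )
    hpsa_adjustment: dict = field(
        default_factory=lambda: {"none": 0.0, "partial": -0.03, "whole": -0.06}
    )

    def probability(self, income_idx: np.ndarray, hpsa_idx: np.ndarray) -> np.ndarray:
        inc = np.array([self.income_adjustment[k] for k in INCOMES])
        hp = np.array([self.hpsa_adjustment[k] for k in HPSA_LEVELS])
        return np.clip(self.base + inc[income_idx] + hp[hpsa_idx], 0.0, 1.0)


@dataclass
class BaselineStates:
    """Targets and adjustments for assigning oral-health states at entry.

    ``age_group_targets`` give the caries-experience fraction in each age
    group; offsets shift individual probabilities on the log-odds scale and
    are re-centred within each age group so the group mean stays on target.
    """

    age_group_targets: dict = field(
        default_factory=lambda: {"0-5": 0.213, "6-12": 0.521, "13-19": 0.568}
    )
    under2_factor: float = 0.30  # ages 0-1 carry a reduced target
    race_logit: dict = field(
        default_factory=lambda: {"hispanic": 0.30, "nh_black": 0.15, "nh_white": 0.0}
    )
    hpsa_logit: dict = field(
        default_factory=lambda: {"none": 0.0, "partial": 0.04, "whole": 0.075}
    )
    income_logit: dict = field(
        default_factory=lambda: {"low": 0.20, "middle": 0.05, "high": -0.20}
    )
    p_untreated: float = 0.35  # untreated share among prevalent cases at entry
    extra_event_rate: float = 0.08  # Poisson mean of extra accrued events per year of age

    # Within-band shape factors for the single-year-of-age prevalence profile.
    # Each band's factors average to 1 so band means equal the group targets,
    # and the resulting profile is monotone in age for the packaged targets
    # (entry prevalence must rise with age for cross-sections to be stationary
    # under nonnegative incidence).
    band_shape: dict = field(
        default_factory=lambda: {"0-5": [0.45, 1.55], "6-12": [0.943, 1.057],
                                 "13-19": [0.93, 1.07]}
    )

    def validate(self) -> None:
        for g, t in self.age_group_targets.items():
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError(f"baseline target for {g} outside [0,1]: {t}")
        if not 0.0 <= self.p_untreated <= 1.0:
            raise ConfigurationError("baseline p_untreated outside [0,1]")

    def age_profile(self) -> np.ndarray:
        """Entry caries-experience fraction by single year of age 0..19."""
        try:
            targets = [self.age_group_targets[g] for g in AGE_GROUPS]
        except KeyError as e:
            raise ConfigurationError(f"missing baseline target for age group {e}") from e
        prof = np.zeros(20)
        t1 = targets[0]
        # ages 0-1: reduced entry prevalence below the youngest measured band
        prof[0] = prof[1] = t1 * self.under2_factor
        for g, t, (lo_age, hi_age) in zip(AGE_GROUPS, targets,
                                          [(2, 5), (6, 12), (13, 19)]):
            f_lo, f_hi = self.band_shape[g]
            prof[lo_age:hi_age + 1] = t * np.linspace(f_lo, f_hi, hi_age - lo_age + 1)
        return np.clip(prof, 0.0, 1.0)


class Population:
    """A simulated cohort stored as parallel arrays (one entry per individual)."""

    MUTABLE = ("age", "caries_events", "untreated", "abscess_count",
               "teeth_lost", "alive", "util_prob")

    def __init__(self, strata: pd.DataFrame, stratum_idx: np.ndarray,
                 age: np.ndarray, weight: np.ndarray):
        n = len(stratum_idx)
        self.strata = strata  # shared, read-only stratum attribute table
        self.stratum_idx = np.asarray(stratum_idx, dtype=np.int32)
        self.age = np.asarray(age, dtype=np.int16)
        self.weight = np.asarray(weight, dtype=np.float64)
        self.caries_events = np.zeros(n, dtype=np.int16)
        self.untreated = np.zeros(n, dtype=bool)
        self.abscess_count = np.zeros(n, dtype=np.int16)
        self.teeth_lost = np.zeros(n, dtype=np.int16)
        self.alive = np.ones(n, dtype=bool)
        self.util_prob = np.full(n, np.nan)
        self.baseline_assigned = False
        # static per-individual categorical codes
        self.codes = {
            dim: np.array(
                [_CATEGORIES[dim].index(v) for v in strata[dim]], dtype=np.int8
            )[self.stratum_idx]
            for dim in DIMENSIONS
        }

    @property
    def n(self) -> int:
        return len(self.stratum_idx)

    @property
    def age_group_idx(self) -> np.ndarray:
        """Age-group index from *current* age."""
        return age_group_of(self.age)

    @property
    def hpsa_idx(self) -> np.ndarray:
        return self.codes["hpsa"]

    @property
    def is_hpsa(self) -> np.ndarray:
        return self.codes["hpsa"] > 0

    @property
    def ever_caries(self) -> np.ndarray:
        return self.caries_events > 0

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.strata = self.strata
        new.stratum_idx = self.stratum_idx
        new.weight = self.weight
        new.codes = self.codes
        new.baseline_assigned = self.baseline_assigned
        for name in self.MUTABLE:
            setattr(new, name, getattr(self, name).copy())
        return new

    def fingerprint(self) -> str:
        """Hash of the generated/baseline state, used to verify scenario pairing."""
        import hashlib

        h = hashlib.sha1()
        for arr in (self.stratum_idx, self.age, self.weight, self.caries_events,
                    self.untreated, self.util_prob):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        """One row per individual with documented columns."""
        df = pd.DataFrame({
            "stratum": self.stratum_idx,
            "age": self.age,
            "weight": self.weight,
            "caries_events": self.caries_events,
            "untreated": self.untreated.astype(int),
            "abscess_count": self.abscess_count,
            "teeth_lost": self.teeth_lost,
            "alive": self.alive.astype(int),
            "util_prob": self.util_prob,
        })
        for dim in DIMENSIONS:
            df[dim] = self.strata[dim].to_numpy()[self.stratum_idx]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_population(n: int, demo: DemographicConfig, seed: int) -> Population:
    """Generate exactly ``n`` individuals matching the configured strata.

    Stratum counts use deterministic largest-remainder quotas with the
    residual units assigned randomly (by seed) in proportion to fractional
    remainders, so total population weight is conserved exactly and runs are
    reproducible bit-for-bit.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    demo.validate()
    props = demo.strata["proportion"].to_numpy(dtype=float)
    quotas = n * props
    counts = np.floor(quotas).astype(np.int64)
    frac = quotas - counts
    residual = n - int(counts.sum())
    if residual > 0:
        rng = stream(seed, TAG_RESIDUAL)
        if frac.sum() > 0:
            p = frac / frac.sum()
            positive = int((p > 0).sum())
            take = min(residual, positive)
            picked = rng.choice(len(props), size=take, replace=False, p=p)
            counts[picked] += 1
            residual -= take
        if residual > 0:  # pathological: more residual units than fractional strata
            picked = rng.choice(np.flatnonzero(props > 0), size=residual, replace=True)
            np.add.at(counts, picked, 1)

    stratum_idx = np.repeat(np.arange(len(props), dtype=np.int32), counts)

    # ages uniform over the integer years of each stratum's age group
    rng_pop = stream(seed, TAG_POPULATION)
    lo = np.array([AGE_GROUP_BOUNDS[g][0] for g in demo.strata["age_group"]])
    hi = np.array([AGE_GROUP_BOUNDS[g][1] for g in demo.strata["age_group"]])
    u = rng_pop.random(len(stratum_idx))
    span = (hi - lo + 1)[stratum_idx]
    age = (lo[stratum_idx] + np.floor(u * span)).astype(np.int16)

    # weights: stratum population / simulated count, then a within-HPSA-level
    # rescale so that level totals are conserved exactly even if a tiny
    # stratum received zero individuals (quantization rule).
    pops = demo.stratum_populations()
    with np.errstate(divide="ignore", invalid="ignore"):
        w_strat = np.where(counts > 0, pops / np.maximum(counts, 1), 0.0)
    weight = w_strat[stratum_idx]
    hpsa_col = demo.strata["hpsa"].to_numpy()
    for level in HPSA_LEVELS:
        mask_s = hpsa_col == level
        level_pop = pops[mask_s].sum()
        represented = (pops[mask_s] * (counts[mask_s] > 0)).sum()
        if represented > 0 and level_pop > 0:
            factor = level_pop / represented
            weight[np.isin(stratum_idx, np.flatnonzero(mask_s))] *= factor
    return Population(demo.strata, stratum_idx, age, weight)


def assign_baseline_states(pop: Population, baseline: BaselineStates,
                           utilization: UtilizationModel, seed: int) -> Population:
    """Seed caries experience, untreated flags, and utilization probabilities.

    The probability of entering with caries experience comes from the
    single-year-of-age profile (whose band means equal the configured group
    targets), shifted on the log-odds scale by race/income/shortage-status
    offsets re-centred (population-weighted) within each age group so group
    fractions are recovered in expectation.
    """
    baseline.validate()
    g = pop.age_group_idx
    profile = baseline.age_profile()
    base_p = profile[np.clip(pop.age, 0, 19)]

    race_off = np.array([baseline.race_logit[r] for r in RACES])[pop.codes["race"]]
    hpsa_off = np.array([baseline.hpsa_logit[h] for h in HPSA_LEVELS])[pop.codes["hpsa"]]
    inc_off = np.array([baseline.income_logit[i] for i in INCOMES])[pop.codes["income"]]
    offset = race_off + hpsa_off + inc_off
    # centre offsets within age group (weighted) so group means stay on target
    for gi in range(len(AGE_GROUPS)):
        m = g == gi
        if m.any():
            offset[m] -= np.average(offset[m], weights=pop.weight[m])

    with np.errstate(divide="ignore"):
        lo = logit(np.clip(base_p, 1e-12, 1 - 1e-12))
    p = np.where(base_p <= 0, 0.0, np.where(base_p >= 1, 1.0, expit(lo + offset)))

    rng = stream(seed, TAG_BASELINE)
    u = rng.random(pop.n)
    ever = u < p
    extra = rng.poisson(baseline.extra_event_rate * np.maximum(pop.age, 0))
    pop.caries_events[:] = np.where(ever, 1 + extra, 0).astype(np.int16)
    u2 = rng.random(pop.n)
    pop.untreated[:] = ever & (u2 < baseline.p_untreated)
    pop.abscess_count[:] = 0
    pop.teeth_lost[:] = 0
    pop.util_prob[:] = utilization.probability(pop.codes["income"], pop.codes["hpsa"])
    pop.baseline_assigned = True
    return pop


# ---------------------------------------------------------------------------
# Packaged default demographic configuration (documented assumptions)
# ---------------------------------------------------------------------------

# Marginal shares; race/income/residence distributions differ by shortage
# status to reflect the higher concentration of low-income, Hispanic/Black,
# and rural children in shortage areas.
_DEFAULT_HPSA_SHARES = {"none": 0.82, "partial": 0.08, "whole": 0.10}
_DEFAULT_AGE_SHARES = {"0-5": 0.30, "6-12": 0.35, "13-19": 0.35}
_DEFAULT_RACE_BY_HPSA = {
    "none": {"hispanic": 0.25, "nh_black": 0.14, "nh_white": 0.61},
    "partial": {"hispanic": 0.28, "nh_black": 0.18, "nh_white": 0.54},
    "whole": {"hispanic": 0.32, "nh_black": 0.22, "nh_white": 0.46},
}
_DEFAULT_INCOME_BY_HPSA = {
    "none": {"low": 0.26, "middle": 0.34, "high": 0.40},
    "partial": {"low": 0.34, "middle": 0.36, "high": 0.30},
    "whole": {"low": 0.42, "middle": 0.36, "high": 0.22},
}
_DEFAULT_RESIDENCE_BY_HPSA = {
    "none": {"urban": 0.88, "rural": 0.12},
    "partial": {"urban": 0.75, "rural": 0.25},
    "whole": {"urban": 0.55, "rural": 0.45},
}
_DEFAULT_HPSA_CHILDREN = 14.7e6  # children living in designated shortage areas


def default_demographics() -> DemographicConfig:
    """Packaged default joint demographic distribution (assumption-based)."""
    hpsa_share = sum(v for k, v in _DEFAULT_HPSA_SHARES.items() if k != "none")
    total = _DEFAULT_HPSA_CHILDREN / hpsa_share
    rows = []
    for hpsa, ph in _DEFAULT_HPSA_SHARES.items():
        for ag, pa in _DEFAULT_AGE_SHARES.items():
            for sex in SEXES:
                for race, pr in _DEFAULT_RACE_BY_HPSA[hpsa].items():
                    for inc, pi in _DEFAULT_INCOME_BY_HPSA[hpsa].items():
                        for res, pu in _DEFAULT_RESIDENCE_BY_HPSA[hpsa].items():
                            rows.append({
                                "age_group": ag, "sex": sex, "race": race,
                                "income": inc, "residence": res, "hpsa": hpsa,
                                "proportion": ph * pa * 0.5 * pr * pi * pu,
                            })
    strata = pd.DataFrame(rows)
    strata["proportion"] /= strata["proportion"].sum()
    return DemographicConfig(
        strata=strata,
        total_child_population=total,
        hpsa_child_population=_DEFAULT_HPSA_CHILDREN,
    )
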