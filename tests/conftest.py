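import copy

import numpy as np
import pandas as pd
import pytest

import cariesim as cs
from cariesim.popsynth import DIMENSIONS


def make_demo(proportions, total=1_000_000.0, **overrides):
    """Small demographic config from a list of (stratum dict, proportion)."""
    rows = []
    for strat, p in proportions:
        row = {"age_group": "6-12", "sex": "female", "race": "nh_white",
               "income": "middle", "residence": "urban", "hpsa": "none"}
        row.update(strat)
        row["proportion"] = p
        rows.append(row)
    strata = pd.DataFrame(rows)
    hpsa = strata["hpsa"].isin(("partial", "whole"))
    hpsa_total = float(strata.loc[hpsa, "proportion"].sum() * total)
    kwargs = dict(total_child_population=total,
                  hpsa_child_population=hpsa_total if hpsa_total > 0 else total)
    kwargs.update(overrides)
    if hpsa_total == 0:
        # keep the invariant satisfiable for configs with no shortage strata
        strata.loc[strata.index[-1], "hpsa"] = "whole"
        kwargs["hpsa_child_population"] = float(
            strata.loc[strata["hpsa"] != "none", "proportion"].sum() * total)
    return cs.DemographicConfig(strata=strata, **kwargs)


def zeroed_risk_model(**overrides):
    """Risk model with every log-odds term zero and no progression/mortality."""
    rm = cs.RiskModel(
        intercept={g: 0.0 for g in ("0-5", "6-12", "13-19")},
        age_logit=[0.0] * 20,
        sex_logit={"female": 0.0, "male": 0.0},
        race_logit={"hispanic": 0.0, "nh_black": 0.0, "nh_white": 0.0},
        income_logit={"low": 0.0, "middle": 0.0, "high": 0.0},
        residence_logit={"urban": 0.0, "rural": 0.0},
        hpsa_logit={"none": 0.0, "partial": 0.0, "whole": 0.0},
        prior_caries_logit=0.0,
        p_untreated_no_util=0.0,
        p_untreated_util=0.0,
        p_abscess=0.0,
        p_toothloss=0.0,
        mortality_bands=[[200, 0.0]],
    )
    for k, v in overrides.items():
        setattr(rm, k, v)
    return rm


def single_individual(age=8, **stratum):
    demo = make_demo([(dict(stratum), 1.0)])
    pop = cs.generate_population(1, demo, seed=0)
    pop.age[:] = age
    pop.util_prob[:] = 0.0
    pop.baseline_assigned = True
    return pop


@pytest.fixture(scope="session")
def default_params():
    return cs.default_parameters()


@pytest.fixture(scope="session")
def pop20k(default_params):
    pop = cs.generate_population(20000, default_params.demographics, seed=1)
    return cs.assign_baseline_states(pop, default_params.baseline,
                                     default_params.utilization, seed=1)


@pytest.fixture(scope="session")
def calibrated_params(default_params, pop20k):
    params = default_params.copy()
    params.risk, report = cs.calibrate(
        params.risk, params.calibration_targets, pop20k,
        cs.CalibrationSettings(disease_seed=1))
    params.calibration_report = report
    return params


@pytest.fixture(scope="session")
def pop5k(default_params):
    pop = cs.generate_population(5000, default_params.demographics, seed=3)
    return cs.assign_baseline_states(pop, default_params.baseline,
                                     default_params.utilization, seed=3)
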