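# cariesim

Individual-level microsimulation of dental-caries burden among US children,
focused on federally designated dental shortage areas (HPSAs) and the effect
of expanding the National Health Service Corps (NHSC) dental workforce.
The package couples a seeded synthetic-population generator, an annual-cycle
caries natural-history model calibrated to prevalence targets, a
budget-to-dentist-FTE workforce pipeline, health-care-perspective cost/QALY
accounting with discounting, and one-way plus probabilistic sensitivity
analysis with cost-effectiveness acceptability curves.

All runs are reproducible bit-for-bit from seeds: every stochastic draw comes
from a counter-based (Philox) stream keyed by `(seed, event slot, cycle)` and
indexed by individual, so compared scenarios share common random numbers and
incremental outcomes isolate the intervention.

Packaged default parameters (demographic stratum proportions, unit costs,
disutility weights, program constants, baseline risks) are documented
assumptions standing in for restricted/unpublished source tables; every value
can be overridden from a YAML file.

## Layout

| module | role |
|---|---|
| `cariesim.popsynth` | synthetic populations: joint demographic strata, exact-weight quotas, baseline oral-health states |
| `cariesim.natural_history` | annual caries risk (additive logistic), untreated-caries progression (abscess, tooth loss), mortality, calibration |
| `cariesim.workforce` | award projections, award-cohort FTE ledger, dentist-density deltas, supply effects on utilization and caries odds |
| `cariesim.economics` | unit costs, disutility weights, discounting, program cost |
| `cariesim.engine` | scenario orchestration, weighted aggregation, incremental outcomes (ICER / NMB) |
| `cariesim.uncertainty` | tornado analysis, probabilistic sensitivity analysis, CEAC |
| `cariesim.config` | `ParameterSet` assembly and YAML round-tripping |
| `cariesim.cli` | `cariesim` command-line interface |

## CLI

```bash
# generate a population
cariesim population --n 10000 --seed 42 --out pop.csv

# calibrate risk adjustments to the packaged prevalence targets
cariesim calibrate --n 20000 --seed 42 --out-params calibrated.yaml --report calibration.csv

# run intervention scenarios against the status quo
cariesim simulate --config calibrated.yaml --growth 0.10 --growth 0.30 \
    --n 10000 --seed 42 --out results/

# sensitivity analyses
cariesim sensitivity one-way --config calibrated.yaml --out tornado.csv
cariesim sensitivity psa --config calibrated.yaml --draws 1000 --out psa/
cariesim sensitivity ceac --draws psa/psa_draws.csv --out ceac.csv
```

`simulate` writes a headline table (`scenario_results.csv`: change in
prevalence in percentage points, cumulative decayed-tooth incidence in
millions, QALYs in thousands, cost in $ millions, ICER/dominance, NMB)
plus per-stratum and per-year CSVs.

## Python API sketch

```python
import cariesim as cs

params = cs.default_parameters()
pop = cs.generate_population(20000, params.demographics, seed=1)
cs.assign_baseline_states(pop, params.baseline, params.utilization, seed=1)
params.risk, report = cs.calibrate(params.risk, params.calibration_targets,
                                   pop, cs.CalibrationSettings(disease_seed=1))

base = cs.run_scenario(pop, params, cs.ScenarioConfig(disease_seed=1))
scen = cs.run_scenario(pop, params, cs.ScenarioConfig(
    label="g10", budget_growth=0.10, disease_seed=1))
print(cs.incremental(scen, base))

summary = cs.psa(params, pop, cs.ScenarioConfig(
    label="g10", budget_growth=0.10, disease_seed=2), n_draws=1000, master_seed=7)
print(summary.outcomes)
print(summary.ceac)
```

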