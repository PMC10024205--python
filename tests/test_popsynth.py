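import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cariesim as cs
from cariesim.errors import ConfigurationError
from cariesim.popsynth import AGE_GROUP_BOUNDS, MEASURE_BANDS

from conftest import make_demo


class TestGeneratePopulation:
    def test_degenerate_single_stratum(self):
        demo = make_demo([({"hpsa": "whole"}, 1.0)])
        pop = cs.generate_population(10000, demo, seed=1)
        assert pop.n == 10000
        assert (pop.stratum_idx == 0).all()

    def test_two_strata_binomial_oracle(self):
        # counts should fall within 3 SD of Binomial(n, 0.3)
        demo = make_demo([({"sex": "female"}, 0.3), ({"sex": "male"}, 0.7)])
        n = 100_000
        pop = cs.generate_population(n, demo, seed=7)
        count0 = int((pop.stratum_idx == 0).sum())
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(count0 - n * 0.3) <= 3 * sd
        # largest-remainder quotas are much tighter than binomial
        assert abs(count0 - n * 0.3) <= 1

    def test_hpsa_weight_total_matches_configured_population(self, default_params):
        demo = default_params.demographics
        pop = cs.generate_population(10000, demo, seed=1)
        hpsa_weight = pop.weight[pop.is_hpsa].sum()
        assert hpsa_weight == pytest.approx(demo.hpsa_child_population, rel=1e-9)

    def test_weight_conservation_total(self, default_params):
        demo = default_params.demographics
        for n in (1000, 10000, 20000):
            pop = cs.generate_population(n, demo, seed=5)
            assert pop.weight.sum() == pytest.approx(
                demo.total_child_population, rel=1e-9)

    def test_weight_equals_stratum_population_over_count(self, default_params):
        demo = default_params.demographics
        pop = cs.generate_population(50000, demo, seed=2)
        pops = demo.stratum_populations()
        counts = np.bincount(pop.stratum_idx, minlength=demo.n_strata)
        for s in np.flatnonzero(counts):
            w = pop.weight[pop.stratum_idx == s]
            # within-level rescale for unrepresented strata may nudge weights
            assert w[0] == pytest.approx(pops[s] / counts[s], rel=1e-2)
            assert (w == w[0]).all()

    def test_reproducible_bit_for_bit(self, default_params):
        demo = default_params.demographics
        a = cs.generate_population(5000, demo, seed=11)
        b = cs.generate_population(5000, demo, seed=11)
        c = cs.generate_population(5000, demo, seed=12)
        assert (a.stratum_idx == b.stratum_idx).all()
        assert (a.age == b.age).all()
        assert (a.weight == b.weight).all()
        assert (a.age != c.age).any() or (a.stratum_idx != c.stratum_idx).any()

    def test_ages_within_group_bounds(self, default_params):
        pop = cs.generate_population(20000, default_params.demographics, seed=4)
        groups = default_params.demographics.strata["age_group"].to_numpy()
        for g, (lo, hi) in AGE_GROUP_BOUNDS.items():
            m = groups[pop.stratum_idx] == g
            assert pop.age[m].min() >= lo
            assert pop.age[m].max() <= hi

    def test_negative_proportion_names_stratum(self):
        with pytest.raises(ConfigurationError, match="male"):
            make_demo([({"sex": "female"}, 1.2), ({"sex": "male"}, -0.2)])

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            make_demo([({"sex": "female"}, 0.5), ({"sex": "male"}, 0.4)])

    def test_duplicate_stratum_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            make_demo([({"hpsa": "whole"}, 0.5), ({"hpsa": "whole"}, 0.5)])

    def test_n_must_be_positive(self, default_params):
        with pytest.raises(ConfigurationError):
            cs.generate_population(0, default_params.demographics, seed=1)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(10, 5000), st.integers(0, 2**31 - 1),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_largest_remainder_quota_property(self, n, seed, raw):
        # every stratum count is floor(n*p) or floor(n*p)+1
        p = np.array(raw) / np.sum(raw)
        sexes = ["female", "male"]
        races = ["hispanic", "nh_black", "nh_white"]
        demo = make_demo([({"sex": sexes[i % 2], "race": races[i // 2]}, pi)
                          for i, pi in enumerate(p)])
        pop = cs.generate_population(n, demo, seed=seed)
        counts = np.bincount(pop.stratum_idx, minlength=len(p))
        assert counts.sum() == n
        assert (counts >= np.floor(n * p)).all()
        assert (counts <= np.floor(n * p) + 1).all()

    def test_marginal_recovery(self, default_params):
        # simulated frequencies approach configured proportions ~ n^(-1/2)
        demo = default_params.demographics
        pop = cs.generate_population(100_000, demo, seed=9)
        for dim in ("race", "income", "hpsa"):
            target = demo.strata.groupby(dim)["proportion"].sum()
            obs = (pd.Series(demo.strata[dim].to_numpy()[pop.stratum_idx])
                   .value_counts(normalize=True))
            for k, t in target.items():
                assert obs[k] == pytest.approx(t, abs=0.01)


class TestAssignBaselineStates:
    def test_targets_all_zero(self, default_params):
        pop = cs.generate_population(2000, default_params.demographics, seed=1)
        baseline = cs.BaselineStates(
            age_group_targets={"0-5": 0.0, "6-12": 0.0, "13-19": 0.0})
        cs.assign_baseline_states(pop, baseline, default_params.utilization, seed=1)
        assert not pop.ever_caries.any()
        assert not pop.untreated.any()

    def test_targets_all_one(self, default_params):
        pop = cs.generate_population(2000, default_params.demographics, seed=1)
        baseline = cs.BaselineStates(
            age_group_targets={"0-5": 1.0, "6-12": 1.0, "13-19": 1.0},
            under2_factor=1.0,
            band_shape={g: (1.0, 1.0) for g in ("0-5", "6-12", "13-19")})
        cs.assign_baseline_states(pop, baseline, default_params.utilization, seed=1)
        assert pop.ever_caries.all()

    def test_age_band_target_binomial_oracle(self, default_params):
        # fraction with caries in the 2-5 band within 3 SD of the 0.213 target
        pop = cs.generate_population(50000, default_params.demographics, seed=6)
        cs.assign_baseline_states(pop, default_params.baseline,
                                  default_params.utilization, seed=6)
        lo, hi = MEASURE_BANDS["0-5"]
        m = (pop.age >= lo) & (pop.age <= hi)
        frac = np.average(pop.ever_caries[m], weights=pop.weight[m])
        n_band = int(m.sum())
        sd = np.sqrt(0.213 * 0.787 / n_band)
        assert abs(frac - 0.213) <= 3 * sd

    def test_missing_target_is_configuration_error(self, default_params):
        pop = cs.generate_population(100, default_params.demographics, seed=1)
        baseline = cs.BaselineStates(age_group_targets={"0-5": 0.2})
        with pytest.raises(ConfigurationError, match="6-12"):
            cs.assign_baseline_states(pop, baseline,
                                      default_params.utilization, seed=1)

    def test_target_outside_unit_interval_rejected(self, default_params):
        pop = cs.generate_population(100, default_params.demographics, seed=1)
        baseline = cs.BaselineStates(
            age_group_targets={"0-5": 1.3, "6-12": 0.5, "13-19": 0.5})
        with pytest.raises(ConfigurationError):
            cs.assign_baseline_states(pop, baseline,
                                      default_params.utilization, seed=1)

    def test_untreated_share(self, pop20k, default_params):
        share = pop20k.untreated[pop20k.ever_caries].mean()
        assert share == pytest.approx(default_params.baseline.p_untreated, abs=0.02)

    def test_reproducible(self, default_params):
        pops = []
        for _ in range(2):
            p = cs.generate_population(3000, default_params.demographics, seed=8)
            cs.assign_baseline_states(p, default_params.baseline,
                                      default_params.utilization, seed=8)
            pops.append(p)
        assert (pops[0].caries_events == pops[1].caries_events).all()
        assert (pops[0].untreated == pops[1].untreated).all()


class TestSerialization:
    def test_demographics_yaml_roundtrip(self, default_params, tmp_path):
        demo = default_params.demographics
        path = tmp_path / "demo.yaml"
        demo.to_yaml(path)
        back = cs.DemographicConfig.from_yaml(path)
        pd.testing.assert_frame_equal(back.strata, demo.strata)
        assert back.total_child_population == demo.total_child_population

    def test_population_csv(self, pop5k, tmp_path):
        path = tmp_path / "pop.csv"
        pop5k.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == pop5k.n
        for col in ("age", "weight", "caries_events", "hpsa", "race"):
            assert col in df.columns
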