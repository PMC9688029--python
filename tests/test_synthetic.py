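"""Generator contracts: reproducibility, survival law, growth law, binning."""

import numpy as np
import pandas as pd
import pytest

import lenstock as ls
from lenstock.synthetic import LogisticSelectivity


class TestSimulatePopulation:
    def test_seeded_reproducibility(self):
        p = ls.PopulationParams(recruits_per_pulse=200, n_years=5)
        a = ls.simulate_population(p, seed=42)
        b = ls.simulate_population(p, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = ls.simulate_population(p, seed=43)
        assert not a["length"].equals(c["length"])

    def test_no_mortality_gives_equal_age_classes(self):
        p = ls.PopulationParams(z=0.0, recruits_per_pulse=500, n_years=10)
        pop = ls.simulate_population(p, seed=0)
        assert pop["alive"].all()
        counts = pop.groupby(np.floor(pop["age"]).astype(int)).size()
        assert (counts == 500).all()

    def test_mean_length_at_age_five_matches_growth_curve(self):
        # oracle: direct evaluation of the mean curve, 171.62*(1-exp(-0.12*5))
        p = ls.PopulationParams(
            linf_mean=171.62, k=0.12, z=0.47, recruits_per_pulse=120_000, n_years=7
        )
        pop = ls.simulate_population(p, seed=1)
        ages = sorted(pop["age"].unique())
        target_age = min(ages, key=lambda a: abs(a - 5.0))
        sub = pop[np.isclose(pop["age"], target_age)]
        expected = 171.62 * (1 - np.exp(-0.12 * target_age))
        assert len(sub) >= 1e5
        assert sub["length"].mean() == pytest.approx(expected, rel=0.01)

    def test_length_never_exceeds_individual_linf(self):
        p = ls.PopulationParams(recruits_per_pulse=300, n_years=15)
        pop = ls.simulate_population(p, seed=2)
        assert (pop["length"] <= pop["linf_i"] + 1e-9).all()

    def test_survival_curve_matches_exponential(self):
        z = 0.4
        p = ls.PopulationParams(z=z, recruits_per_pulse=50_000, n_years=8)
        pop = ls.simulate_population(p, seed=3)
        for age, sub in pop.groupby("age"):
            frac = sub["alive"].mean()
            expected = np.exp(-z * age)
            se = np.sqrt(expected * (1 - expected) / len(sub))
            assert abs(frac - expected) < 5 * se + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ls.simulate_population(ls.PopulationParams(linf_mean=-5), seed=0)
        with pytest.raises(ValueError):
            ls.simulate_population(ls.PopulationParams(k=np.nan), seed=0)
        with pytest.raises(ValueError):
            ls.simulate_population(ls.PopulationParams(prop_female=1.5), seed=0)


class TestSampleLfq:
    def test_knife_edge_at_zero_counts_everyone(self):
        p = ls.PopulationParams(recruits_per_pulse=100, n_years=5, z=0.0)
        pop = ls.simulate_population(p, seed=0)
        sel = LogisticSelectivity(l50=0.0, slope=np.inf)
        lfq = ls.sample_lfq(pop, sel, 5.0, ["2020-01"], seed=1)
        assert lfq.total() == len(pop)

    def test_binning_convention_left_closed(self):
        ind = pd.DataFrame({"length": [87.0]})
        lfq = ls.sample_lfq(ind, None, 5.0, ["2020-01"])
        assert lfq.bin_lower[0] == 85.0
        assert lfq.counts[0, 0] == 1

    def test_knife_edge_retained_fraction(self, rng):
        lengths = rng.uniform(50, 150, 20_000)
        ind = pd.DataFrame({"length": lengths})
        sel = LogisticSelectivity(l50=100.0, slope=np.inf)
        lfq = ls.sample_lfq(ind, sel, 5.0, ["2020-01"], seed=2)
        frac = lfq.total() / len(ind)
        assert frac == pytest.approx((lengths >= 100).mean(), abs=1e-12)

    def test_empty_table_gives_declared_bins(self):
        lfq = ls.sample_lfq(
            pd.DataFrame(columns=["length"]), None, 5.0, ["2020-01", "2020-02"],
            bin_range=(80, 100),
        )
        assert lfq.counts.shape == (4, 2)  # [80,100) in 5 cm bins
        assert lfq.total() == 0

    def test_count_conservation(self):
        p = ls.PopulationParams(recruits_per_pulse=400, n_years=6)
        pop = ls.simulate_population(p, seed=5, sample_times=[6.0, 6.5])
        sel = LogisticSelectivity(30.0, 0.3)
        rng = np.random.default_rng(9)
        alive = pop[pop["alive"]]
        keep = rng.random(len(alive)) < sel.retention(alive["length"])
        lfq = ls.sample_lfq(pop, sel, 5.0, ["2020-01", "2020-07"], seed=9)
        assert lfq.total() == keep.sum()


class TestSurveyRecords:
    def test_seeded_reproducibility(self):
        sp = ls.SpatialFieldParams()
        a = ls.simulate_survey_records(sp, 500, seed=7)
        b = ls.simulate_survey_records(sp, 500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_field_is_deterministic_in_covariates(self):
        sp = ls.SpatialFieldParams(zero_inflation=0.0, noise_sd=0.0)
        rec = ls.simulate_survey_records(sp, 400, seed=0)
        pos = rec[rec["rpn"] > 0]
        # same depth+substrate -> same rpn: check via the generating formula
        bump = np.exp(-0.5 * ((pos["depth"] - sp.depth_opt) / sp.depth_sd) ** 2)
        sub = pos["substrate"].map(lambda s: sp.substrate_effects.get(s, 0.0))
        expected = np.exp(np.log(sp.rpn_scale) + sp.depth_amplitude * (bump - 1) + sub)
        np.testing.assert_allclose(pos["rpn"], expected, rtol=1e-9)

    def test_presence_higher_at_depth_optimum(self):
        sp = ls.SpatialFieldParams()
        rec = ls.simulate_survey_records(sp, 20_000, seed=1)
        near = rec[np.abs(rec["depth"] - sp.depth_opt) < 40]
        far = rec[np.abs(rec["depth"] - sp.depth_opt) > 4 * sp.depth_sd - 40]
        assert (near["rpn"] > 0).mean() > (far["rpn"] > 0).mean() + 0.2

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ValueError, match="substrate"):
            ls.SpatialFieldParams(substrate_effects={"Granite": 1.0}).validate()


class TestTripRecords:
    def test_seeded_reproducibility(self):
        fp = ls.FleetParams()
        a = ls.simulate_trip_records(fp, 300, seed=11)
        b = ls.simulate_trip_records(fp, 300, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_all_equal(self):
        fp = ls.FleetParams(lognormal_sd=0.0, p_zero=0.0)
        trips = ls.simulate_trip_records(fp, 200, seed=0)
        assert np.allclose(trips["catch"], fp.base_catch)

    def test_doubling_year_effects_double_geometric_means(self):
        years = {2010 + i: 2.0 ** i for i in range(4)}
        fp = ls.FleetParams(year_effects=years, lognormal_sd=0.4, p_zero=0.1)
        trips = ls.simulate_trip_records(fp, 40_000, seed=2)
        pos = trips[trips["catch"] > 0]
        gm = pos.groupby("year")["catch"].apply(lambda c: np.exp(np.log(c).mean()))
        ratios = gm.values[1:] / gm.values[:-1]
        assert np.allclose(ratios, 2.0, rtol=0.05)

    def test_empty_year_effects_rejected(self):
        with pytest.raises(ValueError, match="year_effects"):
            ls.simulate_trip_records(ls.FleetParams(year_effects={}), 10, seed=0)
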