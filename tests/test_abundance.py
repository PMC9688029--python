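"""CPUE standardization, min-max normalization and ANCOVA trend comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import lenstock as ls


def make_index(name, years, values):
    t = pd.DataFrame(
        {
            "year": years,
            "index": values,
            "se": 0.0,
            "normalized": values,
        }
    )
    return ls.AbundanceIndex(name=name, table=t)


class TestMinMax:
    def test_basic(self):
        np.testing.assert_allclose(ls.minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        np.testing.assert_allclose(
            ls.minmax_normalize(x), ls.minmax_normalize(3.7 * x + 11.0), atol=1e-12
        )

    def test_direct_arithmetic_example(self):
        out = ls.minmax_normalize([0.47, 0.25, 0.22])
        np.testing.assert_allclose(out, [1.0, 0.12, 0.0])

    def test_idempotent(self, rng):
        x = rng.random(15)
        once = ls.minmax_normalize(x)
        np.testing.assert_allclose(ls.minmax_normalize(once), once, atol=1e-15)

    def test_constant_series_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ls.minmax_normalize([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(out, 0.5)


class TestStandardize:
    def test_balanced_noiseless_year_effects_exact(self):
        fp = ls.FleetParams(
            year_effects={2010: 1.0, 2011: 2.0, 2012: 4.0},
            lognormal_sd=0.0,
            p_zero=0.0,
        )
        trips = ls.simulate_trip_records(fp, 480, seed=0, balanced=True)
        idx = ls.standardize_cpue_hurdle(trips)
        v = idx.values
        assert v[1] / v[0] == pytest.approx(2.0, rel=1e-9)
        assert v[2] / v[0] == pytest.approx(4.0, rel=1e-9)
        np.testing.assert_allclose(idx.table["normalized"], [0.0, 1 / 3, 1.0])

    def test_confounded_design_standardized_flat(self):
        fp = ls.FleetParams(
            year_effects={y: 1.0 for y in range(2010, 2018)},
            vessel_effects={"small": 1.0, "large": 3.0},
            lognormal_sd=0.3,
            p_zero=0.2,
        )
        trips = ls.simulate_trip_records(fp, 5000, seed=7, vessel_trend=0.1)
        nominal = trips[trips.catch > 0].groupby("year").apply(
            lambda d: (d.catch / d.effort).mean(), include_groups=False
        )
        nom_reg = stats.linregress(nominal.index, nominal.values)
        assert nom_reg.pvalue < 0.01  # nominal CPUE spuriously trends
        idx = ls.standardize_cpue_hurdle(trips)
        reg = stats.linregress(idx.years, idx.values)
        half_ci = stats.t.ppf(0.975, len(idx.years) - 2) * reg.stderr
        assert abs(reg.slope) < half_ci  # CI of the standardized slope covers 0

    def test_single_year_degenerate(self):
        fp = ls.FleetParams(year_effects={2015: 1.0}, lognormal_sd=0.1, p_zero=0.0)
        trips = ls.simulate_trip_records(fp, 100, seed=1)
        with pytest.warns(UserWarning, match="single year|constant"):
            idx = ls.standardize_cpue_hurdle(trips)
        assert len(idx.table) == 1
        assert idx.table["normalized"].iloc[0] == 0.5

    def test_year_without_positive_trips_flagged(self):
        fp = ls.FleetParams(
            year_effects={2010: 1.0, 2011: 1.0, 2012: 1.0}, p_zero=0.0
        )
        trips = ls.simulate_trip_records(fp, 600, seed=3)
        trips.loc[trips["year"] == 2011, "catch"] = 0.0
        with pytest.warns(UserWarning, match="no positive trips"):
            idx = ls.standardize_cpue_hurdle(trips)
        assert idx.undefined_years == [2011]
        assert np.isnan(
            idx.table.loc[idx.table["year"] == 2011, "index"].iloc[0]
        )


class TestAncova:
    def test_identical_series(self):
        years = np.arange(2000, 2015)
        vals = 1.0 - 0.02 * (years - 2000)
        idxs = [make_index(n, years, vals) for n in ("CPUE", "LPUE", "RPN")]
        cmp = ls.compare_trends_ancova(idxs)
        assert cmp.interaction_f == pytest.approx(0.0, abs=1e-9)
        assert cmp.interaction_p == pytest.approx(1.0)
        assert (cmp.tukey["pvalue"] > 0.999).all()
        assert np.allclose(cmp.tukey["estimate"], 0.0, atol=1e-12)

    def test_parallel_offset_series(self):
        # slopes equal; one series offset upward: interaction null, only the
        # offset index's two intercept contrasts significant
        years = np.arange(2000, 2020)
        base = 1.0 - 0.02 * (years - 2000)
        idxs = [
            make_index("CPUE", years, base),
            make_index("LPUE", years, base),
            make_index("RPN", years, base + 0.3),
        ]
        cmp = ls.compare_trends_ancova(idxs)
        assert cmp.interaction_p > 0.05
        assert cmp.parallel
        tuk = cmp.tukey.set_index(["index_a", "index_b"])
        assert tuk.loc[("CPUE", "RPN"), "pvalue"] < 0.05
        assert tuk.loc[("LPUE", "RPN"), "pvalue"] < 0.05
        assert tuk.loc[("CPUE", "LPUE"), "pvalue"] > 0.05

    def test_opposite_slopes_interaction_significant(self):
        years = np.arange(2000, 2015)
        up = 0.02 * (years - 2000)
        idxs = [make_index("A", years, up), make_index("B", years, up[::-1])]
        cmp = ls.compare_trends_ancova(idxs)
        assert cmp.interaction_p < 0.05
        assert not cmp.parallel
        assert cmp.tukey is None

    def test_interaction_matches_anova_lm_oracle(self, rng):
        years = np.arange(2000, 2016)
        idxs = [
            make_index(n, years, 1 - 0.01 * (years - 2000) + rng.normal(0, 0.1, 16))
            for n in ("A", "B", "C")
        ]
        cmp = ls.compare_trends_ancova(idxs)
        df = pd.concat(
            [
                pd.DataFrame({"year": i.years, "value": i.table["normalized"],
                              "idx": i.name})
                for i in idxs
            ]
        )
        fit = sm.OLS.from_formula("value ~ year * C(idx)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert cmp.interaction_f == pytest.approx(tab.loc["year:C(idx)", "F"], rel=1e-6)
        assert cmp.interaction_p == pytest.approx(
            tab.loc["year:C(idx)", "PR(>F)"], rel=1e-6
        )

    def test_short_series_rejected(self):
        years = np.array([2000, 2001])
        with pytest.raises(ValueError, match="fewer than 3"):
            ls.compare_trends_ancova(
                [make_index("A", years, [1, 2]), make_index("B", years, [2, 1])]
            )
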