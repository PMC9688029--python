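"""Growth module: VBGF algebra, restructuring, Rn scoring, GA fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lenstock as ls
from lenstock.growth import (
    GASettings,
    RestructuredLFQ,
    VBGFParams,
    elefan_score,
    restructure_lfq,
)
from lenstock.lfq import LengthFrequencyTable


class TestVBGF:
    def test_zero_age_gives_zero_length(self):
        assert ls.vbgf_length_at_age(VBGFParams(170, 0.12), 0.0) == 0.0

    def test_asymptote(self):
        p = VBGFParams(170, 0.12)
        assert ls.vbgf_length_at_age(p, 100 / p.k) == pytest.approx(170, rel=1e-9)

    def test_point_estimate_evaluation(self):
        # 171.62*(1-exp(-3)) at t=25 with k=0.12
        p = VBGFParams(171.62, 0.12)
        assert ls.vbgf_length_at_age(p, 25.0) == pytest.approx(163.08, abs=0.01)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            ls.vbgf_length_at_age(VBGFParams(170, 0.12), -1.0)

    def test_inverse_at_zero_and_half_linf(self):
        p = VBGFParams(170, 0.12)
        assert ls.inverse_vbgf_age_at_length(p, 0.0) == 0.0
        assert ls.inverse_vbgf_age_at_length(p, 85.0) == pytest.approx(
            np.log(2) / 0.12, rel=1e-12
        )

    def test_inverse_rejects_lengths_at_or_above_linf(self):
        with pytest.raises(ValueError):
            ls.inverse_vbgf_age_at_length(VBGFParams(170, 0.12), 170.0)

    @given(
        st.floats(min_value=0.0, max_value=0.99),
        st.floats(min_value=50, max_value=250),
        st.floats(min_value=0.05, max_value=0.9),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, frac, linf, k):
        p = VBGFParams(linf, k)
        length = frac * linf
        t = ls.inverse_vbgf_age_at_length(p, length)
        assert ls.vbgf_length_at_age(p, t) == pytest.approx(length, abs=1e-9 * linf)


class TestPhiPrime:
    @pytest.mark.parametrize(
        "linf,k,expected",
        [(100, 0.1, 3.0), (10, 1.0, 2.0), (171.62, 0.12, 3.5483)],
    )
    def test_values(self, linf, k, expected):
        assert ls.growth_performance_phi(linf, k) == pytest.approx(expected, abs=5e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ls.growth_performance_phi(0, 0.1)


def _lfq(counts, start=0.0, width=5.0, dates=("2020-01",)):
    counts = np.atleast_2d(np.asarray(counts, float))
    if counts.shape[0] == 1 and len(dates) == 1:
        counts = counts.T
    lowers = start + width * np.arange(counts.shape[0])
    t = LengthFrequencyTable(lowers, list(dates), counts)
    t.set_width(width)
    return t


class TestRestructure:
    def test_uniform_counts_score_zero(self):
        r = restructure_lfq(_lfq([7, 7, 7, 7, 7, 7, 7]), ma=5)
        np.testing.assert_allclose(r.scores, 0.0, atol=1e-12)

    def test_all_zero_column_scores_zero(self):
        r = restructure_lfq(_lfq([0, 0, 0, 0, 0]), ma=5)
        assert np.all(np.isfinite(r.scores))
        np.testing.assert_array_equal(r.scores, 0.0)

    def test_single_peak_positive_at_peak_only(self):
        r = restructure_lfq(_lfq([0, 0, 10, 0, 0, 0, 0]), ma=5)
        col = r.scores[:, 0]
        assert col[2] > 0
        assert np.all(col[np.arange(7) != 2] <= 0)

    def test_ma_validation(self):
        with pytest.raises(ValueError):
            restructure_lfq(_lfq([1, 2, 3]), ma=4)
        with pytest.raises(ValueError):
            restructure_lfq(_lfq([1, 2, 3]), ma=5)

    def test_asp_nonnegative_and_balanced(self):
        r = restructure_lfq(_lfq([1, 9, 2, 8, 3, 7, 4]), ma=5)
        col = r.scores[:, 0]
        assert r.asp >= 0
        assert col[col > 0].sum() == pytest.approx(-col[col < 0].sum(), rel=1e-9)


class TestElefanScore:
    def _restructured(self, scores, dates):
        scores = np.asarray(scores, float)
        return RestructuredLFQ(
            bin_lower=5.0 * np.arange(scores.shape[0]),
            dates=[pd.Period(d, freq="M") for d in dates],
            scores=scores,
            asp=float(scores[scores > 0].sum()),
            bin_width=5.0,
        )

    def test_perfect_fit_rn_one(self):
        # one cohort born 1.5 years before the single sample; place the only
        # positive score exactly in the crossed bin
        p = VBGFParams(100.0, 0.5, 0.0)
        date = pd.Period("2000-07", freq="M")
        t = date.year + (date.month - 0.5) / 12
        length = 100 * (1 - np.exp(-0.5 * (t - 1999.0)))
        scores = np.zeros((20, 1))
        scores[int(length // 5), 0] = 2.5
        r = self._restructured(scores, ["2000-07"])
        assert elefan_score(r, p) == pytest.approx(1.0)

    def test_all_zero_crossings_rn_point_one(self):
        # positives exist (ASP > 0) but sit where no curve passes
        scores = np.zeros((10, 1))
        scores[9, 0] = 3.0  # bin [45,50): unreachable for linf=30
        r = self._restructured(scores, ["2000-07"])
        assert elefan_score(r, VBGFParams(30.0, 0.5, 0.0)) == pytest.approx(0.1)

    def test_zero_asp_is_an_error(self):
        scores = -np.ones((6, 1))
        r = self._restructured(scores, ["2000-07"])
        with pytest.raises(ValueError, match="ASP"):
            elefan_score(r, VBGFParams(30.0, 0.5, 0.0))

    def test_truth_outscores_distant_parameters(self, benchmark_lfq):
        r = restructure_lfq(benchmark_lfq, ma=5)
        truth = max(
            elefan_score(r, VBGFParams(170.0, 0.12, a))
            for a in np.linspace(0, 0.95, 20)
        )
        wrong = max(
            elefan_score(r, VBGFParams(85.0, 0.36, a))
            for a in np.linspace(0, 0.95, 20)
        )
        assert truth > wrong

    def test_invariant_to_count_rescaling(self, benchmark_lfq):
        p = VBGFParams(165.0, 0.13, 0.2)
        r1 = restructure_lfq(benchmark_lfq, ma=5)
        scaled = LengthFrequencyTable(
            benchmark_lfq.bin_lower, benchmark_lfq.dates, benchmark_lfq.counts * 7.0
        )
        r2 = restructure_lfq(scaled, ma=5)
        assert elefan_score(r1, p) == pytest.approx(elefan_score(r2, p), rel=1e-9)


class TestFitGrowthGA:
    def test_seeded_determinism(self, benchmark_lfq):
        s = GASettings(pop_size=15, generations=10)
        a = ls.fit_growth_ga(benchmark_lfq, ga_settings=s, seed=4)
        b = ls.fit_growth_ga(benchmark_lfq, ga_settings=s, seed=4)
        assert a.point == b.point
        assert a.rn_score == b.rn_score

    def test_single_date_rejected(self):
        lfq = _lfq([1, 2, 3, 2, 1])
        with pytest.raises(ValueError, match="2 sampling dates"):
            ls.fit_growth_ga(lfq)

    def test_parameter_recovery(self, benchmark_lfq):
        fit = ls.fit_growth_ga(benchmark_lfq, seed=1)
        assert fit.point.linf == pytest.approx(170.0, rel=0.10)
        assert fit.point.k == pytest.approx(0.12, rel=0.25)
        assert 0 < fit.rn_score <= 1

    def test_bootstrap_intervals(self, benchmark_lfq):
        s = GASettings(pop_size=15, generations=12)
        fit = ls.fit_growth_ga(benchmark_lfq, ga_settings=s, n_bootstrap=12, seed=2)
        assert fit.n_bootstrap == 12
        assert len(fit.bootstrap_samples) == 12
        for ci in (fit.ci_linf, fit.ci_k, fit.ci_phi):
            assert ci[0] <= ci[1]
        assert (fit.bootstrap_samples["rn"] > 0).all()
        # determinism of the whole bootstrap chain
        fit2 = ls.fit_growth_ga(benchmark_lfq, ga_settings=s, n_bootstrap=12, seed=2)
        assert fit.ci_linf == fit2.ci_linf
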