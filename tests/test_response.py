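"""Percent-of-baseline normalisation, change rates, and group statistics."""

import numpy as np
import pytest
from scipy import stats as sstats

from phrenic import MetricTimeCourse, change_rate, one_sample_t, paired_t, percent_of_baseline, rm_anova_dunnett
from phrenic.response import _dunnett_prob, dunnett_critical_value


def _tc(values, step=10.0, metric="amp_PNA"):
    values = np.asarray(values, dtype=float)
    times = (np.arange(values.size) + 0.5) * step
    return MetricTimeCourse(metric, times, values)


class TestPercentOfBaseline:
    def test_constant_series_is_100(self):
        out = percent_of_baseline(_tc(np.full(30, 2.7)), injection_time=100.0)
        assert np.allclose(out.percent, 100.0)

    def test_arithmetic(self):
        vals = np.full(30, 2.0)
        vals[15:] = 1.6
        out = percent_of_baseline(_tc(vals), injection_time=150.0)
        assert out.percent[20] == pytest.approx(80.0)

    def test_baseline_window_mean_exactly_100(self, rng):
        vals = 1.0 + rng.random(40)
        out = percent_of_baseline(_tc(vals), injection_time=200.0)
        m = (out.times >= 100.0) & (out.times < 200.0)
        assert out.percent[m].mean() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        vals = 1.0 + rng.random(40)
        a = percent_of_baseline(_tc(vals), 200.0).percent
        b = percent_of_baseline(_tc(vals * 37.5), 200.0).percent
        assert np.allclose(a, b, rtol=1e-12)

    def test_gaps_propagate(self):
        vals = np.full(30, 2.0)
        vals[20] = np.nan
        out = percent_of_baseline(_tc(vals), injection_time=150.0)
        assert np.isnan(out.percent[20])

    def test_empty_or_zero_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_of_baseline(_tc(np.ones(5)), injection_time=-10.0)
        with pytest.raises(ValueError, match="zero"):
            percent_of_baseline(_tc(np.zeros(30)), injection_time=100.0)


class TestChangeRate:
    def test_constant_window(self):
        tc = percent_of_baseline(_tc(np.full(60, 1.0)), 150.0)
        tc.percent[:] = 82.1
        assert change_rate(tc, (60.0, 180.0), 150.0) == pytest.approx(82.1)

    def test_two_sample_mean(self):
        tc = percent_of_baseline(_tc(np.full(60, 1.0)), 150.0)
        m = (tc.times >= 210.0) & (tc.times < 230.0)
        tc.percent[m] = [80.0, 90.0]
        assert change_rate(tc, (60.0, 80.0), 150.0) == pytest.approx(85.0)

    def test_empty_window_errors(self):
        tc = percent_of_baseline(_tc(np.full(20, 1.0)), 150.0)
        with pytest.raises(ValueError):
            change_rate(tc, (1000.0, 1100.0), 150.0)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            change_rate(_tc(np.ones(20)), (60.0, 180.0))


class TestOneSampleT:
    def test_symmetric_about_mu0(self):
        g = one_sample_t([98.0, 100.0, 102.0], 100.0)
        assert g.statistic == pytest.approx(0.0)
        assert g.pvalue == pytest.approx(1.0)

    def test_closed_form(self):
        # mean 110, sd 2: t = 10 / (2/sqrt(3)) = 5*sqrt(3), df 2
        g = one_sample_t([110.0, 112.0, 108.0], 100.0)
        assert g.mean == pytest.approx(110.0)
        assert g.statistic == pytest.approx(10.0 / (2.0 / np.sqrt(3)), abs=1e-8)
        assert g.df == 2

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(100, 5, size=rng.integers(3, 12))
            g = one_sample_t(x, 100.0)
            ref = sstats.ttest_1samp(x, 100.0)
            assert g.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert g.pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_zero_variance(self):
        g = one_sample_t([100.0, 100.0], 100.0)
        assert (g.statistic, g.pvalue) == (0.0, 1.0)
        g2 = one_sample_t([105.0, 105.0], 100.0)
        assert g2.degenerate and g2.pvalue == 0.0 and np.isinf(g2.statistic)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([100.0])


class TestPairedT:
    def test_identical_lists(self):
        g = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g.statistic == pytest.approx(0.0)
        assert g.pvalue == pytest.approx(1.0)

    def test_constant_difference_degenerate(self):
        g = paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert g.degenerate
        assert g.pvalue < 1e-12

    def test_closed_form(self):
        # differences {2, 0, -2, 4}: mean 1, sd 2.582, t = 0.7746, df 3
        g = paired_t([0.0, 0.0, 0.0, 0.0], [2.0, 0.0, -2.0, 4.0])
        sd = np.std([2.0, 0.0, -2.0, 4.0], ddof=1)
        assert g.statistic == pytest.approx(1.0 / (sd / 2.0), abs=1e-8)
        assert g.df == 3

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a, b = rng.normal(size=n), rng.normal(size=n)
            g = paired_t(a, b)
            ref = sstats.ttest_rel(b, a)
            assert g.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert g.pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestRMANOVADunnett:
    def test_identical_columns_null(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        res = rm_anova_dunnett(X, control_index=0)
        assert res.F == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert all(g.pvalue == pytest.approx(1.0) for g in res.timepoints)

    def test_anova_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        X = 100 + rng.standard_normal((8, 5)) + rng.standard_normal((8, 1))
        res = rm_anova_dunnett(X, control_index=0)
        long = pd.DataFrame({
            "y": X.ravel(),
            "subject": np.repeat(np.arange(8), 5),
            "time": np.tile(np.arange(5), 8),
        })
        ref = pg.rm_anova(data=long, dv="y", within="time", subject="subject")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.pvalue == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_dunnett_prob_reduces_to_student_t(self):
        for c in (1.0, 2.0, 3.0):
            want = 1.0 - 2.0 * sstats.t.sf(c, 10)
            assert _dunnett_prob(c, 1, 10) == pytest.approx(want, abs=1e-5)

    def test_dunnett_prob_matches_monte_carlo(self):
        # equicorrelated rho=1/2 t family simulated via its factor structure
        rng = np.random.default_rng(0)
        m, df, n_mc = 3, 12, 400_000
        z0 = rng.standard_normal(n_mc)
        zi = rng.standard_normal((n_mc, m))
        w = np.sqrt(rng.chisquare(df, n_mc) / df)
        T = (zi + z0[:, None]) / np.sqrt(2.0) / w[:, None]
        for c in (2.0, 2.5, 3.0):
            mc = np.mean(np.all(np.abs(T) <= c, axis=1))
            assert _dunnett_prob(c, m, df) == pytest.approx(mc, abs=0.01)

    def test_critical_value_consistency(self):
        c = dunnett_critical_value(5, 20, alpha=0.05)
        assert _dunnett_prob(c, 5, 20) == pytest.approx(0.95, abs=1e-4)
        # must exceed the unadjusted two-sided t critical value
        assert c > sstats.t.ppf(0.975, 20)

    def test_power_single_shifted_timepoint(self, rng):
        # one timepoint shifted 5 within-subject SDs: it is flagged, others not
        hits, false = 0, 0
        for _ in range(20):
            X = 100 + rng.standard_normal((10, 6))
            X[:, 3] += 5.0
            res = rm_anova_dunnett(X, control_index=0)
            flags = [g.significant for g in res.timepoints]  # cols 1..5
            hits += flags[2]
            false += sum(flags) - flags[2]
        assert hits >= 19
        assert false <= 5

    def test_subjects_with_gaps_dropped(self):
        X = 100 + np.random.default_rng(1).standard_normal((6, 4))
        X[2, 1] = np.nan
        res = rm_anova_dunnett(X, control_index=0)
        assert res.n_dropped == 1
        assert res.n_subjects == 5

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            rm_anova_dunnett(np.ones((1, 4)), control_index=0)
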