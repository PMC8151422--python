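"""Validity statistics: scales, exclusions, paired panel, posthoc, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lv1rm import (absolute_pct_error, bonferroni_pairwise, classify_magnitude,
                   exclude_outliers, paired_validity, power_sample_size)
from lv1rm.errors import (ConfigurationError, InputError,
                          InsufficientDataError)


class TestAbsolutePctError:
    @pytest.mark.parametrize("pred, actual, expected", [
        (110.0, 100.0, 10.0),
        (90.0, 100.0, 10.0),   # symmetric in absolute value
        (100.0, 100.0, 0.0),
        (150.0, 100.0, 50.0),
    ])
    def test_arithmetic(self, pred, actual, expected):
        assert absolute_pct_error(pred, actual) == pytest.approx(expected)

    def test_scale_invariance(self):
        a = np.array([80.0, 100.0, 120.0])
        p = np.array([85.0, 95.0, 130.0])
        base = absolute_pct_error(p, a)
        for c in (0.5, 3.7):
            assert absolute_pct_error(c * p, c * a) == pytest.approx(base)

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(InputError):
            absolute_pct_error(100.0, 0.0)


class TestClassifyMagnitude:
    @pytest.mark.parametrize("value, label", [
        (0.0, "low"), (4.9, "low"), (5.0, "moderate"), (10.0, "moderate"),
        (10.01, "high"), (55.0, "high")])
    def test_abs_error_scale(self, value, label):
        assert classify_magnitude(value, "abs_error") == label

    @pytest.mark.parametrize("value, label", [
        (0.0, "trivial"), (0.09, "trivial"), (0.10, "small"),
        (0.30, "moderate"), (0.50, "large"), (0.70, "very large"),
        (0.90, "nearly perfect"), (0.99, "nearly perfect"), (1.0, "perfect"),
        (-0.95, "nearly perfect")])  # classified by |r|
    def test_correlation_scale(self, value, label):
        assert classify_magnitude(value, "correlation") == label

    @pytest.mark.parametrize("value, label", [
        (0.0, "trivial"), (0.19, "trivial"), (0.20, "small"),
        (0.60, "moderate"), (1.20, "large"), (2.00, "large"),
        (2.01, "very large"), (-0.7, "moderate")])
    def test_effect_size_scale(self, value, label):
        assert classify_magnitude(value, "effect_size") == label

    def test_unknown_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_magnitude(0.5, "banana")


def _pred_frame(errors_by_athlete: dict) -> pd.DataFrame:
    rows = []
    for athlete, method_errors in errors_by_athlete.items():
        for method, err in method_errors.items():
            rows.append((athlete, "young", method, err))
    return pd.DataFrame(rows, columns=["athlete_id", "group", "method",
                                       "abs_pct_error"])


class TestExcludeOutliers:
    def test_single_prediction_above_threshold_dropped(self):
        df = _pred_frame({"A": {"low_load": 55.0, "high_load": 12.0}})
        kept, report = exclude_outliers(df, 50.0)
        assert len(kept) == 1
        assert kept["method"].tolist() == ["high_load"]
        assert report.excluded_subjects == []
        assert report.excluded_predictions["stage"].tolist() == ["prediction"]

    def test_systematic_athlete_removed_everywhere(self):
        df = _pred_frame({
            "A": {"multiple_point": 60.0, "distant_two_point": 70.0,
                  "low_load": 90.0, "high_load": 55.0},
            "B": {"multiple_point": 5.0, "distant_two_point": 6.0,
                  "low_load": 60.0, "high_load": 7.0}})
        kept, report = exclude_outliers(df, 50.0)
        assert report.excluded_subjects == ["A"]
        assert "A" not in kept["athlete_id"].tolist()
        # B loses only the low-load prediction
        assert len(kept[kept["athlete_id"] == "B"]) == 3
        stages = report.excluded_predictions.groupby("stage").size()
        assert stages["subject"] == 4 and stages["prediction"] == 1

    def test_no_outliers_is_a_noop(self):
        df = _pred_frame({"A": {"low_load": 12.0, "high_load": 3.0}})
        kept, report = exclude_outliers(df, 50.0)
        pd.testing.assert_frame_equal(kept, df)
        assert report.n_excluded == 0

    def test_every_exclusion_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        df = _pred_frame({f"S{i}": {m: float(rng.uniform(0, 120))
                                    for m in ("a", "b", "c", "d")}
                          for i in range(30)})
        kept, report = exclude_outliers(df, 50.0)
        assert (report.excluded_predictions["abs_pct_error"] > 50.0).all()
        assert len(kept) + report.n_excluded == len(df)


class TestPairedValidity:
    def test_identical_pairs_are_degenerate_perfect_agreement(self):
        a = np.array([80.0, 95.0, 110.0, 120.0])
        v = paired_validity(a, a.copy())
        assert v.raw_diff_mean == 0.0
        assert v.t_p_value == 1.0
        assert v.es == 0.0 and v.es_label == "trivial"
        assert v.mean_abs_pct_error == 0.0 and v.error_label == "low"
        assert v.r_pearson == 1.0 and v.r_pearson_label == "perfect"

    def test_constant_shift_conventions(self):
        a = np.array([80.0, 95.0, 110.0, 120.0])
        v = paired_validity(a, a + 10.0)
        assert v.raw_diff_mean == pytest.approx(10.0)
        assert v.raw_diff_sd == 0.0
        assert v.r_pearson == 1.0
        assert v.r_hetero == 0.0 and not v.heteroscedastic
        assert v.t_p_value == 0.0  # infinite paired t by convention

    def test_matches_textbook_formula_oracle(self):
        """Every statistic agrees with directly coded definitional formulas."""
        rng = np.random.default_rng(77)
        a = rng.uniform(60, 140, 20)
        p = a + rng.normal(3, 8, 20)
        v = paired_validity(a, p)

        d = p - a
        n = 20
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p_t = 2 * stats.t.sf(abs(t), n - 1)
        es = d.mean() / np.sqrt((a.var(ddof=1) + p.var(ddof=1)) / 2)

        def corr(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        assert v.t_p_value == pytest.approx(p_t, abs=1e-10)
        assert v.es == pytest.approx(es, abs=1e-10)
        assert v.r_pearson == pytest.approx(corr(a, p), abs=1e-10)
        assert v.r_hetero == pytest.approx(corr(d, (a + p) / 2), abs=1e-10)
        assert v.raw_diff_mean == pytest.approx(d.mean(), abs=1e-10)
        assert v.raw_diff_sd == pytest.approx(d.std(ddof=1), abs=1e-10)
        assert v.mean_abs_pct_error == pytest.approx(
            np.mean(100 * np.abs(d) / a), abs=1e-10)

    def test_heteroscedastic_flag_threshold(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(60, 140, 50)
        p = a + (a - 100) * 0.4 + rng.normal(0, 2, 50)  # error grows with size
        v = paired_validity(a, p)
        assert v.r_hetero > 0.32 and v.heteroscedastic

    def test_es_sign_matches_mean_difference(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(60, 140, 15)
        under = paired_validity(a, a - rng.uniform(2, 8, 15))
        over = paired_validity(a, a + rng.uniform(2, 8, 15))
        assert under.es < 0 < over.es

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_validity([100.0], [95.0])


class TestBonferroni:
    def test_four_methods_give_six_comparisons(self):
        rng = np.random.default_rng(4)
        rows = [(f"S{i}", m, rng.uniform(0, 20))
                for i in range(10) for m in ("a", "b", "c", "d")]
        df = pd.DataFrame(rows, columns=["athlete_id", "method",
                                         "abs_pct_error"])
        out = bonferroni_pairwise(df)
        assert len(out) == 6
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_adjustment_multiplies_and_caps(self):
        assert min(1.0, 6 * 0.5) == 1.0          # capping mirrors reports
        rng = np.random.default_rng(9)
        rows = [(f"S{i}", m, rng.uniform(0, 20) + (30 if m == "d" else 0))
                for i in range(12) for m in ("a", "b", "c", "d")]
        df = pd.DataFrame(rows, columns=["athlete_id", "method",
                                         "abs_pct_error"])
        out = bonferroni_pairwise(df)
        small = out[out["p_raw"] < 1 / 6]
        assert np.allclose(small["p_bonferroni"], 6 * small["p_raw"])
        big = out[out["p_raw"] >= 1 / 6]
        assert (big["p_bonferroni"] == 1.0).all()


class TestPowerSampleSize:
    def test_study_design_value(self):
        """d=1.1, alpha=0.05, power=0.95, one-tailed needs 19 per group."""
        assert power_sample_size(1.1, 0.05, 0.95, tails=1) == 19

    def test_monotone_in_effect_size(self):
        sizes = [power_sample_size(d, 0.05, 0.95, tails=1)
                 for d in (0.4, 0.8, 1.1, 1.6, 2.2)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_statsmodels_solver(self):
        """Independent noncentral-t power implementation agrees."""
        from statsmodels.stats.power import TTestIndPower
        solver = TTestIndPower()
        for d, tails in ((0.8, 1), (1.1, 1), (0.5, 2)):
            n = power_sample_size(d, 0.05, 0.95, tails=tails)
            alt = "larger" if tails == 1 else "two-sided"
            assert solver.power(d, n, 0.05, alternative=alt) >= 0.95
            assert solver.power(d, n - 1, 0.05, alternative=alt) < 0.95

    def test_integer_scan_oracle(self):
        """Brute-force scan over n using the exact noncentral-t power."""
        from scipy.stats import nct, t

        def power_at(n, d, alpha):
            df = 2 * n - 2
            crit = t.ppf(1 - alpha, df)
            return nct.sf(crit, df, d * np.sqrt(n / 2))

        d = 0.8
        scan = next(n for n in range(2, 500)
                    if power_at(n, d, 0.05) >= 0.95)
        assert power_sample_size(d, 0.05, 0.95, tails=1) == scan

    def test_invalid_arguments(self):
        with pytest.raises(InputError):
            power_sample_size(-1.0)
        with pytest.raises(InputError):
            power_sample_size(1e-6, max_n=100)
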