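"""Odds ratios, group comparisons, logistic screening and ROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from helpers import make_binary_cohort
from lungdens import (CohortSpec, CollinearityError, ContingencyTable,
                      ConvergenceError, DegenerateTestError, PatientRecord,
                      ZeroCellError, build_table1, build_table2,
                      delong_auc_variance, fit_multivariate, fit_univariate,
                      format_percent, generate_cohort, group_compare,
                      odds_ratio_2x2, roc_analysis)


class TestOddsRatio2x2:
    def test_unit_table_is_symmetric_about_one(self):
        res = odds_ratio_2x2(ContingencyTable(1, 1, 1, 1))
        assert res.or_value == 1.0
        assert math.log(res.ci_low) == pytest.approx(-math.log(res.ci_high))

    def test_zero_cell_raises_named_error(self):
        with pytest.raises(ZeroCellError, match="cell b"):
            odds_ratio_2x2(ContingencyTable(5, 0, 3, 4))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(-1, 2, 3, 4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=80)] * 4))
    def test_recoding_invariance(self, cells):
        """Swapping exposure coding together with outcome recoding leaves
        the OR unchanged; swapping only the exposure inverts it and swaps
        the CI bounds."""
        a, b, c, d = cells
        base = odds_ratio_2x2(ContingencyTable(a, b, c, d))
        double_swap = odds_ratio_2x2(ContingencyTable(d, c, b, a))
        assert double_swap.or_value == pytest.approx(base.or_value)
        flipped = odds_ratio_2x2(ContingencyTable(b, a, d, c))
        assert flipped.or_value == pytest.approx(1.0 / base.or_value)
        assert flipped.ci_low == pytest.approx(1.0 / base.ci_high)
        assert flipped.ci_high == pytest.approx(1.0 / base.ci_low)

    def test_confidence_level_widens_interval(self):
        t = ContingencyTable(35, 6, 30, 18)
        narrow = odds_ratio_2x2(t, confidence=0.90)
        wide = odds_ratio_2x2(t, confidence=0.99)
        assert wide.ci_low < narrow.ci_low < narrow.ci_high < wide.ci_high


class TestGroupCompare:
    def test_identical_binary_gives_fisher_p_one(self):
        recs = make_binary_cohort(2, 6, 2, 6)
        res = group_compare(recs, "heavy_smoker")
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_path_matches_hand_computed_statistic(self):
        """(35,6,30,18): all expected cells >= 5, so the chi-square branch
        runs; the statistic equals n(ad-bc)^2 / (margin products)."""
        recs = make_binary_cohort(35, 6, 30, 18)
        res = group_compare(recs, "heavy_smoker")
        assert res.test == "chi2"
        n = 89
        expected = n * (35 * 18 - 6 * 30) ** 2 / (41 * 48 * 65 * 24)
        assert res.statistic == pytest.approx(expected)
        assert round(res.p_value, 3) == 0.015

    def test_sparse_table_takes_fisher(self):
        recs = make_binary_cohort(8, 2, 1, 9)
        assert group_compare(recs, "heavy_smoker").test == "fisher"

    def test_lognormal_marker_takes_mannwhitney(self):
        """Log-normal markers fail Shapiro-Wilk at n = 48, so the
        Mann-Whitney branch runs."""
        recs = generate_cohort(CohortSpec(seed=11))
        res = group_compare(recs, "cea")
        assert res.test == "mannwhitney"

    def test_normal_variable_takes_t_test(self, rng):
        recs = generate_cohort(CohortSpec(seed=11))
        for r in recs:
            r.cea = float(rng.normal(5.0, 1.0))
        assert group_compare(recs, "cea").test == "ttest"

    def test_constant_variable_rejected(self):
        recs = make_binary_cohort(5, 5, 5, 5)
        for r in recs:
            r.bulla = 1
        with pytest.raises(DegenerateTestError):
            group_compare(recs, "bulla")


class TestLogistic:
    @pytest.mark.parametrize("cells", [(35, 6, 30, 18), (11, 30, 3, 45),
                                       (34, 7, 24, 24)])
    def test_univariate_matches_cross_product_or(self, cells):
        recs = make_binary_cohort(*cells)
        fit = fit_univariate(recs, "heavy_smoker")
        table_or = odds_ratio_2x2(ContingencyTable(*cells))
        assert fit.or_values[0] == pytest.approx(table_or.or_value, abs=1e-6)
        # Wald CI on the coefficient exponentiates to the Woolf CI
        assert fit.ci_low[0] == pytest.approx(table_or.ci_low, abs=1e-4)
        assert fit.ci_high[0] == pytest.approx(table_or.ci_high, abs=1e-4)

    def test_null_predictor_or_near_one(self, rng):
        recs = make_binary_cohort(500, 500, 500, 500)
        for r in recs:
            r.heavy_smoker = int(rng.random() < 0.5)
        fit = fit_univariate(recs, "heavy_smoker")
        assert fit.or_values[0] == pytest.approx(1.0, abs=0.25)

    def test_perfect_separation_raises(self):
        recs = make_binary_cohort(10, 0, 0, 10)
        with pytest.raises(ConvergenceError):
            fit_univariate(recs, "heavy_smoker")

    def test_single_selected_variable_reduces_to_univariate(self):
        recs = make_binary_cohort(34, 7, 24, 24)
        multi, selected = fit_multivariate(recs, ["heavy_smoker", "bulla"])
        assert selected == ["heavy_smoker"]
        uni = fit_univariate(recs, "heavy_smoker")
        assert multi.or_values[0] == pytest.approx(uni.or_values[0], rel=1e-9)

    def test_collinear_predictors_raise(self):
        recs = make_binary_cohort(34, 7, 24, 24)
        for r in recs:
            r.dist1_indicator = r.heavy_smoker
        from lungdens.stats import _fit_logit
        from lungdens.synthetic import records_to_dataframe

        df = records_to_dataframe(recs)
        with pytest.raises(CollinearityError):
            _fit_logit(df["outcome"].to_numpy(float),
                       df[["heavy_smoker", "dist1_indicator"]])

    def test_multivariate_recovers_generating_ors(self):
        """Per-group prevalences chosen for marginal ORs (3.8, 5.3, 3.5);
        with predictors conditionally independent given the outcome the
        joint logistic coefficients equal the marginal log-ORs, so the
        fit at n = 2,000 recovers them within 15%."""
        target = {"heavy_smoker": 3.8, "dist1_indicator": 5.3,
                  "dist2_indicator": 3.5}
        p_ctrl = {"heavy_smoker": 0.4, "dist1_indicator": 0.15,
                  "dist2_indicator": 0.35}

        def case_p(v):
            odds = target[v] * p_ctrl[v] / (1 - p_ctrl[v])
            return odds / (1 + odds)

        spec = CohortSpec(
            n_case=1000, n_control=1000, seed=31,
            smoking_effect=target["heavy_smoker"],
            smoking_control_prevalence=p_ctrl["heavy_smoker"],
            interval_shift_probability={
                "case": {"distribution_1": case_p("dist1_indicator"),
                         "distribution_2": case_p("dist2_indicator")},
                "control": {"distribution_1": p_ctrl["dist1_indicator"],
                            "distribution_2": p_ctrl["dist2_indicator"]}})
        recs = generate_cohort(spec)
        fit, selected = fit_multivariate(
            recs, ["heavy_smoker", "dist1_indicator", "dist2_indicator"])
        assert set(selected) == set(target)
        for v, t in target.items():
            assert fit.term_or(v)[0] == pytest.approx(t, rel=0.15)


class TestROC:
    def test_perfect_classifier(self):
        y = np.array([0] * 10 + [1] * 10)
        roc = roc_analysis(y, y.astype(float))
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_null_scores_auc_near_half(self, rng):
        y = rng.integers(0, 2, size=10_000)
        scores = rng.random(10_000)
        roc = roc_analysis(y, scores)
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_brute_force_concordance(self, rng):
        """Trapezoidal/placement AUC vs exhaustive pair enumeration
        (ties count one half) on n <= 200."""
        y = rng.integers(0, 2, size=150)
        y[:5], y[5:10] = 1, 0  # guarantee both classes
        scores = np.round(rng.random(150), 2)  # force some ties
        roc = roc_analysis(y, scores)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc.auc == pytest.approx(wins / (len(pos) * len(neg)),
                                        abs=1e-12)

    def test_delong_interval_contains_auc(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:5], y[5:10] = 1, 0
        scores = rng.random(100) + 0.5 * y
        roc = roc_analysis(y, scores)
        assert roc.ci_low <= roc.auc <= roc.ci_high
        hm = roc_analysis(y, scores, ci_method="hanley-mcneil")
        assert hm.ci_low <= hm.auc <= hm.ci_high

    def test_youden_point_maximizes_j(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:5], y[5:10] = 1, 0
        scores = rng.random(80) + 0.8 * y
        roc = roc_analysis(y, scores)
        j = roc.tpr - roc.fpr
        assert roc.sensitivity - (1 - roc.specificity) == pytest.approx(
            j.max())

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTestError):
            roc_analysis(np.ones(10, int), np.random.rand(10))

    def test_delong_variance_positive(self, rng):
        y = rng.integers(0, 2, size=60)
        y[:3], y[3:6] = 1, 0
        _, var = delong_auc_variance(y, rng.random(60))
        assert var > 0


class TestReports:
    def test_percent_rendering(self):
        assert format_percent(24, 48) == "24(50%)"
        assert format_percent(3, 48) == "3(6.2%)"
        assert format_percent(11, 41) == "11(26.8%)"
        assert format_percent(0, 41) == "0(0%)"

    def test_table1_interval_rows(self, table_cohort):
        t1 = build_table1(table_cohort)
        cells = t1.set_index("variable")
        assert cells.loc["  [-850,-750)", "case"] == "11(26.8%)"
        assert cells.loc["  [-850,-750)", "control"] == "3(6.2%)"
        assert cells.loc["  [-900,-850)", "case"] == "34(82.9%)"
        assert cells.loc["  [-900,-850)", "control"] == "24(50%)"

    def test_table2_univariate_rows_match_printed_tables(self, table_cohort):
        t2, _, _ = build_table2(table_cohort)
        t2 = t2.set_index("variable")
        assert t2.loc["heavy_smoker", "or_univariate"] == 3.5
        assert t2.loc["dist1_indicator", "or_univariate"] == 5.5
        assert t2.loc["dist1_indicator", "ci_univariate"] == \
            "(1.415 ~ 21.378)"
        assert t2.loc["dist2_indicator", "or_univariate"] == 4.857
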