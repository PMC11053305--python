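"""Screening metrics: confusion, exact CIs, AUC, windows, PPV/NPV."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragscreen import screening_evaluation as se


class TestConfusionMetrics:
    def test_discovery_specificity(self):
        # 40 controls, 2 predicted positive -> specificity 0.95
        truth = [0] * 40
        pred = [1] * 2 + [0] * 38
        cm = se.confusion_metrics(truth, pred)
        assert cm.specificity == pytest.approx(0.95)

    def test_evaluation_specificity(self):
        # 50 controls, 6 predicted positive -> specificity 0.88
        cm = se.confusion_metrics([0] * 50, [1] * 6 + [0] * 44)
        assert cm.specificity == pytest.approx(0.88)

    def test_perfect_prediction(self):
        truth = [1] * 5 + [0] * 5
        cm = se.confusion_metrics(truth, truth)
        assert cm.sensitivity == 1.0
        assert cm.specificity == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            se.confusion_metrics([0, 1], [0])

    def test_invariant_under_sample_reordering(self, rng):
        truth = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        perm = rng.permutation(100)
        a = se.confusion_metrics(truth, pred)
        b = se.confusion_metrics(truth[perm], pred[perm])
        assert (a.sensitivity, a.specificity) == (b.sensitivity, b.specificity)


def _ci_grid_scan(x, n, alpha=0.05, step=1e-6):
    """Brute-force Clopper-Pearson endpoints by scanning p over a fine grid."""
    grid = np.arange(step, 1.0, step)
    upper_tail = stats.binom.sf(x - 1, n, grid)  # P(X >= x | p)
    lower_tail = stats.binom.cdf(x, n, grid)     # P(X <= x | p)
    lower = 0.0 if x == 0 else grid[np.searchsorted(upper_tail >= alpha / 2, True)]
    upper = 1.0 if x == n else grid[len(lower_tail) - np.searchsorted(
        (lower_tail >= alpha / 2)[::-1], True) - 1]
    return float(lower), float(upper)


class TestExactBinomialCI:
    def test_matches_printed_interval_44_of_50(self):
        lo, hi = se.exact_binomial_ci(44, 50)
        assert round(100 * lo, 1) == 75.7
        assert round(100 * hi, 1) == 95.5

    def test_zero_successes_lower_is_zero(self):
        lo, hi = se.exact_binomial_ci(0, 10)
        assert lo == 0.0
        assert hi < 1.0

    def test_all_successes_upper_is_one(self):
        lo, hi = se.exact_binomial_ci(10, 10)
        assert hi == 1.0

    def test_matches_grid_scan_oracle(self):
        lo, hi = se.exact_binomial_ci(7, 23)
        glo, ghi = _ci_grid_scan(7, 23)
        assert abs(lo - glo) < 1e-5
        assert abs(hi - ghi) < 1e-5

    @pytest.mark.parametrize("x,n", [(1, 10), (7, 23), (44, 50), (3, 3), (0, 7), (12, 30)])
    def test_tail_equalities_hold(self, x, n):
        """Endpoints satisfy P(X>=x|lower)=alpha/2 and P(X<=x|upper)=alpha/2."""
        lo, hi = se.exact_binomial_ci(x, n)
        if x > 0:
            assert stats.binom.sf(x - 1, n, lo) == pytest.approx(0.025, abs=1e-8)
        if x < n:
            assert stats.binom.cdf(x, n, hi) == pytest.approx(0.025, abs=1e-8)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            se.exact_binomial_ci(5, 4)

    def test_wilson_differs_from_exact_for_44_of_50(self):
        # the printed interval matches the exact method, not Wilson
        wlo, whi = se.wilson_ci(44, 50)
        assert round(100 * wlo, 1) != 75.7 or round(100 * whi, 1) != 95.5


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truth = [1, 1, 0, 0]
        auc, _ = se.roc_auc(scores, truth)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = se.roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_concordance(self, rng):
        n = 30
        scores = rng.choice(np.linspace(0, 1, 11), n)  # force ties
        truth = rng.integers(0, 2, n)
        truth[0], truth[1] = 1, 0  # both classes present
        auc, _ = se.roc_auc(scores, truth)
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        ) / (len(pos) * len(neg))
        assert abs(auc - conc) < 1e-12

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            se.roc_auc([0.1, 0.9], [1, 1])

    def test_ci_brackets_point_estimate(self, rng):
        scores = rng.random(80)
        truth = (scores + rng.normal(0, 0.3, 80)) > 0.5
        auc, (lo, hi) = se.roc_auc(scores, truth)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestTimeWindows:
    def test_default_labels_unique_and_ordered(self):
        labels = [w.label for w in se.DEFAULT_WINDOWS]
        assert labels == ["0-1y", "1-2y", "2-3y", "3-4y", ">4y"]

    @pytest.mark.parametrize(
        "years,expected",
        [(0.5, "0-1y"), (1.0, "0-1y"), (1.5, "1-2y"), (4.0, "3-4y"), (6.0, ">4y"),
         (0.0, "0-1y")],
    )
    def test_boundary_belongs_to_narrower_window(self, years, expected):
        assert se.assign_window(years) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            se.TimeWindow("bad", 2.0, 1.0)


class TestWindowSensitivity:
    def test_all_above_cutoff(self):
        df = pd.DataFrame(
            {"subject_id": ["a", "b"], "window": ["0-1y"] * 2, "score": [0.9, 0.8]}
        )
        (res,) = se.window_sensitivity(df, cutoff=0.5, windows=se.DEFAULT_WINDOWS[:1])
        assert res.sensitivity == 1.0
        assert res.n == 2

    def test_subject_counted_once_per_window(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "window": ["0-1y", "1-2y"],
                "score": [0.9, 0.1],
            }
        )
        res = se.window_sensitivity(df, cutoff=0.5, windows=se.DEFAULT_WINDOWS[:2])
        assert [r.n for r in res] == [1, 1]
        assert [r.detected for r in res] == [1, 0]

    def test_empty_window_reports_nan(self):
        df = pd.DataFrame({"subject_id": [], "window": [], "score": []})
        res = se.window_sensitivity(df, cutoff=0.5, windows=se.DEFAULT_WINDOWS[:1])
        assert math.isnan(res[0].sensitivity)


class TestIncidenceRate:
    def test_screening_cohort_example(self):
        # 81 events over 21,189 person-years -> 382 per 100,000 (rounded)
        assert round(se.incidence_rate(81, 21_189)) == 382

    def test_zero_events(self):
        assert se.incidence_rate(0, 1000) == 0.0

    def test_plain_arithmetic(self):
        assert se.incidence_rate(5, 2500) == pytest.approx(200.0)

    def test_nonpositive_person_years_rejected(self):
        with pytest.raises(ValueError):
            se.incidence_rate(1, 0)


class TestPpvNpv:
    def test_screening_worked_example(self):
        # sens 36.4%, spec 88%, prevalence 0.382% -> PPV 1.15%, NPV 99.72%
        ppv, npv = se.ppv_npv(0.364, 0.88, 0.00382)
        assert round(100 * ppv, 2) == 1.15
        assert round(100 * npv, 2) == 99.72

    def test_perfect_test(self):
        ppv, npv = se.ppv_npv(1.0, 1.0, 0.01)
        assert ppv == 1.0 and npv == 1.0

    def test_matches_population_simulation(self, rng):
        sens, spec, prev = 0.364, 0.88, 0.00382
        n = 10_000_000
        n_diseased = rng.binomial(n, prev)
        tp = rng.binomial(n_diseased, sens)
        fn = n_diseased - tp
        tn = rng.binomial(n - n_diseased, spec)
        fp = (n - n_diseased) - tn
        ppv_sim, npv_sim = tp / (tp + fp), tn / (tn + fn)
        ppv, npv = se.ppv_npv(sens, spec, prev)
        se_ppv = math.sqrt(ppv_sim * (1 - ppv_sim) / (tp + fp))
        se_npv = math.sqrt(npv_sim * (1 - npv_sim) / (tn + fn))
        assert abs(ppv - ppv_sim) < 3 * se_ppv
        assert abs(npv - npv_sim) < 3 * se_npv

    def test_bayes_identity_on_expected_table(self, rng):
        """PPV/NPV equal Bayes' rule on the infinite-population 2x2 table."""
        for _ in range(20):
            sens, spec, p = rng.random(3)
            tp, fn = sens * p, (1 - sens) * p
            tn, fp = spec * (1 - p), (1 - spec) * (1 - p)
            ppv, npv = se.ppv_npv(sens, spec, p)
            if tp + fp > 0:
                assert ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
            if tn + fn > 0:
                assert npv == pytest.approx(tn / (tn + fn), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            se.ppv_npv(1.5, 0.9, 0.1)

    def test_degenerate_denominator_returns_nan(self):
        ppv, _ = se.ppv_npv(0.0, 1.0, 0.0)
        assert math.isnan(ppv)


class TestPpvNpvByWindow:
    def test_ppv_monotone_in_sensitivity(self):
        res = [
            se.WindowResult("a", 10, 2, 0.2, (0.1, 0.4)),
            se.WindowResult("b", 10, 4, 0.364, (0.2, 0.6)),
        ]
        out = se.ppv_npv_by_window(res, specificity=0.88, prevalence=0.00382)
        assert out[0].ppv < out[1].ppv

    def test_missing_sensitivity_propagates(self):
        res = [se.WindowResult("a", 0, 0, math.nan, (math.nan, math.nan))]
        out = se.ppv_npv_by_window(res, 0.88, 0.00382)
        assert math.isnan(out[0].ppv)

    def test_full_report_matches_per_window_brute_force(self, rng):
        spec, prev = 0.9, 0.004
        results = [
            se.WindowResult(f"w{i}", 20, k, k / 20, se.exact_binomial_ci(k, 20))
            for i, k in enumerate([2, 5, 9, 13])
        ]
        out = se.ppv_npv_by_window(results, spec, prev)
        for w in out:
            num = w.sensitivity * prev
            den = num + (1 - spec) * (1 - prev)
            assert w.ppv == pytest.approx(num / den, abs=1e-12)


class TestEvaluateScreening:
    def test_counts_reconstruct_proportions(self, rng):
        cases = pd.DataFrame(
            {
                "subject_id": [f"c{i}" for i in range(30)],
                "window": rng.choice([w.label for w in se.DEFAULT_WINDOWS], 30),
                "score": rng.random(30),
            }
        )
        controls = rng.random(40)
        rep = se.evaluate_screening(cases, controls, cutoff=0.5, incidence_per_100k=382.0)
        assert rep.specificity == rep.n_controls_negative / rep.n_controls
        for w in rep.windows:
            if w.n:
                assert w.sensitivity == pytest.approx(w.detected / w.n)
                assert w.ci[0] <= w.sensitivity <= w.ci[1]

    def test_json_report_roundtrip(self, tmp_path, rng):
        cases = pd.DataFrame(
            {"subject_id": ["a"], "window": ["0-1y"], "score": [0.9]}
        )
        rep = se.evaluate_screening(cases, rng.random(10), cutoff=0.5)
        out = tmp_path / "report.json"
        rep.to_json(out)
        assert out.exists() and out.read_text().startswith("{")
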