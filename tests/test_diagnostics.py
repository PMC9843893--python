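"""Diagnostic-accuracy statistics tests, including printed-table checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pancrad import diagnostics as dx
from pancrad.errors import ConfigurationError
from pancrad.tables import LOCAL_CROSSTAB, NATIONWIDE_CROSSTAB

import oracles


class TestProportionCI:
    @pytest.mark.parametrize("k,n,point,lo,hi", [
        (65, 92, 0.707, 0.602, 0.797),
        (196, 199, 0.985, 0.957, 0.997),
        (355, 380, 0.934, 0.904, 0.957),
        (48, 92, 0.522, 0.415, 0.627),
    ])
    def test_published_sensitivities(self, k, n, point, lo, hi):
        est = dx.proportion_ci(k, n)
        assert est.round() == (point, lo, hi)

    def test_zero_successes_lower_bound_zero(self):
        est = dx.proportion_ci(0, 25)
        assert est.lower == 0.0 and est.point == 0.0

    def test_all_successes_upper_bound_one(self):
        est = dx.proportion_ci(30, 30)
        assert est.upper == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            dx.proportion_ci(1, 0)
        with pytest.raises(ConfigurationError):
            dx.proportion_ci(5, 4)

    @pytest.mark.parametrize("n", [20, 92, 671])
    def test_coverage_at_least_nominal(self, n):
        """Clopper–Pearson coverage >= 95% over 2000 simulated cohorts."""
        rng = np.random.default_rng(2024)
        p_true = 0.75
        ks = rng.binomial(n, p_true, size=2000)
        covered = 0
        for k in np.unique(ks):
            est = dx.proportion_ci(int(k), n)
            covered += ((ks == k).sum()
                        if est.lower <= p_true <= est.upper else 0)
        assert covered / 2000 >= 0.95


class TestAccuracyMetrics:
    def test_nationwide_series_row(self):
        m = dx.accuracy_metrics(NATIONWIDE_CROSSTAB.series_counts())
        assert m["sensitivity"].round() == (0.742, 0.707, 0.775)
        assert m["specificity"].round() == (0.952, 0.934, 0.965)
        assert m["accuracy"].round() == (0.856, 0.837, 0.874)

    def test_perfect_classifier(self):
        m = dx.accuracy_metrics(dx.ConfusionCounts(tp=40, fp=0, tn=60, fn=0))
        assert m["sensitivity"].point == 1.0
        assert m["specificity"].point == 1.0
        assert m["accuracy"].point == 1.0

    def test_matches_recount_from_raw_calls(self, rng):
        truth = rng.integers(0, 2, 200).astype(bool)
        calls = truth ^ (rng.random(200) < 0.2)
        counts = dx.ConfusionCounts.from_calls(calls, truth)
        m = dx.accuracy_metrics(counts)
        assert m["sensitivity"].point == pytest.approx(
            calls[truth].mean())
        assert m["specificity"].point == pytest.approx(
            (~calls[~truth]).mean())
        assert m["accuracy"].point == pytest.approx((calls == truth).mean())

    def test_accuracy_prevalence_identity(self, rng):
        c = dx.ConfusionCounts(tp=34, fp=11, tn=87, fn=12)
        m = dx.accuracy_metrics(c)
        prev = c.n_cases / c.total
        assert m["accuracy"].point == pytest.approx(
            m["sensitivity"].point * prev + m["specificity"].point * (1 - prev))


class TestLikelihoodRatios:
    def test_nationwide_series_lr(self):
        lr_pos, lr_neg = dx.likelihood_ratios(NATIONWIDE_CROSSTAB.series_counts())
        assert lr_pos.point == pytest.approx(15.32, abs=0.01)
        assert lr_pos.lower == pytest.approx(11.24, abs=0.02)
        assert lr_pos.upper == pytest.approx(20.87, abs=0.02)

    def test_local_series_lr(self):
        lr_pos, _ = dx.likelihood_ratios(LOCAL_CROSSTAB.series_counts())
        assert lr_pos.point == pytest.approx(35.96, abs=0.01)
        assert lr_pos.lower == pytest.approx(11.67, abs=0.02)
        assert lr_pos.upper == pytest.approx(110.85, abs=0.02)

    def test_uninformative_test_lr_one(self):
        counts = dx.ConfusionCounts(tp=30, fn=70, fp=30, tn=70)  # sens = 1-spec
        lr_pos, _ = dx.likelihood_ratios(counts)
        assert lr_pos.point == pytest.approx(1.0)

    def test_zero_false_positives_gives_infinite_sentinel(self):
        lr_pos, _ = dx.likelihood_ratios(dx.ConfusionCounts(tp=10, fn=2,
                                                            fp=0, tn=50))
        assert np.isinf(lr_pos.point)

    def test_stratum_lrs_reproduce_published_cells(self):
        got = dx.stratum_likelihood_ratios(NATIONWIDE_CROSSTAB)
        expected = {"3d+2d+": (15.32, 11.24, 20.87),
                    "3d+2d-": (1.73, 1.05, 2.85),
                    "3d-2d+": (0.92, 0.70, 1.21),
                    "3d-2d-": (0.11, 0.08, 0.14)}
        for cell, (point, lo, hi) in expected.items():
            assert got[cell].point == pytest.approx(point, abs=0.01)
            assert got[cell].lower == pytest.approx(lo, abs=0.02)
            assert got[cell].upper == pytest.approx(hi, abs=0.02)
        local = dx.stratum_likelihood_ratios(LOCAL_CROSSTAB)
        assert local["3d+2d+"].point == pytest.approx(35.96, abs=0.01)
        assert local["3d-2d-"].point == pytest.approx(0.14, abs=0.01)

    def test_uniform_crosstab_all_cells_one(self):
        tab = dx.CrossTab(pc=(25, 25, 25, 25), control=(40, 40, 40, 40))
        for est in dx.stratum_likelihood_ratios(tab).values():
            assert est.point == pytest.approx(1.0)


class TestAUC:
    def test_perfect_separation(self):
        est = dx.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert est.point == 1.0

    def test_equals_pairwise_oracle_with_ties(self, rng):
        for _ in range(5):
            scores = rng.integers(0, 6, size=40).astype(float)  # many ties
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            assert dx.auc_point(scores, labels) == pytest.approx(
                oracles.naive_auc(scores, labels), abs=1e-12)

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=400)
        labels = np.array([1] * 200 + [0] * 200)
        assert 0.42 <= dx.auc_point(scores, labels) <= 0.58

    def test_ci_brackets_point(self, rng):
        est = dx.roc_auc(rng.normal(size=100), rng.integers(0, 2, 100))
        assert est.lower <= est.point <= est.upper


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        delta, p = dx.delong_paired_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(3)
        n = 300
        y = np.array([1] * n + [0] * n)
        informative = y + rng.normal(0, 0.7, size=2 * n)
        noise = rng.normal(size=2 * n)
        _, p = dx.delong_paired_test(informative, noise, y)
        assert p < 0.01

    def test_agrees_with_stratified_bootstrap(self):
        """Two correlated scores, n=100: DeLong p within 0.02 of a 2000-rep
        paired stratified bootstrap of the AUC difference."""
        rng = np.random.default_rng(17)
        n = 50
        y = np.array([1] * n + [0] * n)
        base = y * 0.8 + rng.normal(0, 1.0, 2 * n)
        a = base + rng.normal(0, 0.4, 2 * n)
        b = base + rng.normal(0, 0.6, 2 * n)
        delta, p = dx.delong_paired_test(a, b, y)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        deltas = []
        for _ in range(2000):
            ip = rng.choice(pos, size=n)
            ineg = rng.choice(neg, size=n)
            idx = np.concatenate([ip, ineg])
            yb = y[idx]
            deltas.append(dx.auc_point(a[idx], yb) - dx.auc_point(b[idx], yb))
        se = np.std(deltas, ddof=1)
        z = delta / se
        p_boot = 2 * stats.norm.sf(abs(z))
        assert p == pytest.approx(p_boot, abs=0.02)


class TestTrend:
    def test_published_strata_trend_significant(self):
        p = dx.cochran_armitage_trend([48, 301, 185], [92, 380, 199])
        assert p < 0.001

    def test_matches_prop_trend_chi_square_formula(self):
        r = np.array([10.0, 18, 29])
        n = np.array([40.0, 40, 40])
        x = np.array([0.0, 1, 2])
        p_ours = dx.cochran_armitage_trend(r, n, x)
        # R prop.trend.test: chi2 = (sum(w(p-pbar)x))^2 / (pbar qbar [sum w x2 - (sum w x)^2/sum w])
        pbar = r.sum() / n.sum()
        num = (r * x).sum() - pbar * (n * x).sum()
        den = pbar * (1 - pbar) * ((n * x * x).sum() - (n * x).sum() ** 2 / n.sum())
        chi2 = num ** 2 / den
        assert p_ours == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)

    def test_null_trend_p_roughly_uniform(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(1000):
            r = rng.binomial([60, 60, 60], 0.6)
            ps.append(dx.cochran_armitage_trend(r, [60, 60, 60]))
        ps = np.asarray(ps)
        # calibrated: about 5% below 0.05, mean near 0.5
        assert 0.02 < (ps < 0.05).mean() < 0.09
        assert 0.45 < ps.mean() < 0.55

    def test_all_detected_sensitivities_one(self):
        per, _ = dx.size_stratified_sensitivity(
            {"<2cm": 10, "2-4cm": 20, ">4cm": 15},
            {"<2cm": 10, "2-4cm": 20, ">4cm": 15})
        assert all(est.point == 1.0 for est in per.values())

    def test_stratum_assignment_cuts(self):
        assert dx.assign_size_stratum(12) == "<2cm"
        assert dx.assign_size_stratum(20) == "2-4cm"
        assert dx.assign_size_stratum(40) == "2-4cm"
        assert dx.assign_size_stratum(41) == ">4cm"


class TestMcNemar:
    def test_symmetric_disagreement_p_one(self):
        a = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        b = np.array([1, 0, 1, 0, 0, 1], dtype=bool)
        assert dx.mcnemar_exact(a, b) == pytest.approx(1.0)

    def test_one_sided_disagreement_small_p(self):
        a = np.ones(20, dtype=bool)
        b = np.zeros(20, dtype=bool)
        assert dx.mcnemar_exact(a, b) < 0.001


class TestFeatureScreen:
    def test_null_features_calibrated(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(80, 1000)))
        groups = np.array([1] * 40 + [0] * 40)
        _, n_below = dx.feature_screen(table, groups)
        assert n_below <= 6  # ~0.1% expected under the null

    def test_disjoint_supports_tiny_p(self):
        x = np.concatenate([np.zeros(50), np.ones(50) + 5])
        table = pd.DataFrame({"f": x})
        pvals, n = dx.feature_screen(table, np.array([0] * 50 + [1] * 50))
        assert pvals["f"] < 1e-10 and n == 1

    def test_u_statistic_matches_pairwise_oracle(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(0.5, 1, size=12)
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert u == pytest.approx(oracles.naive_mannwhitney_u(x, y))

    def test_binary_feature_uses_fisher(self):
        g = np.array([1] * 30 + [0] * 30)
        f = (g == 1).astype(float)  # perfectly associated binary feature
        pvals, _ = dx.feature_screen(pd.DataFrame({"f": f}), g)
        assert pvals["f"] == pytest.approx(
            stats.fisher_exact([[30, 0], [0, 30]])[1])
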