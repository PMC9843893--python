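"""Fusion model, Youden cutoffs and decision-rule tests."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from pancrad.errors import ConfigurationError, IncompleteStudyError, TrainingError
from pancrad.fusion import (CutoffSet, NEGATIVE, POSITIVE, REFERENCE_FUSION,
                            combined_probability, decide, fit_fusion,
                            fit_fusion_ci, youden_cutoff)


def simulate_from_reference(rng, n=5000):
    p3d = rng.uniform(0, 1, size=n)
    area = rng.uniform(0, 2000, size=n)  # mm^2, spans the logit range
    p = expit(REFERENCE_FUSION.logit(p3d, area))
    y = (rng.uniform(size=n) < p).astype(int)
    return p3d, area, y


class TestCombinedProbability:
    def test_reference_spot_values(self):
        p0 = combined_probability(REFERENCE_FUSION, 0.0, 0.0)
        assert p0 == pytest.approx(1 / (1 + np.exp(2.79234888)), abs=1e-9)
        p1 = combined_probability(REFERENCE_FUSION, 1.0, 0.0)
        assert REFERENCE_FUSION.logit(1.0, 0.0) == pytest.approx(1.16524828, abs=1e-8)
        assert p1 == pytest.approx(1 / (1 + np.exp(-1.16524828)), abs=1e-9)

    def test_strictly_increasing_in_each_argument(self):
        base = combined_probability(REFERENCE_FUSION, 0.5, 500.0)
        assert combined_probability(REFERENCE_FUSION, 0.6, 500.0) > base
        assert combined_probability(REFERENCE_FUSION, 0.5, 600.0) > base

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            combined_probability(REFERENCE_FUSION, 1.2, 0.0)
        with pytest.raises(ConfigurationError):
            combined_probability(REFERENCE_FUSION, 0.5, -1.0)

    def test_monotone_study_ordering_under_area_scaling(self, rng):
        p3d = rng.uniform(0, 1, 20)
        area = rng.uniform(0, 800, 20)
        for scale in (0.5, 1.0, 2.0):
            p = combined_probability(REFERENCE_FUSION, p3d, area * scale)
            order = np.argsort(REFERENCE_FUSION.logit(p3d, area * scale))
            assert np.array_equal(np.argsort(p), order)


class TestFitFusion:
    def test_parameter_recovery_within_15_percent(self):
        rng = np.random.default_rng(42)
        p3d, area, y = simulate_from_reference(rng, n=5000)
        fit = fit_fusion(p3d, area, y)
        assert not fit.penalized
        assert fit.coef_p3d == pytest.approx(REFERENCE_FUSION.coef_p3d, rel=0.15)
        assert fit.coef_area == pytest.approx(REFERENCE_FUSION.coef_area, rel=0.15)

    def test_null_labels_cis_cover_zero(self):
        rng = np.random.default_rng(9)
        p3d = rng.uniform(0, 1, 800)
        area = rng.uniform(0, 1000, 800)
        y = rng.integers(0, 2, 800)
        _, ci = fit_fusion_ci(p3d, area, y)
        assert ci[1, 0] < 0 < ci[1, 1]  # b1
        assert ci[2, 0] < 0 < ci[2, 1]  # b2

    def test_duplicated_dataset_identical_fit(self, rng):
        p3d, area, y = simulate_from_reference(rng, n=400)
        a = fit_fusion(p3d, area, y)
        b = fit_fusion(np.tile(p3d, 2), np.tile(area, 2), np.tile(y, 2))
        assert a.coef_p3d == pytest.approx(b.coef_p3d, rel=1e-5)
        assert a.coef_area == pytest.approx(b.coef_area, rel=1e-5)

    def test_perfect_separation_falls_back_to_penalized(self):
        p3d = np.array([0.1, 0.2, 0.8, 0.9])
        area = np.array([0.0, 0.0, 500.0, 600.0])
        y = np.array([0, 0, 1, 1])
        fit = fit_fusion(p3d, area, y)
        assert fit.penalized

    def test_single_class_raises(self):
        with pytest.raises(TrainingError):
            fit_fusion([0.1, 0.2], [1.0, 2.0], [1, 1])


class TestYoudenCutoff:
    def test_perfect_separation_cutoff_between_classes(self):
        c = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < c < 0.8

    def test_matches_brute_force_over_midpoints(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        c = youden_cutoff(scores, labels)
        distinct = np.unique(scores)
        candidates = np.concatenate([[-np.inf],
                                     (distinct[:-1] + distinct[1:]) / 2,
                                     [np.inf]])
        best_j, best_c = -np.inf, None
        for cand in candidates:
            call = scores > cand
            j = (call[labels == 1].mean() + (~call[labels == 0]).mean()) - 1
            if j > best_j:
                best_j, best_c = j, cand
        assert c == best_c

    def test_identical_scores_give_j_zero(self):
        c = youden_cutoff([0.5] * 6, [0, 0, 0, 1, 1, 1])
        calls = np.array([0.5] * 6) > c
        j = calls[3:].mean() + (~calls[:3]).mean() - 1
        assert j == pytest.approx(0.0)


class TestDecide:
    CUTS = CutoffSet(p3d=0.5, area2d=100.0, p_combined=0.5)

    def test_rule_table_exhaustive(self):
        """All four (3D call, 2D call) combinations match the truth table."""
        for p3d, area in itertools.product((0.2, 0.8), (50.0, 150.0)):
            pred = decide("s", p3d, area, 0.7, self.CUTS)
            c3 = p3d > 0.5
            c2 = area > 100.0
            assert (pred.call_series == POSITIVE) == (c3 and c2)
            assert (pred.call_parallel == POSITIVE) == (c3 or c2)

    def test_score_equal_to_cutoff_is_negative(self):
        pred = decide("s", 0.5, 100.0, 0.5, self.CUTS)
        assert pred.call3d == NEGATIVE
        assert pred.call2d == NEGATIVE
        assert pred.call_combined == NEGATIVE

    def test_missing_score_raises(self):
        with pytest.raises(IncompleteStudyError):
            decide("s", 0.5, np.nan, 0.5, self.CUTS)

    def test_series_subset_of_parallel_on_cohort(self, rng):
        preds = [decide(str(i), rng.uniform(), rng.uniform(0, 200),
                        rng.uniform(), self.CUTS) for i in range(100)]
        for p in preds:
            if p.call_series == POSITIVE:
                assert p.call_parallel == POSITIVE

    def test_series_parallel_sensitivity_specificity_ordering(self, rng):
        """sens(series) <= min branch sens; spec(series) >= max branch spec."""
        n = 300
        truth = rng.integers(0, 2, n).astype(bool)
        p3d = np.clip(truth * 0.4 + rng.uniform(0, 0.6, n), 0, 1)
        area = truth * 80 + rng.uniform(0, 150, n)
        preds = [decide(str(i), p3d[i], area[i], 0.5, self.CUTS)
                 for i in range(n)]
        c3 = np.array([p.call3d == POSITIVE for p in preds])
        c2 = np.array([p.call2d == POSITIVE for p in preds])
        cs = np.array([p.call_series == POSITIVE for p in preds])
        cp = np.array([p.call_parallel == POSITIVE for p in preds])
        sens = lambda c: c[truth].mean()
        spec = lambda c: (~c[~truth]).mean()
        assert sens(cs) <= min(sens(c3), sens(c2)) + 1e-12
        assert spec(cs) >= max(spec(c3), spec(c2)) - 1e-12
        assert sens(cp) >= max(sens(c3), sens(c2)) - 1e-12
        assert spec(cp) <= min(spec(c3), spec(c2)) + 1e-12
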