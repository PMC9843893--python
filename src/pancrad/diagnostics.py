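"""Cohort-level diagnostic accuracy statistics.

Implements the accuracy layer of the CAD tool: sensitivity / specificity /
accuracy with exact (Clopper–Pearson) binomial confidence intervals,
positive and negative likelihood ratios with log-method CIs, cross-tab
stratum likelihood ratios, ROC AUC with DeLong variance and the paired
DeLong AUC comparison, tumor-size-stratified sensitivity with a
Cochran–Armitage trend test, paired McNemar comparisons of sensitivities,
and a univariate feature screen (Mann–Whitney U for continuous features,
Fisher's exact test for binary ones).

All intervals are two-sided 95% and no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, TrainingError

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with two-sided 95% bounds and the method used."""

    point: float
    lower: float
    upper: float
    method: str

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper or
                np.isnan(self.point)):
            raise ConfigurationError(
                f"interval ({self.lower}, {self.upper}) does not bracket "
                f"point {self.point}")

    def round(self, ndigits: int = 3) -> tuple[float, float, float]:
        return (round(self.point, ndigits), round(self.lower, ndigits),
                round(self.upper, ndigits))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for one decision rule."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    @classmethod
    def from_calls(cls, calls, truth) -> "ConfusionCounts":
        calls = np.asarray(calls, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(tp=int((calls & truth).sum()),
                   fp=int((calls & ~truth).sum()),
                   tn=int((~calls & ~truth).sum()),
                   fn=int((~calls & truth).sum()))


@dataclass(frozen=True)
class CrossTab:
    """PC/control counts in the four (3D call, 2D call) cells.

    Cell order: (3D+,2D+), (3D+,2D-), (3D-,2D+), (3D-,2D-).
    """

    pc: tuple[int, int, int, int]
    control: tuple[int, int, int, int]

    @property
    def n_pc(self) -> int:
        return sum(self.pc)

    @property
    def n_control(self) -> int:
        return sum(self.control)

    def series_counts(self) -> ConfusionCounts:
        """Positive iff both 3D and 2D positive (first cell)."""
        return ConfusionCounts(tp=self.pc[0], fp=self.control[0],
                               tn=self.n_control - self.control[0],
                               fn=self.n_pc - self.pc[0])

    def parallel_counts(self) -> ConfusionCounts:
        """Positive iff either 3D or 2D positive (first three cells)."""
        pos_pc = sum(self.pc[:3])
        pos_ctrl = sum(self.control[:3])
        return ConfusionCounts(tp=pos_pc, fp=pos_ctrl,
                               tn=self.n_control - pos_ctrl,
                               fn=self.n_pc - pos_pc)

    def counts_3d(self) -> ConfusionCounts:
        pos_pc = self.pc[0] + self.pc[1]
        pos_ctrl = self.control[0] + self.control[1]
        return ConfusionCounts(tp=pos_pc, fp=pos_ctrl,
                               tn=self.n_control - pos_ctrl,
                               fn=self.n_pc - pos_pc)

    def counts_2d(self) -> ConfusionCounts:
        pos_pc = self.pc[0] + self.pc[2]
        pos_ctrl = self.control[0] + self.control[2]
        return ConfusionCounts(tp=pos_pc, fp=pos_ctrl,
                               tn=self.n_control - pos_ctrl,
                               fn=self.n_pc - pos_pc)

    @classmethod
    def from_calls(cls, call3d, call2d, truth) -> "CrossTab":
        call3d = np.asarray(call3d, dtype=bool)
        call2d = np.asarray(call2d, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        cells = [(True, True), (True, False), (False, True), (False, False)]
        pc = tuple(int(((call3d == a) & (call2d == b) & truth).sum())
                   for a, b in cells)
        ctrl = tuple(int(((call3d == a) & (call2d == b) & ~truth).sum())
                     for a, b in cells)
        return cls(pc=pc, control=ctrl)


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def proportion_ci(successes: int, n: int) -> IntervalEstimate:
    """Clopper–Pearson exact two-sided 95% interval for a proportion."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ConfigurationError("successes must lie in [0, n]")
    lower, upper = proportion_confint(successes, n, alpha=0.05, method="beta")
    return IntervalEstimate(point=successes / n, lower=float(lower),
                            upper=float(upper), method="exact-binomial")


def accuracy_metrics(counts: ConfusionCounts) -> dict[str, IntervalEstimate]:
    """Sensitivity, specificity and accuracy with exact binomial CIs."""
    out: dict[str, IntervalEstimate] = {}
    if counts.n_cases > 0:
        out["sensitivity"] = proportion_ci(counts.tp, counts.n_cases)
    if counts.n_controls > 0:
        out["specificity"] = proportion_ci(counts.tn, counts.n_controls)
    if counts.total > 0:
        out["accuracy"] = proportion_ci(counts.tp + counts.tn, counts.total)
    return out


# ---------------------------------------------------------------------------
# Likelihood ratios (log-method CIs, Simel et al.)
# ---------------------------------------------------------------------------

def _ratio_ci(a: int, n1: int, b: int, n0: int, method: str) -> IntervalEstimate:
    """CI for (a/n1)/(b/n0) via ln LR +/- z*sqrt(1/a - 1/n1 + 1/b - 1/n0)."""
    if a == 0 or b == 0:
        point = np.inf if b == 0 and a > 0 else 0.0
        return IntervalEstimate(point=point, lower=0.0, upper=np.inf,
                                method=method)
    lr = (a / n1) / (b / n0)
    se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / b - 1.0 / n0)
    return IntervalEstimate(point=float(lr),
                            lower=float(np.exp(np.log(lr) - Z95 * se)),
                            upper=float(np.exp(np.log(lr) + Z95 * se)),
                            method=method)


def likelihood_ratios(counts: ConfusionCounts) -> tuple[IntervalEstimate, IntervalEstimate]:
    """(LR+, LR-) with log-method CIs.

    LR+ = sens/(1-spec) = (TP/n1)/(FP/n0); LR- = (1-sens)/spec =
    (FN/n1)/(TN/n0).  A zero denominator yields an infinite-LR sentinel
    with a one-sided bound.
    """
    n1, n0 = counts.n_cases, counts.n_controls
    if n1 == 0 or n0 == 0:
        raise ConfigurationError("likelihood ratios need both classes")
    lr_pos = _ratio_ci(counts.tp, n1, counts.fp, n0, "log-LR")
    lr_neg = _ratio_ci(counts.fn, n1, counts.tn, n0, "log-LR")
    return lr_pos, lr_neg


def stratum_likelihood_ratios(tab: CrossTab) -> dict[str, IntervalEstimate]:
    """Per-cell LR = (PC fraction in cell)/(control fraction in cell)."""
    if tab.n_pc == 0 or tab.n_control == 0:
        raise ConfigurationError("cross-tab rows must be non-empty")
    names = ("3d+2d+", "3d+2d-", "3d-2d+", "3d-2d-")
    return {name: _ratio_ci(tab.pc[i], tab.n_pc, tab.control[i], tab.n_control,
                            "log-LR")
            for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# ROC / AUC (DeLong)
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and the DeLong structural components (V10 per case, V01 per
    control) for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ConfigurationError("AUC needs both classes")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def auc_point(scores, labels) -> float:
    """Mann–Whitney AUC (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, _, _ = _delong_components(scores, labels)
    return auc


def roc_auc(scores, labels) -> IntervalEstimate:
    """AUC with a 95% CI from the DeLong variance (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(scores, labels)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    half = Z95 * np.sqrt(var)
    return IntervalEstimate(point=auc,
                            lower=float(max(0.0, auc - half)),
                            upper=float(min(1.0, auc + half)),
                            method="DeLong")


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong comparison of two AUCs on the same studies.

    Returns ``(delta_auc, two_sided_p)``.  Identical score vectors give
    delta 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ConfigurationError("paired test needs aligned score vectors")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Size-stratified sensitivity and trend
# ---------------------------------------------------------------------------

SIZE_STRATA = ("<2cm", "2-4cm", ">4cm")


def assign_size_stratum(diameter_mm: float) -> str:
    """Tumor size stratum from the maximal diameter (cuts at 20 and 40 mm)."""
    if diameter_mm < 20:
        return SIZE_STRATA[0]
    if diameter_mm <= 40:
        return SIZE_STRATA[1]
    return SIZE_STRATA[2]


def cochran_armitage_trend(successes, totals, scores=None) -> float:
    """Two-sided Cochran–Armitage trend p-value for ordered proportions.

    Equivalent to the chi-square linear-trend (prop.trend) statistic with
    equally spaced stratum scores by default.
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(n <= 0) or len(r) < 2:
        raise ConfigurationError("trend test needs >= 2 non-empty strata")
    x = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, float)
    N = n.sum()
    pbar = r.sum() / N
    t = (x * r).sum() - pbar * (x * n).sum()
    var = pbar * (1 - pbar) * ((n * x ** 2).sum() - (n * x).sum() ** 2 / N)
    if var <= 0:
        return 1.0
    z = t / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def size_stratified_sensitivity(detected: dict[str, int], totals: dict[str, int]
                                ) -> tuple[dict[str, IntervalEstimate], float]:
    """Per-stratum sensitivity with exact CIs and the trend p-value.

    ``detected``/``totals`` map stratum name -> counts; strata are ordered
    per :data:`SIZE_STRATA` when present.
    """
    order = [s for s in SIZE_STRATA if s in totals] or list(totals)
    per = {s: proportion_ci(detected.get(s, 0), totals[s]) for s in order}
    p_trend = cochran_armitage_trend([detected.get(s, 0) for s in order],
                                     [totals[s] for s in order])
    return per, p_trend


def mcnemar_exact(calls_a, calls_b) -> float:
    """Exact McNemar p-value for paired binary calls (e.g. two analyses'
    detections on the same tumors)."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    table = [[int((a & b).sum()), int((a & ~b).sum())],
             [int((~a & b).sum()), int((~a & ~b).sum())]]
    return float(mcnemar(table, exact=True).pvalue)


# ---------------------------------------------------------------------------
# Feature screening
# ---------------------------------------------------------------------------

def feature_screen(table: pd.DataFrame, groups,
                   alpha: float = 0.001) -> tuple[pd.Series, int]:
    """Univariate two-group screen over a feature table.

    Continuous features use the two-sided Mann–Whitney U test; features with
    at most two distinct values use Fisher's exact test.  Returns the
    p-value per feature and the count below ``alpha``.
    """
    groups = np.asarray(groups, dtype=int)
    if np.unique(groups).size != 2:
        raise TrainingError("feature screen needs exactly two groups")
    g1 = groups == 1
    pvals = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        vals = np.unique(x[~np.isnan(x)])
        if len(vals) <= 1:
            pvals[col] = 1.0
        elif len(vals) == 2:
            hi = x == vals[1]
            tab = [[int((hi & g1).sum()), int((hi & ~g1).sum())],
                   [int((~hi & g1).sum()), int((~hi & ~g1).sum())]]
            pvals[col] = float(stats.fisher_exact(tab)[1])
        else:
            pvals[col] = float(stats.mannwhitneyu(
                x[g1], x[~g1], alternative="two-sided").pvalue)
    series = pd.Series(pvals)
    return series, int((series < alpha).sum())
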