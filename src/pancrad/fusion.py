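"""Logistic fusion of the 3D probability and 2D high-risk area, operating
cutoffs by the Youden index, and series/parallel decision rules.

The combined study-level probability is

    logit(p) = b0 + b1 * p3d + b2 * area2d

with ``p3d`` the 3D model's probability and ``area2d`` the high-risk-region
area in mm^2.  The published CAD operating point ships as
:data:`REFERENCE_FUSION` so its printed equation is directly testable:
b1 = 3.95759716, b2 = 0.00241766494, b0 = -2.79234888.

Decision rules per study: each branch's score is compared with its cutoff
(positive iff score > cutoff), and the series (both positive) / parallel
(either positive) combinations are derived from the 3D and 2D calls.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import warnings

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .errors import ConfigurationError, IncompleteStudyError, TrainingError

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class FusionModel:
    """Coefficients of the logistic fusion of (p3d, area2d)."""

    intercept: float
    coef_p3d: float
    coef_area: float
    penalized: bool = False  # True when fit fell back to a ridge-penalized fit

    def logit(self, p3d, area2d) -> np.ndarray:
        return (self.intercept + self.coef_p3d * np.asarray(p3d, dtype=float)
                + self.coef_area * np.asarray(area2d, dtype=float))


#: Published operating point of the combined analysis (versioned constant).
REFERENCE_FUSION = FusionModel(intercept=-2.79234888,
                               coef_p3d=3.95759716,
                               coef_area=0.00241766494)


def fit_fusion(p3d, area2d, labels) -> FusionModel:
    """Maximum-likelihood logistic fit of study label on (p3d, area2d).

    On perfect separation the MLE diverges; the fit falls back to an
    L2-penalized estimate and flags it via ``penalized=True``.
    """
    p3d = np.asarray(p3d, dtype=float)
    area2d = np.asarray(area2d, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise TrainingError("fusion fit needs both classes")
    X = sm.add_constant(np.column_stack([p3d, area2d]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0)
        b0, b1, b2 = res.params
        return FusionModel(intercept=float(b0), coef_p3d=float(b1),
                           coef_area=float(b2))
    except Exception:
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        b0, b1, b2 = np.asarray(res.params, dtype=float)
        return FusionModel(intercept=float(b0), coef_p3d=float(b1),
                           coef_area=float(b2), penalized=True)


def fit_fusion_ci(p3d, area2d, labels) -> tuple[FusionModel, np.ndarray]:
    """Fusion fit plus the 95% Wald CIs of (intercept, b1, b2)."""
    p3d = np.asarray(p3d, dtype=float)
    area2d = np.asarray(area2d, dtype=float)
    y = np.asarray(labels, dtype=int)
    X = sm.add_constant(np.column_stack([p3d, area2d]))
    res = sm.Logit(y, X).fit(disp=0)
    model = FusionModel(intercept=float(res.params[0]),
                        coef_p3d=float(res.params[1]),
                        coef_area=float(res.params[2]))
    return model, np.asarray(res.conf_int())


def combined_probability(model: FusionModel, p3d, area2d) -> np.ndarray:
    """Evaluate p = sigmoid(b0 + b1*p3d + b2*area2d)."""
    p3d = np.asarray(p3d, dtype=float)
    area2d = np.asarray(area2d, dtype=float)
    if np.any((p3d < 0) | (p3d > 1)):
        raise ConfigurationError("p3d must lie in [0, 1]")
    if np.any(area2d < 0):
        raise ConfigurationError("area must be non-negative")
    return expit(model.logit(p3d, area2d))


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    -inf/+inf; a study is called positive when score > cutoff.  Ties in J
    resolve to the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise TrainingError("Youden cutoff needs both classes")
    distinct = np.unique(scores)
    candidates = np.concatenate([[-np.inf],
                                 (distinct[:-1] + distinct[1:]) / 2.0,
                                 [np.inf]])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_j, best_c = -np.inf, candidates[0]
    for c in candidates:
        call = scores > c
        sens = (call & (y == 1)).sum() / n_pos
        spec = (~call & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (lowest) candidate wins ties
            best_j, best_c = j, c
    return float(best_c)


@dataclass(frozen=True)
class CutoffSet:
    """Operating cutoffs for the three study-level scores."""

    p3d: float
    area2d: float
    p_combined: float

    def to_json(self) -> str:
        return json.dumps({"p3d": self.p3d, "area2d": self.area2d,
                           "p_combined": self.p_combined})

    @classmethod
    def from_json(cls, text: str) -> "CutoffSet":
        obj = json.loads(text)
        return cls(p3d=obj["p3d"], area2d=obj["area2d"],
                   p_combined=obj["p_combined"])


def select_cutoffs(p3d, area2d, p_combined, labels) -> CutoffSet:
    """Youden cutoffs of all three branches on the validation outputs."""
    return CutoffSet(p3d=youden_cutoff(p3d, labels),
                     area2d=youden_cutoff(area2d, labels),
                     p_combined=youden_cutoff(p_combined, labels))


@dataclass
class StudyPrediction:
    """Per-study outputs and the five decision calls."""

    study_id: str
    p3d: float
    area2d: float
    p_combined: float
    call3d: str
    call2d: str
    call_combined: str
    call_series: str
    call_parallel: str

    def as_dict(self) -> dict:
        return dict(study_id=self.study_id, p3d=self.p3d, area2d=self.area2d,
                    p_combined=self.p_combined, call3d=self.call3d,
                    call2d=self.call2d, call_combined=self.call_combined,
                    call_series=self.call_series, call_parallel=self.call_parallel)


def _call(score: float, cutoff: float) -> str:
    return POSITIVE if score > cutoff else NEGATIVE


def decide(study_id: str, p3d: float, area2d: float, p_combined: float,
           cutoffs: CutoffSet) -> StudyPrediction:
    """Populate all five calls for one study.

    Series is positive iff both branch calls are positive; parallel iff
    either is.  Scores exactly equal to a cutoff are called negative.
    """
    for name, val in (("p3d", p3d), ("area2d", area2d), ("p_combined", p_combined)):
        if val is None or not np.isfinite(val):
            raise IncompleteStudyError(f"missing or non-finite score: {name}")
    c3 = _call(p3d, cutoffs.p3d)
    c2 = _call(area2d, cutoffs.area2d)
    cc = _call(p_combined, cutoffs.p_combined)
    series = POSITIVE if (c3 == POSITIVE and c2 == POSITIVE) else NEGATIVE
    parallel = POSITIVE if (c3 == POSITIVE or c2 == POSITIVE) else NEGATIVE
    return StudyPrediction(study_id=study_id, p3d=float(p3d),
                           area2d=float(area2d), p_combined=float(p_combined),
                           call3d=c3, call2d=c2, call_combined=cc,
                           call_series=series, call_parallel=parallel)
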