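"""Gradient-boosted tree classifiers with validation-AUC early stopping.

Both the study-level 3D model and the patch-level 2D model are XGBoost
boosters with logistic loss.  Training monitors AUC on a validation split
and stops after 30 evaluations without improvement; the iteration with the
highest validation AUC is kept as the final model.  Hyperparameters beyond
the loss and stopping rule (depth 6, learning rate 0.1, up to 1000 rounds,
no subsampling) are recorded in the model metadata for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import SchemaError, TrainingError


@dataclass(frozen=True)
class TrainingConfig:
    max_rounds: int = 1000
    early_stop_patience: int = 30
    learning_rate: float = 0.1
    max_depth: int = 6
    scale_pos_weight: float = 1.0  # optional imbalance reweighting; 1 = off
    seed: int = 0

    def booster_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "auc",
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": 1.0,
            "colsample_bytree": 1.0,
            "scale_pos_weight": self.scale_pos_weight,
            "seed": self.seed,
            "nthread": 1,
        }


@dataclass
class TrainedClassifier:
    booster: xgb.Booster
    feature_names: list[str]
    selected_iteration: int
    validation_auc_trace: np.ndarray
    config: TrainingConfig
    manifest_hash: str = ""

    @property
    def best_validation_auc(self) -> float:
        return float(self.validation_auc_trace[self.selected_iteration])

    def save(self, path: str | Path) -> None:
        """Persist model + metadata as a JSON bundle."""
        path = Path(path)
        payload = {
            "feature_names": self.feature_names,
            "selected_iteration": self.selected_iteration,
            "validation_auc_trace": self.validation_auc_trace.tolist(),
            "config": asdict(self.config),
            "manifest_hash": self.manifest_hash,
            "booster": self.booster.save_raw("json").decode(),
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster"].encode()))
        return cls(booster=booster,
                   feature_names=payload["feature_names"],
                   selected_iteration=int(payload["selected_iteration"]),
                   validation_auc_trace=np.asarray(payload["validation_auc_trace"]),
                   config=TrainingConfig(**payload["config"]),
                   manifest_hash=payload.get("manifest_hash", ""))


def manifest_hash(feature_names: list[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    names = feature_names or [f"f{i}" for i in range(arr.shape[1])]
    return arr, list(names)


def train_classifier(X_train, y_train, X_val, y_val,
                     config: TrainingConfig = TrainingConfig(),
                     feature_names: list[str] | None = None) -> TrainedClassifier:
    """Fit a boosted-tree classifier, returning the best-AUC iteration.

    Raises :class:`TrainingError` when either split is single-class or
    features contain NaNs (NaN would silently become a missing-value branch).
    """
    Xtr, names = _as_matrix(X_train, feature_names)
    Xva, names_va = _as_matrix(X_val, feature_names)
    if names != names_va:
        raise SchemaError("train/validation feature names differ")
    ytr = np.asarray(y_train, dtype=int)
    yva = np.asarray(y_val, dtype=int)
    for split, y in (("training", ytr), ("validation", yva)):
        if np.unique(y).size < 2:
            raise TrainingError(f"{split} split contains a single class")
    if np.isnan(Xtr).any() or np.isnan(Xva).any():
        raise TrainingError("feature matrix contains NaN values")

    dtrain = xgb.DMatrix(Xtr, label=ytr, feature_names=names)
    dval = xgb.DMatrix(Xva, label=yva, feature_names=names)
    evals_result: dict = {}
    booster = xgb.train(
        config.booster_params(), dtrain,
        num_boost_round=config.max_rounds,
        evals=[(dval, "validation")],
        early_stopping_rounds=config.early_stop_patience,
        evals_result=evals_result,
        verbose_eval=False,
    )
    trace = np.asarray(evals_result["validation"]["auc"], dtype=float)
    selected = int(np.argmax(trace))
    return TrainedClassifier(booster=booster, feature_names=names,
                             selected_iteration=selected,
                             validation_auc_trace=trace, config=config,
                             manifest_hash=manifest_hash(names))


def predict_probability(model: TrainedClassifier, rows) -> np.ndarray:
    """Probabilities from the selected iteration; validates the schema."""
    if isinstance(rows, pd.DataFrame):
        if list(rows.columns) != model.feature_names:
            raise SchemaError("feature names/order differ from fit time")
        arr = rows.to_numpy(dtype=float)
    else:
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} features, got {arr.shape}")
    if arr.shape[0] == 0:
        return np.empty(0)
    dm = xgb.DMatrix(arr, feature_names=model.feature_names)
    return model.booster.predict(
        dm, iteration_range=(0, model.selected_iteration + 1))


def feature_gain_ranking(model: TrainedClassifier) -> list[tuple[str, float]]:
    """Total split gain per feature, sorted non-increasing.

    Features the booster never split on are absent from the ranking.
    """
    gains = model.booster.get_score(importance_type="total_gain")
    return sorted(gains.items(), key=lambda kv: (-kv[1], kv[0]))
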