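"""Random-search tuning, k-fold ensemble training, and weighted soft voting.

The classifier is a leaf-wise histogram gradient-boosted decision tree
(LightGBM) consumed through a fit / predict-probability contract.  Training
runs stratified tenfold cross-validation with the tuned hyper-parameters,
yielding ten fold models, each weighted by its held-out balanced accuracy.
Prediction is weighted soft voting: the balanced-accuracy-weighted mean of
the fold models' positive-class probabilities, thresholded at 0.5 (scores
exactly at the threshold round up to positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import Booster, LGBMClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .data_model import FeatureTable
from .errors import ConfigError, SchemaError, StratificationError, ValidationError

#: num_leaves candidate grid used for tuning (50 values, 5..500).
NUM_LEAVES_GRID = [
    5, 15, 25, 35, 45, 55, 65, 75, 85, 95,
    106, 116, 126, 136, 146, 156, 166, 176, 186, 196,
    207, 217, 227, 237, 247, 257, 267, 277, 287, 297,
    308, 318, 328, 338, 348, 358, 368, 378, 388, 398,
    409, 419, 429, 439, 449, 459, 469, 479, 489, 500,
]


@dataclass(frozen=True)
class HyperParams:
    n_estimators: int
    num_leaves: int
    learning_rate: float

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.num_leaves < 2:
            raise ConfigError("n_estimators >= 1 and num_leaves >= 2 required")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ConfigError("learning_rate must be in (0, 1]")


@dataclass
class SearchSpace:
    n_estimators: list[int] = field(
        default_factory=lambda: list(range(50, 501, 50))
    )
    num_leaves: list[int] = field(default_factory=lambda: list(NUM_LEAVES_GRID))
    n_iterations: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_estimators or not self.num_leaves:
            raise ConfigError("candidate lists must be non-empty")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")

    def sample(self, rng: np.random.Generator) -> HyperParams:
        lr = 0.0
        while lr == 0.0:  # uniform on (0, 1), excluding 0
            lr = float(rng.random())
        return HyperParams(
            n_estimators=int(rng.choice(self.n_estimators)),
            num_leaves=int(rng.choice(self.num_leaves)),
            learning_rate=lr,
        )


def _make_learner(params: HyperParams, seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=params.n_estimators,
        num_leaves=params.num_leaves,
        learning_rate=params.learning_rate,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_row_wise=True,
    )


def _binary_y(table: FeatureTable, positive_label: str) -> np.ndarray:
    if positive_label not in set(table.y):
        raise ValidationError(f"positive label {positive_label!r} absent from table")
    return (table.y.to_numpy() == positive_label).astype(int)


class _BoosterModel:
    """predict_proba adapter around a text-deserialized LightGBM booster."""

    def __init__(self, booster: Booster):
        self.booster = booster

    def predict_proba(self, X) -> np.ndarray:
        p = np.asarray(self.booster.predict(X))
        return np.column_stack([1.0 - p, p])


@dataclass
class EnsembleModel:
    fold_models: list
    fold_balanced_accuracies: list[float]
    params: HyperParams
    feature_names: list[str]
    positive_label: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.fold_models) != len(self.fold_balanced_accuracies):
            raise ValidationError("one weight per fold model required")
        if any(w <= 0 for w in self.fold_balanced_accuracies):
            raise ValidationError("fold weights must be positive")

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.fold_balanced_accuracies))


def random_search(
    train: FeatureTable,
    space: SearchSpace,
    positive_label: str,
    inner_folds: int = 5,
) -> tuple[HyperParams, float]:
    """Sample configurations and score each by inner stratified-CV mean balanced accuracy."""
    y = _binary_y(train, positive_label)
    if min(np.bincount(y)) < 2:
        raise ValidationError("need >= 2 samples per class for tuning")
    rng = np.random.default_rng(space.seed)
    inner_folds = min(inner_folds, int(min(np.bincount(y))))
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=space.seed)
    X = train.X

    best: tuple[HyperParams, float] | None = None
    for _ in range(space.n_iterations):
        params = space.sample(rng)
        scores = []
        for tr_idx, va_idx in skf.split(X, y):
            model = _make_learner(params, space.seed)
            model.fit(X.iloc[tr_idx], y[tr_idx])
            scores.append(
                balanced_accuracy_score(y[va_idx], model.predict(X.iloc[va_idx]))
            )
        score = float(np.mean(scores))
        if best is None or score > best[1]:
            best = (params, score)
    assert best is not None
    return best


def cv_train(
    train: FeatureTable,
    params: HyperParams,
    positive_label: str,
    k: int = 10,
    seed: int = 0,
) -> EnsembleModel:
    """Train k fold models; each is weighted by its held-out balanced accuracy."""
    y = _binary_y(train, positive_label)
    if k > int(min(np.bincount(y))):
        raise StratificationError(
            f"k={k} exceeds the smallest class size {int(min(np.bincount(y)))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    models, weights = [], []
    for tr_idx, va_idx in skf.split(train.X, y):
        model = _make_learner(params, seed)
        model.fit(train.X.iloc[tr_idx], y[tr_idx])
        bal = balanced_accuracy_score(y[va_idx], model.predict(train.X.iloc[va_idx]))
        models.append(model)
        weights.append(float(bal))
    return EnsembleModel(
        fold_models=models,
        fold_balanced_accuracies=weights,
        params=params,
        feature_names=list(train.feature_names),
        positive_label=positive_label,
    )


def ensemble_predict(
    model: EnsembleModel, samples: FeatureTable | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted soft vote: scores in [0, 1] and binary labels (1 = positive class)."""
    X = samples.X if isinstance(samples, FeatureTable) else samples
    missing = set(model.feature_names) - set(X.columns)
    if missing:
        raise SchemaError(f"samples lack model features: {sorted(missing)}")
    X = X[model.feature_names]
    w = np.asarray(model.fold_balanced_accuracies, dtype=float)
    probs = np.stack(
        [np.asarray(m.predict_proba(X))[:, 1] for m in model.fold_models]
    )
    scores = (w[:, None] * probs).sum(axis=0) / w.sum()
    labels = (scores >= model.threshold).astype(int)
    return scores, labels


# -- persistence -------------------------------------------------------------


def save_ensemble(model: EnsembleModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "params": vars(model.params),
        "fold_balanced_accuracies": model.fold_balanced_accuracies,
        "feature_names": model.feature_names,
        "positive_label": model.positive_label,
        "threshold": model.threshold,
        "n_folds": len(model.fold_models),
    }
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for i, m in enumerate(model.fold_models):
        booster = m.booster_ if isinstance(m, LGBMClassifier) else m.booster
        (out / f"fold_{i:02d}.txt").write_text(booster.model_to_string())


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    src = Path(in_dir)
    meta = json.loads((src / "ensemble.json").read_text())
    models = [
        _BoosterModel(
            Booster(model_str=(src / f"fold_{i:02d}.txt").read_text())
        )
        for i in range(meta["n_folds"])
    ]
    return EnsembleModel(
        fold_models=models,
        fold_balanced_accuracies=[float(w) for w in meta["fold_balanced_accuracies"]],
        params=HyperParams(**meta["params"]),
        feature_names=meta["feature_names"],
        positive_label=meta["positive_label"],
        threshold=float(meta["threshold"]),
    )
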