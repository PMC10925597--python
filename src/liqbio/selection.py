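"""Iterative gain-importance feature selection with a boosted-tree ranker.

Five rounds by default: round 1 fits on the full reduced feature set and
records the top-k (default 10) features by total split gain; before each
subsequent round the subset_size = floor(n / n_rounds) lowest-gain features
are removed, so with 40 features the rounds see 40, 32, 24, 16 and 8.  The
selected set is the deduplicated union of all rounds' top features in
first-occurrence order.

The ranker is an XGBoost classifier consumed purely through its
fit / per-feature total-gain contract; the monitored evaluation metric during
fitting is the misclassification error rate, while the training objective is
binary log-loss (boosting needs a differentiable objective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from xgboost import XGBClassifier

from .data_model import FeatureTable
from .errors import ConfigError, ValidationError

DEFAULT_LEARNER = {
    "n_estimators": 100,
    "max_depth": 6,
    "learning_rate": 0.3,
}


@dataclass
class SelectionRound:
    round_index: int
    input_features: list[str]
    importances: dict[str, float]
    top_features: list[str]


@dataclass
class SelectionReport:
    subset_size: int
    rounds: list[SelectionRound]
    selected: list[str]

    def to_dict(self) -> dict:
        return {
            "subset_size": self.subset_size,
            "rounds": [
                {
                    "round_index": r.round_index,
                    "input_features": r.input_features,
                    "importances": r.importances,
                    "top_features": r.top_features,
                }
                for r in self.rounds
            ],
            "selected": self.selected,
        }


def _binary_target(table: FeatureTable) -> np.ndarray:
    classes = sorted(set(table.y))
    if len(classes) != 2:
        raise ValidationError(
            f"selection requires a binary target, got {len(classes)} class(es)"
        )
    return (table.y.to_numpy() == classes[1]).astype(int)


def _gain_importances(
    table: FeatureTable,
    features: list[str],
    learner_config: dict | None,
    seed: int,
) -> dict[str, float]:
    cfg = dict(DEFAULT_LEARNER)
    cfg.update(learner_config or {})
    model = XGBClassifier(
        eval_metric="error",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        **cfg,
    )
    sub = table.X[features]
    model.fit(sub, _binary_target(table))
    gains = model.get_booster().get_score(importance_type="total_gain")
    return {f: float(gains.get(f, 0.0)) for f in features}


def _rank(features: list[str], gains: dict[str, float], order: dict[str, int]) -> list[str]:
    """Gain-descending; zero-gain features rank last; ties by canonical column order."""
    return sorted(features, key=lambda f: (-gains[f], order[f]))


def importance_round(
    train: FeatureTable,
    features: list[str],
    top_k: int = 10,
    learner_config: dict | None = None,
    seed: int = 0,
    round_index: int = 1,
) -> SelectionRound:
    unknown = set(features) - set(train.feature_names)
    if unknown:
        raise ValidationError(f"unknown features: {sorted(unknown)}")
    gains = _gain_importances(train, features, learner_config, seed)
    order = {f: i for i, f in enumerate(train.feature_names)}
    ranked = _rank(list(features), gains, order)
    return SelectionRound(
        round_index=round_index,
        input_features=list(features),
        importances=gains,
        top_features=ranked[:top_k],
    )


def iterative_select(
    train: FeatureTable,
    n_rounds: int = 5,
    top_k: int = 10,
    learner_config: dict | None = None,
    seed: int = 0,
) -> SelectionReport:
    if n_rounds < 1:
        raise ConfigError("n_rounds must be >= 1")
    features = list(train.feature_names)
    if len(features) < n_rounds:
        raise ValidationError(
            f"{len(features)} features cannot support {n_rounds} shrinking rounds"
        )
    subset_size = len(features) // n_rounds
    order = {f: i for i, f in enumerate(train.feature_names)}

    rounds: list[SelectionRound] = []
    current = features
    for t in range(1, n_rounds + 1):
        rnd = importance_round(
            train, current, top_k=top_k, learner_config=learner_config,
            seed=seed, round_index=t,
        )
        rounds.append(rnd)
        if t < n_rounds:
            ranked = _rank(current, rnd.importances, order)
            survivors = set(ranked[: len(current) - subset_size])
            current = [f for f in current if f in survivors]

    selected = list(
        dict.fromkeys(f for rnd in rounds for f in rnd.top_features)
    )
    return SelectionReport(subset_size=subset_size, rounds=rounds, selected=selected)
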