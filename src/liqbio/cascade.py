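"""Multi-level binary cascade: cancer detection, then one-vs-rest typing stages.

Stage 0 separates Cancer from Normal on the full cohort.  Stage t > 0 takes
the samples of the cancer types not yet claimed, labels the next type in
``class_order`` as the target and the remainder as other, and fits a binary
classifier.  Each stage owns its full artifact chain: a stratified 90/10
split, correlation+MI feature reduction, iterative gain selection,
random-search tuning, and a balanced-accuracy-weighted CV ensemble, all
computed on that stage's training split only.

At prediction time a sample rejected by the detector is Normal; otherwise it
receives the first typing stage that claims it, falling back to the last
class when every typing stage declines (the final binary stage's negative
side), so the decision is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureTable, group_labels, stratified_split
from .ensemble import (
    EnsembleModel,
    SearchSpace,
    cv_train,
    ensemble_predict,
    random_search,
)
from .errors import ConfigError, SchemaError, ValidationError
from .evaluation import Metrics, compute_metrics, confusion_matrix, roc_auc
from .reduction import ReductionReport, apply_reduction, reduce_features
from .selection import SelectionReport, iterative_select

OTHER_LABEL = "Other"
DETECTION_LABEL = "Cancer"
NORMAL_LABEL = "Normal"


@dataclass
class PipelineConfig:
    """Knobs shared by every stage of the cascade (and the detection-only pipeline)."""

    test_fraction: float = 0.1
    corr_threshold: float = 0.5
    mi_bins: int = 10
    n_rounds: int = 5
    top_k: int = 10
    selection_learner: dict = field(default_factory=dict)
    search_iterations: int = 60
    inner_folds: int = 5
    cv_folds: int = 10
    class_order: list[str] | None = None
    seed: int = 0


@dataclass
class CascadeStage:
    stage_index: int
    positive_label: str
    training_population: list[str]
    reduction: ReductionReport
    selection: SelectionReport
    ensemble: EnsembleModel
    test_metrics: Metrics


@dataclass
class CascadeModel:
    stages: list[CascadeStage]
    class_order: list[str]


def build_stage_datasets(
    table: FeatureTable, class_order: list[str]
) -> list[FeatureTable]:
    """Binary stage datasets: detection on the full cohort, then shrinking one-vs-rest."""
    present = set(table.y)
    if len(class_order) < 2:
        raise ValidationError("need at least 2 cancer types for a cascade")
    extra = present - {NORMAL_LABEL} - set(class_order)
    if extra:
        raise ValidationError(f"labels outside class_order: {sorted(extra)}")
    for cls in class_order:
        if cls not in present:
            raise ValidationError(f"cancer type {cls!r} has zero samples")

    detection = group_labels(
        table, {cls: DETECTION_LABEL for cls in class_order}
    )
    datasets = [detection]
    for t in range(1, len(class_order)):
        remaining = class_order[t - 1 :]
        ids = table.y.index[table.y.isin(remaining)]
        sub = table.subset_samples(ids)
        target = class_order[t - 1]
        binary = group_labels(
            sub, {cls: OTHER_LABEL for cls in remaining[1:]}
        )
        datasets.append(binary)
    return datasets


def fit_stage(
    dataset: FeatureTable,
    positive_label: str,
    config: PipelineConfig,
    seed: int,
    stage_index: int = 0,
) -> CascadeStage:
    """Split / reduce / select / tune / train / evaluate one binary stage."""
    split = stratified_split(dataset, config.test_fraction, seed)
    reduction = reduce_features(
        split.train, threshold=config.corr_threshold, n_bins=config.mi_bins
    )
    reduced_train = apply_reduction(split.train, reduction)
    selection = iterative_select(
        reduced_train,
        n_rounds=config.n_rounds,
        top_k=config.top_k,
        learner_config=config.selection_learner,
        seed=seed,
    )
    selected_train = reduced_train.subset_features(selection.selected)
    space = SearchSpace(n_iterations=config.search_iterations, seed=seed)
    params, _ = random_search(
        selected_train, space, positive_label, inner_folds=config.inner_folds
    )
    model = cv_train(
        selected_train, params, positive_label, k=config.cv_folds, seed=seed
    )
    test = split.test.subset_features(selection.selected)
    scores, labels = ensemble_predict(model, test)
    y_true = (test.y.to_numpy() == positive_label).astype(int)
    metrics = compute_metrics(
        confusion_matrix(y_true, labels), auc=roc_auc(y_true, scores)
    )
    return CascadeStage(
        stage_index=stage_index,
        positive_label=positive_label,
        training_population=list(dataset.class_set),
        reduction=reduction,
        selection=selection,
        ensemble=model,
        test_metrics=metrics,
    )


def fit_cascade(table: FeatureTable, config: PipelineConfig) -> CascadeModel:
    class_order = config.class_order or [
        c for c in table.class_set if c != NORMAL_LABEL
    ]
    if len(class_order) == 1:
        # degenerate cascade: detection stage only
        datasets = [
            group_labels(table, {class_order[0]: DETECTION_LABEL})
        ]
    else:
        datasets = build_stage_datasets(table, class_order)
    stages = []
    for t, ds in enumerate(datasets):
        positive = DETECTION_LABEL if t == 0 else class_order[t - 1]
        stages.append(
            fit_stage(ds, positive, config, seed=config.seed + t, stage_index=t)
        )
    return CascadeModel(stages=stages, class_order=class_order)


def predict_cascade(model: CascadeModel, samples: FeatureTable) -> pd.Series:
    """One label per sample: Normal, a claimed cancer type, or the fallback last type."""
    needed = {f for s in model.stages for f in s.ensemble.feature_names}
    missing = needed - set(samples.X.columns)
    if missing:
        raise SchemaError(f"samples lack cascade features: {sorted(missing)}")

    n = samples.n_samples
    out = np.array([model.class_order[-1]] * n, dtype=object)
    _, det = ensemble_predict(
        model.stages[0].ensemble, samples.X[model.stages[0].ensemble.feature_names]
    )
    out[det == 0] = NORMAL_LABEL
    undecided = det == 1
    for stage in model.stages[1:]:
        if not undecided.any():
            break
        X = samples.X.loc[undecided, stage.ensemble.feature_names]
        _, labels = ensemble_predict(stage.ensemble, X)
        idx = np.flatnonzero(undecided)
        claimed = idx[labels == 1]
        out[claimed] = stage.positive_label
        undecided[claimed] = False
    return pd.Series(out, index=samples.X.index, name="predicted")
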