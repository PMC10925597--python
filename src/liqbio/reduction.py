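"""Redundancy filtering: Pearson-correlated pairs resolved by mutual information.

Feature pairs whose absolute Pearson correlation exceeds a threshold (default
0.5, strict) are treated as redundant; within each pair the member carrying
less mutual information with the class label is dropped.  Pairs are processed
in |r|-descending order with a skip-if-already-dropped rule, which makes the
outcome canonical for correlation chains.

Mutual information is estimated with a binned plug-in estimator in nats,
I(X;Y) = H(X) - H(X|Y): continuous features are discretized by equal-frequency
binning (default 10 bins); discrete features use their values directly, so on
fully discrete data the estimator equals the exact plug-in formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureTable
from .errors import ValidationError


@dataclass(frozen=True)
class CorrelatedPair:
    """One redundant pair and the decision taken on it.

    ``dropped`` is None when both members were already resolved by
    higher-|r| pairs, so this pair forced no new removal.
    """

    feature_a: str
    feature_b: str
    r: float
    mi_a: float
    mi_b: float
    dropped: str | None


@dataclass
class ReductionReport:
    threshold: float
    pairs: list[CorrelatedPair]
    kept_features: list[str]
    dropped_features: list[str]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "pairs": [vars(p) for p in self.pairs],
            "kept_features": self.kept_features,
            "dropped_features": self.dropped_features,
        }


def pearson_correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; constant features give NaN rows."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for correlations")
    C = table.X.corr(method="pearson", min_periods=2)
    # canonical diagonal: 1 for non-constant features, NaN (undefined) otherwise
    for name in C.columns:
        col = table.X[name].dropna()
        C.loc[name, name] = 1.0 if col.nunique() > 1 else np.nan
    return C


def find_correlated_pairs(
    matrix: pd.DataFrame, threshold: float = 0.5
) -> list[tuple[str, str, float]]:
    """All unordered pairs with |r| strictly above threshold, |r| desc then lexicographic."""
    names = list(matrix.columns)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = matrix.iloc[i, j]
            if pd.notna(r) and abs(r) > threshold:
                a, b = sorted((names[i], names[j]))
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))
    return pairs


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    codes = pd.qcut(x, n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(values, labels, n_bins: int = 10) -> float:
    """Plug-in MI (nats) between a feature and the class label, via H(X) - H(X|Y)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    mask = ~np.isnan(x)
    if not mask.any():
        raise ValidationError("feature has no observed values")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    x, y = x[mask], y[mask]
    codes = _discretize(x, n_bins)
    joint = pd.crosstab(codes, y).to_numpy().astype(float)
    h_x = _entropy(joint.sum(axis=1))
    n = joint.sum()
    h_x_given_y = sum(
        (joint[:, k].sum() / n) * _entropy(joint[:, k])
        for k in range(joint.shape[1])
        if joint[:, k].sum() > 0
    )
    return max(h_x - h_x_given_y, 0.0)


def reduce_features(
    table: FeatureTable, threshold: float = 0.5, n_bins: int = 10
) -> ReductionReport:
    """Drop the lower-MI member of each correlated pair; ties keep the earlier column."""
    matrix = pearson_correlation_matrix(table)
    raw_pairs = find_correlated_pairs(matrix, threshold)
    order = {name: i for i, name in enumerate(table.feature_names)}
    mi_cache: dict[str, float] = {}

    def mi(name: str) -> float:
        if name not in mi_cache:
            mi_cache[name] = mutual_information(table.X[name], table.y, n_bins)
        return mi_cache[name]

    dropped: list[str] = []
    records: list[CorrelatedPair] = []
    for a, b, r in raw_pairs:
        if a in dropped or b in dropped:
            records.append(CorrelatedPair(a, b, r, mi(a), mi(b), dropped=None))
            continue
        mi_a, mi_b = mi(a), mi(b)
        if mi_a == mi_b:
            loser = a if order[a] > order[b] else b
        else:
            loser = a if mi_a < mi_b else b
        dropped.append(loser)
        records.append(CorrelatedPair(a, b, r, mi_a, mi_b, dropped=loser))

    kept = [f for f in table.feature_names if f not in set(dropped)]
    dropped_sorted = sorted(dropped, key=order.__getitem__)
    return ReductionReport(
        threshold=threshold,
        pairs=records,
        kept_features=kept,
        dropped_features=dropped_sorted,
    )


def apply_reduction(table: FeatureTable, report: ReductionReport) -> FeatureTable:
    return table.subset_features(report.kept_features)
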