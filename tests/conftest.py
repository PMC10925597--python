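import numpy as np
import pandas as pd
import pytest

from liqbio import FeatureMeta, FeatureTable, SyntheticConfig, generate_cohort


def make_table(values: dict, labels: list, kinds: dict | None = None) -> FeatureTable:
    """Small FeatureTable from a {feature: column} dict."""
    kinds = kinds or {}
    X = pd.DataFrame(values, index=[f"S{i}" for i in range(len(labels))])
    features = [FeatureMeta(name=c, kind=kinds.get(c, "biomarker")) for c in X.columns]
    y = pd.Series(labels, index=X.index, name="label")
    return FeatureTable(X=X, y=y, features=features)


@pytest.fixture(scope="session")
def small_cohort() -> FeatureTable:
    """200-sample two-class cohort with one strong marker and one redundant pair."""
    cfg = SyntheticConfig(
        n_per_class={"Cancer": 110, "Normal": 90},
        n_biomarkers=8,
        informative={"Cancer": [(0, 2.5)]},
        correlated_pairs=[(0, 4, 0.8)],
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_cohort() -> FeatureTable:
    """Linearly separable table: marker ranges for the two classes do not overlap."""
    rng = np.random.default_rng(7)
    n = 120
    marker = np.concatenate([rng.uniform(10.0, 11.0, n), rng.uniform(0.0, 1.0, n)])
    noise = rng.uniform(0.0, 5.0, 2 * n)
    return make_table(
        {"Marker": marker, "Noise": noise},
        ["Cancer"] * n + ["Normal"] * n,
    )
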