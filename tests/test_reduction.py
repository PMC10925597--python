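import math

import numpy as np
import pandas as pd
import pytest

from liqbio import (
    SyntheticConfig,
    apply_reduction,
    find_correlated_pairs,
    generate_cohort,
    mutual_information,
    pearson_correlation_matrix,
    reduce_features,
)
from liqbio.errors import ValidationError

from conftest import make_table


def raw_moment_pearson(x, y):
    """Raw-moment correlation: (N*Sxy - Sx*Sy) / sqrt((N*Sxx - Sx^2)(N*Syy - Sy^2))."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = math.sqrt(
        (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
    )
    return num / den


def plugin_mi_oracle(codes, labels):
    """Brute-force double sum over the joint distribution, in nats."""
    codes, labels = np.asarray(codes), np.asarray(labels)
    n = len(codes)
    mi = 0.0
    for cx in np.unique(codes):
        px = (codes == cx).mean()
        for cy in np.unique(labels):
            pxy = ((codes == cx) & (labels == cy)).mean()
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * (labels == cy).mean()))
    return mi


class TestPearson:
    def test_self_correlation_is_one(self):
        t = make_table({"A": [1.0, 2.0, 5.0], "B": [2.0, 2.0, 3.0]}, ["x", "y", "x"])
        C = pearson_correlation_matrix(t)
        assert C.loc["A", "A"] == 1.0

    def test_perfect_negative(self):
        t = make_table({"X": [1.0, 2.0, 3.0], "Y": [6.0, 4.0, 2.0]}, ["a", "b", "a"])
        C = pearson_correlation_matrix(t)
        assert C.loc["X", "Y"] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_evaluated_raw_moment_case(self):
        t = make_table(
            {"X": [1.0, 2.0, 3.0, 4.0], "Y": [2.0, 1.0, 4.0, 3.0]}, ["a", "b"] * 2
        )
        C = pearson_correlation_matrix(t)
        assert C.loc["X", "Y"] == pytest.approx(0.6, abs=1e-12)

    def test_agrees_with_raw_moment_form_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x, y = rng.normal(size=30), rng.normal(size=30)
            t = make_table(
                {"X": np.abs(x), "Y": np.abs(y)}, ["a", "b"] * 15
            )
            C = pearson_correlation_matrix(t)
            assert C.loc["X", "Y"] == pytest.approx(
                raw_moment_pearson(np.abs(x), np.abs(y)), abs=1e-12
            )

    def test_constant_feature_flagged_undefined(self):
        t = make_table({"A": [1.0, 2.0, 3.0], "K": [5.0, 5.0, 5.0]}, ["a", "b", "a"])
        C = pearson_correlation_matrix(t)
        assert np.isnan(C.loc["K", "K"]) and np.isnan(C.loc["A", "K"])

    def test_pairwise_complete_with_missing(self, tmp_path):
        t = make_table(
            {"A": [1.0, 2.0, np.nan, 4.0], "B": [2.0, 4.0, 1.0, 8.0]}, ["a", "b"] * 2
        )
        C = pearson_correlation_matrix(t)
        assert C.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)


class TestFindCorrelatedPairs:
    def test_no_pairs_on_identity(self):
        C = pd.DataFrame(np.eye(3), columns=list("ABC"), index=list("ABC"))
        assert find_correlated_pairs(C) == []

    def test_sorted_by_absolute_r_descending(self):
        C = pd.DataFrame(
            [[1, 0.9, -0.6], [0.9, 1, 0.2], [-0.6, 0.2, 1]],
            columns=list("ABC"), index=list("ABC"),
        )
        pairs = find_correlated_pairs(C, 0.5)
        assert [(a, b) for a, b, _ in pairs] == [("A", "B"), ("A", "C")]
        assert pairs[0][2] == 0.9 and pairs[1][2] == -0.6

    def test_threshold_zero_gives_all_pairs(self):
        rng = np.random.default_rng(1)
        k = 6
        M = rng.normal(size=(50, k))
        C = pd.DataFrame(np.corrcoef(M.T), columns=[f"F{i}" for i in range(k)],
                         index=[f"F{i}" for i in range(k)])
        assert len(find_correlated_pairs(C, 0.0)) == k * (k - 1) // 2

    def test_threshold_is_strict(self):
        C = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], columns=list("AB"), index=list("AB")
        )
        assert find_correlated_pairs(C, 0.5) == []


class TestMutualInformation:
    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        y = rng.choice(["a", "b"], size=5000)
        assert mutual_information(x, y) < 0.01

    def test_deterministic_binary_dependence_is_ln2(self):
        y = np.array(["a", "b"] * 500)
        x = (y == "a").astype(float)
        assert mutual_information(x, y) == pytest.approx(math.log(2), abs=1e-12)

    def test_discrete_joint_table_matches_plugin_oracle(self):
        # joint counts {(0,A):4,(0,B):0,(1,A):1,(1,B):3,(2,A):0,(2,B):2}
        x = [0] * 4 + [1] * 4 + [2] * 2
        y = ["A"] * 4 + ["A"] + ["B"] * 3 + ["B"] * 2
        assert mutual_information(x, y) == pytest.approx(0.4682131227124219, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(
            plugin_mi_oracle(x, y), abs=1e-12
        )

    def test_oracle_equivalence_on_random_discrete_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(10, 60)
            x = rng.integers(0, rng.integers(2, 6), size=n)
            y = rng.choice(list("ABC"), size=n)
            assert mutual_information(x, y) == pytest.approx(
                plugin_mi_oracle(x, y), abs=1e-12
            )

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([np.nan, np.nan], ["a", "b"])

    def test_nonnegative_clamp(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=40)
            y = rng.choice(["a", "b"], size=40)
            assert mutual_information(np.abs(x), y) >= 0.0


class TestReduceFeatures:
    def test_no_pairs_means_identity(self):
        rng = np.random.default_rng(6)
        t = make_table(
            {f"F{i}": np.abs(rng.normal(size=60)) for i in range(4)},
            ["a", "b"] * 30,
        )
        rep = reduce_features(t, threshold=0.99)
        assert rep.kept_features == t.feature_names
        assert rep.dropped_features == []

    def test_drops_redundant_members_on_synthetic_ground_truth(self):
        cfg = SyntheticConfig(
            n_per_class={"Cancer": 600, "Normal": 600},
            n_biomarkers=12,
            informative={"Cancer": [(0, 2.0), (2, 2.0), (4, 2.0)]},
            correlated_pairs=[(0, 6, 0.8), (2, 7, 0.8), (4, 8, 0.8)],
            include_omega=False,
            seed=13,
        )
        t = generate_cohort(cfg)
        rep = reduce_features(t)
        assert set(rep.dropped_features) == {"BM07", "BM08", "BM09"}
        reduced = apply_reduction(t, rep)
        assert len(reduced.features) == len(t.features) - 3

    def test_never_drops_both_members(self, small_cohort):
        rep = reduce_features(small_cohort)
        for pair in rep.pairs:
            assert not (
                pair.feature_a in rep.dropped_features
                and pair.feature_b in rep.dropped_features
            )
            if pair.dropped is not None:
                assert pair.dropped in (pair.feature_a, pair.feature_b)

    def test_partition_invariant(self, small_cohort):
        rep = reduce_features(small_cohort)
        assert sorted(rep.kept_features + rep.dropped_features) == sorted(
            small_cohort.feature_names
        )
        assert not set(rep.kept_features) & set(rep.dropped_features)
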