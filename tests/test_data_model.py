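import numpy as np
import pandas as pd
import pytest

from liqbio import (
    FeatureMeta,
    group_labels,
    load_feature_table,
    schema_for_table,
    stratified_split,
    write_feature_table,
)
from liqbio.errors import SchemaError, StratificationError, ValidationError

from conftest import make_table


class TestFeatureMeta:
    def test_routine_requires_biomarker_kind(self):
        with pytest.raises(ValidationError):
            FeatureMeta(name="Age", kind="clinical", routine=True)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            FeatureMeta(name="x", kind="genomic")


class TestFeatureTable:
    def test_negative_biomarker_rejected(self):
        with pytest.raises(ValidationError):
            make_table({"CA-125": [1.0, -2.0]}, ["Cancer", "Normal"])

    def test_clinical_values_may_be_negative(self):
        t = make_table({"Z": [-1.0, 2.0]}, ["A", "B"], kinds={"Z": "clinical"})
        assert t.n_samples == 2

    def test_subset_features_keeps_canonical_order(self, small_cohort):
        sub = small_cohort.subset_features(["Age", "BM01"])
        assert sub.feature_names == ["BM01", "Age"]


class TestIO:
    def test_minimal_csv_parse(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,CA-125,label\nS0,35.1,Cancer\nS1,10.2,Normal\n")
        t = load_feature_table(p, {"label_column": "label", "id_column": "id"})
        assert t.n_samples == 2
        assert [f.kind for f in t.features] == ["biomarker"]

    def test_missing_label_column_is_schema_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,CA-125\nS0,35.1\n")
        with pytest.raises(SchemaError):
            load_feature_table(p, {"label_column": "label"})

    def test_duplicate_feature_columns_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,A,A,label\nS0,1,2,Cancer\n")
        with pytest.raises(ValidationError):
            load_feature_table(p, {"label_column": "label", "id_column": "id"})

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,A,label\n")
        with pytest.raises(ValidationError):
            load_feature_table(p, {"label_column": "label"})

    def test_non_numeric_cells_become_missing(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("id,A,label\nS0,n/a,Cancer\nS1,2.5,Normal\n")
        t = load_feature_table(p, {"label_column": "label", "id_column": "id"})
        assert np.isnan(t.X.loc["S0", "A"])

    @pytest.mark.parametrize("suffix", [".csv", ".tsv"])
    def test_write_read_round_trip(self, tmp_path, small_cohort, suffix):
        p = tmp_path / f"cohort{suffix}"
        write_feature_table(small_cohort, p)
        schema = schema_for_table(small_cohort)
        back = load_feature_table(p, schema)
        assert back.feature_names == small_cohort.feature_names
        assert list(back.y) == list(small_cohort.y)
        assert [(f.kind, f.routine) for f in back.features] == [
            (f.kind, f.routine) for f in small_cohort.features
        ]
        np.testing.assert_allclose(
            back.X.to_numpy(), small_cohort.X.to_numpy(), rtol=1e-12
        )


class TestGroupLabels:
    def test_upper_gi_grouping_yields_seven_cancer_classes(self):
        eight = ["Colorectal", "Breast", "Esophagus", "Stomach", "Lung",
                 "Pancreas", "Ovarian", "Liver"]
        labels = eight * 2 + ["Normal", "Normal"]
        t = make_table({"A": list(np.arange(len(labels), dtype=float))}, labels)
        g = group_labels(t, {"Esophagus": "Upper GI", "Stomach": "Upper GI"})
        cancer = [c for c in g.class_set if c != "Normal"]
        assert len(cancer) == 7
        assert "Upper GI" in cancer

    def test_empty_mapping_is_identity(self, small_cohort):
        g = group_labels(small_cohort, {})
        assert list(g.y) == list(small_cohort.y)
        assert g.class_set == small_cohort.class_set

    def test_detection_labelling(self, small_cohort):
        g = group_labels(small_cohort, {"Cancer": "Cancer"})
        assert set(g.class_set) == {"Cancer", "Normal"}

    def test_unknown_key_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            group_labels(small_cohort, {"Lung": "Upper GI"})

    def test_idempotent_when_range_disjoint_from_domain(self, small_cohort):
        mapping = {"Cancer": "Malignant"}
        once = group_labels(small_cohort, mapping)
        twice = group_labels(once, {k: v for k, v in mapping.items() if k in once.class_set})
        assert list(once.y) == list(twice.y)


class TestStratifiedSplit:
    def test_cohort_scale_counts(self):
        labels = ["Cancer"] * 1005 + ["Normal"] * 812
        t = make_table({"A": list(np.arange(1817, dtype=float))}, labels)
        res = stratified_split(t, 0.1, seed=0)
        counts = res.test.y.value_counts()
        assert counts["Cancer"] == 101
        assert counts["Normal"] == 81
        assert res.test.n_samples == 182

    def test_symmetric_half_split(self):
        t = make_table({"A": list(np.arange(20, dtype=float))}, ["X"] * 10 + ["Y"] * 10)
        res = stratified_split(t, 0.5, seed=1)
        assert res.test.y.value_counts().to_dict() == {"X": 5, "Y": 5}

    def test_deterministic_given_seed(self, small_cohort):
        a = stratified_split(small_cohort, 0.2, seed=9)
        b = stratified_split(small_cohort, 0.2, seed=9)
        assert a.test.sample_ids == b.test.sample_ids
        assert a.train.sample_ids == b.train.sample_ids

    def test_partition_preserves_label_multiset(self, small_cohort):
        res = stratified_split(small_cohort, 0.3, seed=2)
        combined = pd.concat([res.train.y, res.test.y]).value_counts()
        assert combined.to_dict() == small_cohort.y.value_counts().to_dict()
        assert not set(res.train.sample_ids) & set(res.test.sample_ids)

    def test_singleton_class_rejected(self):
        t = make_table({"A": [1.0, 2.0, 3.0]}, ["X", "X", "Y"])
        with pytest.raises(StratificationError):
            stratified_split(t, 0.4, seed=0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_invalid_fraction_rejected(self, small_cohort, frac):
        with pytest.raises(ValidationError):
            stratified_split(small_cohort, frac, seed=0)
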