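"""Cohort feature tables: metadata, label grouping, stratified splitting, CSV/TSV I/O.

The :class:`FeatureTable` is the currency of the whole pipeline: one row per
plasma sample, one column per feature (protein biomarker concentration, the
cfDNA omega score, or a clinical covariate), plus a class label per sample
(``Normal`` or a cancer type).  Missing measurements are carried as NaN and
passed through to learners that handle them natively; no imputation is done.

Categorical clinical covariates (sex, race) are stored as small non-negative
integer codes; the code table travels in the feature's free-text ``unit``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, StratificationError, ValidationError

FEATURE_KINDS = ("biomarker", "clinical", "omega")


@dataclass(frozen=True)
class FeatureMeta:
    """Per-feature metadata.

    ``routine`` marks the six biomarkers in common clinical use (AFP,
    CA 19-9, CA 125, CEA, Prolactin, CA 15-3), which matters only to the
    cost model.
    """

    name: str
    kind: str = "biomarker"
    routine: bool = False
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.routine and self.kind != "biomarker":
            raise ValidationError(
                f"feature {self.name!r}: routine=True requires kind='biomarker'"
            )


@dataclass
class FeatureTable:
    """Samples x features matrix with labels and per-feature metadata.

    ``X`` is indexed by sample id with columns in canonical (metadata) order;
    ``y`` is the aligned label series; ``class_set`` is the ordered list of
    distinct labels (first-occurrence order unless supplied).
    """

    X: pd.DataFrame
    y: pd.Series
    features: list[FeatureMeta]
    class_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names")
        if list(self.X.columns) != names:
            raise ValidationError("matrix columns do not match feature metadata order")
        if len(self.X) == 0:
            raise ValidationError("empty table")
        if len(self.y) != len(self.X) or not self.y.index.equals(self.X.index):
            raise ValidationError("labels not aligned with sample matrix")
        if not self.class_set:
            self.class_set = list(dict.fromkeys(self.y))
        missing = set(self.y) - set(self.class_set)
        if missing:
            raise ValidationError(f"labels outside class_set: {sorted(missing)}")
        for meta in self.features:
            if meta.kind == "biomarker":
                col = self.X[meta.name]
                vals = pd.to_numeric(col, errors="coerce")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"negative biomarker values in {meta.name!r}")

    # -- accessors -----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.X.index]

    def meta(self, name: str) -> FeatureMeta:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    # -- derived tables ------------------------------------------------------

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the given features, keeping canonical column order."""
        keep = [f for f in self.features if f.name in set(names)]
        missing = set(names) - {f.name for f in keep}
        if missing:
            raise ValidationError(f"unknown features: {sorted(missing)}")
        return FeatureTable(
            X=self.X[[f.name for f in keep]].copy(),
            y=self.y.copy(),
            features=keep,
            class_set=list(self.class_set),
        )

    def subset_samples(self, ids: Sequence) -> "FeatureTable":
        X = self.X.loc[list(ids)]
        return FeatureTable(
            X=X.copy(),
            y=self.y.loc[list(ids)].copy(),
            features=list(self.features),
            class_set=[c for c in self.class_set if c in set(self.y.loc[list(ids)])],
        )


@dataclass
class SplitResult:
    train: FeatureTable
    test: FeatureTable
    seed: int
    test_fraction: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def group_labels(table: FeatureTable, mapping: Mapping[str, str]) -> FeatureTable:
    """Merge classes by relabelling, e.g. esophagus/stomach -> Upper GI.

    Mapping keys must be existing classes; labels not in the mapping pass
    through unchanged.
    """
    unknown = set(mapping) - set(table.class_set)
    if unknown:
        raise ValidationError(f"mapping keys not in class_set: {sorted(unknown)}")
    new_y = table.y.map(lambda lab: mapping.get(lab, lab))
    new_classes = list(dict.fromkeys(new_y))
    if not new_classes:
        raise ValidationError("mapping produced an empty class set")
    return FeatureTable(
        X=table.X.copy(), y=new_y, features=list(table.features), class_set=new_classes
    )


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> SplitResult:
    """Per-class random split; test size per class is round(f * n), half away from zero.

    This rounding reproduces 101 cancer / 81 normal test samples from a
    1005/812 cohort at a 10% test fraction.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_ids: list = []
    train_ids: list = []
    for cls in table.class_set:
        ids = np.asarray(table.y.index[table.y == cls])
        n = len(ids)
        if n < 2:
            raise StratificationError(f"class {cls!r} has {n} sample(s); need >= 2")
        n_test = _round_half_away(test_fraction * n)
        if n_test >= n:
            raise StratificationError(
                f"class {cls!r}: test fraction leaves no training samples"
            )
        perm = rng.permutation(n)
        test_ids.extend(ids[perm[:n_test]])
        train_ids.extend(ids[perm[n_test:]])
    # preserve original row order within each part
    order = {sid: i for i, sid in enumerate(table.X.index)}
    test_ids.sort(key=order.__getitem__)
    train_ids.sort(key=order.__getitem__)
    return SplitResult(
        train=table.subset_samples(train_ids),
        test=table.subset_samples(test_ids),
        seed=seed,
        test_fraction=test_fraction,
    )


# -- I/O ---------------------------------------------------------------------


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_schema(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_feature_table(
    path: str | Path, schema: Mapping | str | Path, delimiter: str | None = None
) -> FeatureTable:
    """Read a cohort CSV/TSV into a validated :class:`FeatureTable`.

    ``schema`` (a mapping or path to a JSON file) declares ``label_column``,
    optionally ``id_column`` and ``delimiter``, and per-feature metadata under
    ``features`` ({name: {kind, routine, unit}}).  Columns absent from the
    schema default to non-routine biomarkers.  Non-numeric cells in feature
    columns become missing entries.
    """
    path = Path(path)
    if isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    label_col = schema.get("label_column")
    if not label_col:
        raise SchemaError("schema must declare 'label_column'")
    sep = _delimiter_for(path, delimiter or schema.get("delimiter"))

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None:
        raise ValidationError(f"{path}: empty file")
    if label_col not in header:
        raise SchemaError(f"label column {label_col!r} not found in {path}")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValidationError(f"duplicate columns in {path}: {sorted(dupes)}")

    df = pd.read_csv(path, sep=sep, dtype=str)
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    id_col = schema.get("id_column")
    if id_col and id_col in df.columns:
        df = df.set_index(id_col)
    else:
        df.index = [f"S{i}" for i in range(len(df))]
    y = df[label_col].astype(str)
    feat_cols = [c for c in df.columns if c != label_col]
    meta_spec = schema.get("features", {})
    features = [
        FeatureMeta(
            name=c,
            kind=meta_spec.get(c, {}).get("kind", "biomarker"),
            routine=bool(meta_spec.get(c, {}).get("routine", False)),
            unit=meta_spec.get(c, {}).get("unit", ""),
        )
        for c in feat_cols
    ]
    X = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    return FeatureTable(X=X, y=y.rename("label"), features=features)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    delimiter: str | None = None,
    label_column: str = "label",
    id_column: str = "id",
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    out = table.X.copy()
    out.insert(0, id_column, table.X.index)
    out[label_column] = table.y.values
    out.to_csv(path, sep=sep, index=False)


def schema_for_table(
    table: FeatureTable, label_column: str = "label", id_column: str = "id"
) -> dict:
    """Schema dict that makes ``write -> load`` a lossless round trip."""
    return {
        "label_column": label_column,
        "id_column": id_column,
        "features": {
            f.name: {"kind": f.kind, "routine": f.routine, "unit": f.unit}
            for f in table.features
        },
    }
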