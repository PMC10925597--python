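"""Omega score: UID-weighted log-ratio summary of per-well cfDNA mutation p-values.

Each sequencing well i contributes a weight w_i = UIDs_i / sum(UIDs) (its share
of unique template molecules) and a log-ratio ln(p_i^C / p_i^N) of the well's
p-value under the cancer vs. normal mutant-allele-frequency distributions:

    omega = sum_i w_i * ln(p_i^C / p_i^N)

Upstream derivation of the per-well p-values from sequencing reads is outside
this package; they are consumed as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class OmegaWellData:
    """Per-well UID counts and cancer/normal p-values for one plasma sample."""

    uids_per_well: tuple[int, ...]
    p_cancer: tuple[float, ...]
    p_normal: tuple[float, ...]

    def __post_init__(self) -> None:
        w = len(self.uids_per_well)
        if w < 1:
            raise ValidationError("at least one well required")
        if len(self.p_cancer) != w or len(self.p_normal) != w:
            raise ValidationError("uids, p_cancer, p_normal must have equal length")
        if any(u <= 0 for u in self.uids_per_well):
            raise ValidationError("UID counts must be positive")
        for p in (*self.p_cancer, *self.p_normal):
            if not 0.0 < p <= 1.0:
                raise ValidationError(f"p-value {p} outside (0, 1]")

    @property
    def n_wells(self) -> int:
        return len(self.uids_per_well)

    @property
    def weights(self) -> np.ndarray:
        u = np.asarray(self.uids_per_well, dtype=float)
        return u / u.sum()


def compute_omega(wells: OmegaWellData) -> float:
    """UID-weighted sum of per-well log p-value ratios (natural log)."""
    ratio = np.asarray(wells.p_cancer) / np.asarray(wells.p_normal)
    return float(np.dot(wells.weights, np.log(ratio)))


def load_well_data(path: str | Path) -> OmegaWellData:
    """Read a per-well CSV with columns uids, p_cancer, p_normal (a 'well' id column is ignored)."""
    df = pd.read_csv(path)
    for col in ("uids", "p_cancer", "p_normal"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return OmegaWellData(
        uids_per_well=tuple(int(u) for u in df["uids"]),
        p_cancer=tuple(float(p) for p in df["p_cancer"]),
        p_normal=tuple(float(p) for p in df["p_normal"]),
    )
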