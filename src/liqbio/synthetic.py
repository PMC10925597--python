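"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multi-analyte liquid-biopsy cohort: non-negative,
right-skewed protein biomarker concentrations (log-normal), class-dependent
mean shifts on the log scale for informative features, correlated feature
pairs induced through shared Gaussian latent factors, an omega score computed
from simulated per-well UID/p-value data, and age/sex/race covariates.

Default class counts mirror the cohort the pipeline targets: 1005 cancer
samples over seven types and 812 healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureMeta, FeatureTable
from .errors import ConfigError
from .omega import OmegaWellData, compute_omega

#: Seven-type class counts matching the target cohort's 1005 cancers, plus controls.
DEFAULT_CLASS_COUNTS = {
    "Colorectal": 388,
    "Breast": 209,
    "Upper GI": 113,
    "Lung": 104,
    "Pancreas": 93,
    "Ovarian": 54,
    "Liver": 44,
    "Normal": 812,
}

_NORMAL_AGE = (17.0, 88.0, 49.0)
_CANCER_AGE = (22.0, 93.0, 63.0)
_SEX_PROBS = {"Female": 0.507, "Male": 0.493}
_RACE_PROBS = {
    "Asian": 0.178,
    "Black": 0.092,
    "Caucasian": 0.554,
    "Hispanic": 0.042,
    "Other": 0.134,
}


@dataclass
class SyntheticConfig:
    """Cohort recipe.

    informative maps a class label to (biomarker index, effect size) pairs;
    effects are shifts of the log-concentration in units of its SD.
    correlated_pairs lists (i, j, rho) latent correlations; the realized
    Pearson r on the raw (exponentiated) scale is close to, not exactly, rho.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_biomarkers: int = 39
    informative: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    correlated_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    age_ranges: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(_SEX_PROBS))
    race_probs: dict[str, float] = field(default_factory=lambda: dict(_RACE_PROBS))
    include_omega: bool = True
    n_wells: int = 4
    omega_cancer_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ConfigError("n_per_class is empty")
        for cls, n in self.n_per_class.items():
            if n <= 0:
                raise ConfigError(f"class {cls!r} count must be positive")
        if self.n_biomarkers < 1:
            raise ConfigError("n_biomarkers must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        seen: set[int] = set()
        for i, j, rho in self.correlated_pairs:
            if i == j:
                raise ConfigError("a correlated pair needs two distinct features")
            for k in (i, j):
                if not 0 <= k < self.n_biomarkers:
                    raise ConfigError(f"pair feature index {k} out of range")
                if k in seen:
                    raise ConfigError(f"feature {k} appears in more than one pair")
                seen.add(k)
            if not abs(rho) < 1:
                raise ConfigError("|rho| must be < 1")
        for cls, effects in self.informative.items():
            if cls not in self.n_per_class:
                raise ConfigError(f"informative class {cls!r} not in n_per_class")
            for idx, eff in effects:
                if not 0 <= idx < self.n_biomarkers:
                    raise ConfigError(f"informative feature index {idx} out of range")
                if not np.isfinite(eff):
                    raise ConfigError("effect sizes must be finite")
        # A pair whose members are both informative for a class must share the
        # effect; anything else makes the redundancy ground truth ambiguous.
        for i, j, _ in self.correlated_pairs:
            for cls, effects in self.informative.items():
                eff = dict(effects)
                if i in eff and j in eff and eff[i] != eff[j]:
                    raise ConfigError(
                        f"pair ({i}, {j}) has contradictory effects for class {cls!r}"
                    )

    @property
    def class_order(self) -> list[str]:
        return list(self.n_per_class)


def generate_well_data(
    n_wells: int, cancer_shift: float, seed: int | np.random.Generator
) -> OmegaWellData:
    """Simulate per-well UID counts and p-values.

    p_N ~ U(0,1], p_C = v^(1+shift) with v ~ U(0,1] independent, so
    E[ln(p_C/p_N)] = -(1+shift) + 1 = -shift for every well, giving the
    closed-form expectation E[omega] = -shift regardless of UID weights.
    A positive shift biases cancer p-values low, i.e. omega negative.
    """
    if n_wells < 1:
        raise ConfigError("n_wells must be >= 1")
    if cancer_shift < 0:
        raise ConfigError("cancer_shift must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    uids = rng.integers(50, 2001, size=n_wells)
    # 1 - random() lies in (0, 1]
    p_normal = 1.0 - rng.random(n_wells)
    p_cancer = (1.0 - rng.random(n_wells)) ** (1.0 + cancer_shift)
    return OmegaWellData(
        uids_per_well=tuple(int(u) for u in uids),
        p_cancer=tuple(float(p) for p in p_cancer),
        p_normal=tuple(float(p) for p in p_normal),
    )


def _latent_rho(rho: float, sigma: float) -> float:
    """Latent Gaussian correlation that realizes Pearson r = rho after exp().

    For a bivariate log-normal with equal log-scale SD sigma, the raw-scale
    correlation is (exp(sigma^2 * rho_L) - 1) / (exp(sigma^2) - 1); this
    inverts that map.  Strong negative raw-scale correlations are not
    attainable for log-normals, in which case the config is rejected.
    """
    arg = 1.0 + rho * (np.exp(sigma**2) - 1.0)
    if arg <= 0:
        raise ConfigError(
            f"target correlation {rho} not attainable for a log-normal pair"
        )
    rho_l = np.log(arg) / sigma**2
    if not -1.0 < rho_l < 1.0:
        raise ConfigError(
            f"target correlation {rho} not attainable at noise_sd={sigma}"
        )
    return float(rho_l)


def _draw_ages(
    rng: np.random.Generator, n: int, bounds: tuple[float, float, float]
) -> np.ndarray:
    lo, hi, mean = bounds
    ages = rng.normal(mean, (hi - lo) / 6.0, size=n)
    return np.clip(np.round(ages), lo, hi)


def _categorical_codes(
    rng: np.random.Generator, n: int, probs: dict[str, float]
) -> np.ndarray:
    p = np.asarray(list(probs.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(len(p), size=n, p=p)


def _code_table(probs: dict[str, float]) -> str:
    return ",".join(f"{i}={k}" for i, k in enumerate(probs))


def generate_cohort(config: SyntheticConfig) -> FeatureTable:
    """Draw a full cohort feature table; bit-identical given the same config."""
    rng = np.random.default_rng(config.seed)
    labels = [
        cls for cls in config.class_order for _ in range(config.n_per_class[cls])
    ]
    n_total = len(labels)
    p = config.n_biomarkers
    y = pd.Series(labels, index=[f"S{i:05d}" for i in range(n_total)], name="label")

    # latent standard-normal matrix with pair structure
    Z = rng.standard_normal((n_total, p))
    for i, j, rho in config.correlated_pairs:
        rho_l = _latent_rho(rho, config.noise_sd)
        f = rng.standard_normal(n_total)
        a = np.sqrt(abs(rho_l))
        b = np.sqrt(1.0 - abs(rho_l))
        Z[:, i] = a * f + b * rng.standard_normal(n_total)
        Z[:, j] = np.sign(rho_l) * a * f + b * rng.standard_normal(n_total)

    # class-dependent shifts on the log scale, in SD units
    for cls, effects in config.informative.items():
        rows = y.to_numpy() == cls
        for idx, eff in effects:
            Z[rows, idx] += eff

    base_log_mean = rng.uniform(1.0, 6.0, size=p)
    values = np.exp(base_log_mean[None, :] + config.noise_sd * Z)

    names = [f"BM{i + 1:02d}" for i in range(p)]
    columns = {name: values[:, i] for i, name in enumerate(names)}
    features = [FeatureMeta(name=n, kind="biomarker", unit="pg/ml") for n in names]

    if config.include_omega:
        omegas = np.empty(n_total)
        for k, cls in enumerate(y):
            shift = 0.0 if cls == "Normal" else config.omega_cancer_shift
            omegas[k] = compute_omega(
                generate_well_data(config.n_wells, shift, rng)
            )
        columns["Omega Score"] = omegas
        features.append(FeatureMeta(name="Omega Score", kind="omega", unit="ln ratio"))

    ages = np.empty(n_total)
    for cls in config.class_order:
        rows = y.to_numpy() == cls
        bounds = config.age_ranges.get(
            cls, _NORMAL_AGE if cls == "Normal" else _CANCER_AGE
        )
        ages[rows] = _draw_ages(rng, int(rows.sum()), bounds)
    columns["Age"] = ages
    features.append(FeatureMeta(name="Age", kind="clinical", unit="years"))

    columns["Sex"] = _categorical_codes(rng, n_total, config.sex_probs)
    features.append(
        FeatureMeta(name="Sex", kind="clinical", unit=_code_table(config.sex_probs))
    )
    columns["Race"] = _categorical_codes(rng, n_total, config.race_probs)
    features.append(
        FeatureMeta(name="Race", kind="clinical", unit=_code_table(config.race_probs))
    )

    X = pd.DataFrame(columns, index=y.index)[[f.name for f in features]]
    return FeatureTable(X=X, y=y, features=features, class_set=config.class_order)
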