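"""End-to-end orchestration: config parsing, run directories, reproducible reports.

A run takes a single JSON config (either a synthetic-cohort recipe or a path
to a cohort CSV + schema), executes detection — split, reduce, select, tune,
CV-train, evaluate — and optionally the full typing cascade, and writes every
artifact under an output directory.  Reruns with the same config and seed
reproduce all JSON reports byte-identically: reports are serialized with
sorted keys and contain no timestamps (wall-clock lines go to the text log
only).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cascade import (
    DETECTION_LABEL,
    NORMAL_LABEL,
    CascadeModel,
    CascadeStage,
    PipelineConfig,
    fit_cascade,
    fit_stage,
)
from .data_model import FeatureTable, group_labels, load_feature_table
from .ensemble import load_ensemble, save_ensemble
from .errors import ConfigError
from .evaluation import stage_macro_average
from .synthetic import SyntheticConfig, generate_cohort


@dataclass
class RunConfig:
    seed: int
    synthetic: dict | None = None
    input_path: str | None = None
    schema_path: str | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    cascade: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set 'seed'")
        pipe_raw = dict(raw.get("pipeline", {}))
        cfg = cls(
            seed=int(raw["seed"]),
            synthetic=raw.get("synthetic"),
            input_path=raw.get("input"),
            schema_path=raw.get("schema"),
            pipeline=PipelineConfig(**pipe_raw),
            cascade=bool(raw.get("cascade", False)),
        )
        cfg.pipeline.seed = cfg.seed
        if cfg.synthetic is None and cfg.input_path is None:
            raise ConfigError("config needs either 'synthetic' or 'input'")
        if cfg.input_path is not None and cfg.schema_path is None:
            raise ConfigError("'input' requires 'schema'")
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def synthetic_config_from_dict(raw: dict, seed: int | None = None) -> SyntheticConfig:
    """Build a SyntheticConfig from plain-JSON data (lists instead of tuples)."""
    raw = dict(raw)
    if seed is not None:
        raw.setdefault("seed", seed)
    if "informative" in raw:
        raw["informative"] = {
            cls: [(int(i), float(e)) for i, e in effects]
            for cls, effects in raw["informative"].items()
        }
    if "correlated_pairs" in raw:
        raw["correlated_pairs"] = [
            (int(i), int(j), float(r)) for i, j, r in raw["correlated_pairs"]
        ]
    if "age_ranges" in raw:
        raw["age_ranges"] = {
            cls: tuple(float(v) for v in bounds)
            for cls, bounds in raw["age_ranges"].items()
        }
    return SyntheticConfig(**raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_stage(stage: CascadeStage, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _dump_json(stage.reduction.to_dict(), out / "reduction.json")
    _dump_json(stage.selection.to_dict(), out / "selection.json")
    _dump_json(
        {
            "stage_index": stage.stage_index,
            "positive_label": stage.positive_label,
            "training_population": stage.training_population,
            "params": asdict(stage.ensemble.params),
            "fold_balanced_accuracies": stage.ensemble.fold_balanced_accuracies,
            "mean_cv_balanced_accuracy": stage.ensemble.mean_balanced_accuracy,
            "test_metrics": stage.test_metrics.to_dict(),
        },
        out / "stage.json",
    )
    save_ensemble(stage.ensemble, out / "ensemble")


def save_cascade(model: CascadeModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_json(
        {"class_order": model.class_order, "n_stages": len(model.stages)},
        out / "cascade.json",
    )
    for stage in model.stages:
        _write_stage(stage, out / f"stage_{stage.stage_index:02d}")


def load_cascade(in_dir: str | Path) -> CascadeModel:
    """Reload a cascade bundle for prediction (fit-time reports are not rehydrated)."""
    src = Path(in_dir)
    meta = json.loads((src / "cascade.json").read_text())
    stages = []
    for t in range(meta["n_stages"]):
        sdir = src / f"stage_{t:02d}"
        smeta = json.loads((sdir / "stage.json").read_text())
        stages.append(
            CascadeStage(
                stage_index=t,
                positive_label=smeta["positive_label"],
                training_population=smeta["training_population"],
                reduction=None,
                selection=None,
                ensemble=load_ensemble(sdir / "ensemble"),
                test_metrics=None,
            )
        )
    return CascadeModel(stages=stages, class_order=meta["class_order"])


def _load_cohort(config: RunConfig) -> FeatureTable:
    if config.synthetic is not None:
        return generate_cohort(
            synthetic_config_from_dict(config.synthetic, seed=config.seed)
        )
    return load_feature_table(config.input_path, config.schema_path)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured run and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"{time.strftime('%Y-%m-%d %H:%M:%S')} run started (seed={config.seed})"]

    table = _load_cohort(config)
    log_lines.append(
        f"cohort: {table.n_samples} samples, {len(table.features)} features, "
        f"classes={table.class_set}"
    )

    if config.cascade:
        model = fit_cascade(table, config.pipeline)
        save_cascade(model, out / "cascade")
        per_stage = [s.test_metrics for s in model.stages]
        _dump_json(
            {
                "per_stage": [m.to_dict() for m in per_stage],
                "macro_average": stage_macro_average(per_stage).to_dict(),
                "typing_macro_average": stage_macro_average(per_stage[1:]).to_dict()
                if len(per_stage) > 1
                else None,
            },
            out / "metrics.json",
        )
        log_lines.append(f"cascade: {len(model.stages)} stages fitted")
    else:
        cancer_classes = [c for c in table.class_set if c != NORMAL_LABEL]
        detection = group_labels(
            table, {c: DETECTION_LABEL for c in cancer_classes}
        )
        stage = fit_stage(
            detection, DETECTION_LABEL, config.pipeline, seed=config.seed
        )
        _write_stage(stage, out / "detection")
        _dump_json(
            {"detection": stage.test_metrics.to_dict()}, out / "metrics.json"
        )
        log_lines.append("detection stage fitted")

    raw_cfg = {
        "seed": config.seed,
        "synthetic": config.synthetic,
        "input": config.input_path,
        "schema": config.schema_path,
        "pipeline": asdict(config.pipeline),
        "cascade": config.cascade,
    }
    cfg_json = json.dumps(raw_cfg, sort_keys=True)
    _dump_json(
        {
            "liqbio_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "config": raw_cfg,
        },
        out / "manifest.json",
    )
    log_lines.append(f"{time.strftime('%Y-%m-%d %H:%M:%S')} run finished")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
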