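"""End-to-end orchestration: generate → featurize → train → evaluate → compare.

A single validated config drives the whole run. In ``synthetic`` input mode the
movies come from the generator (one wild-type parameter set plus its widened
mutant variant, several videos per genotype); in ``mask-files`` mode frame
tables are read from a per-nucleus CSV produced by the detection step. Every
intermediate table is persisted, and the run report records config, seeds and
library versions so any output can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluation as E
from . import features as F
from . import groups as G
from . import model as M
from . import synthetic as S
from .types import GENOTYPES, FrameTable, read_frames_csv, write_frames_csv

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


class PipelineConfigError(ValueError):
    """Aggregated, human-readable config validation failures."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid pipeline config:\n" + "\n".join(f"- {e}" for e in self.errors))


@dataclass
class PipelineConfig:
    """Validated settings for one full run."""

    input_mode: str = "synthetic"  # "synthetic" | "mask-files"
    synth: S.SynthParams = field(default_factory=S.SynthParams)
    n_videos_per_group: int = 4
    frames_csv: str | None = None  # mask-files mode: per-nucleus CSV
    grid_size: float = 62.5
    ripley_radius: float | None = None  # default: grid_size / 2
    ripley_correction: str = "none"
    model: M.ModelConfig = field(default_factory=M.ModelConfig)
    kl_axis: str = "DV"
    bootstrap_B: int = 10_000
    bootstrap_alpha: float = 0.05
    outdir: str = "embryocast_run"
    seed: int = 0


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Normalize a raw mapping (e.g. parsed YAML) into a validated config.

    All cross-field constraints are checked up front and reported together so
    a bad config fails before any computation.
    """
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        errors: list[str] = []
        raw = dict(raw or {})
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            errors.append(f"unsupported schema_version {version}")
        synth_raw = raw.pop("synth", {}) or {}
        model_raw = raw.pop("model", {}) or {}
        try:
            synth = S.SynthParams(**synth_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"synth: {exc}")
            synth = S.SynthParams()
        try:
            if "features" in model_raw:
                model_raw["features"] = tuple(model_raw["features"])
            model = M.ModelConfig(**model_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"model: {exc}")
            model = M.ModelConfig()
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            errors.append(f"unknown config keys: {sorted(unknown)}")
        if errors:
            raise PipelineConfigError(errors)
        cfg = PipelineConfig(synth=synth, model=model,
                             **{k: v for k, v in raw.items() if k in known - {"synth", "model"}})

    errors = []
    if cfg.input_mode not in ("synthetic", "mask-files"):
        errors.append(f"input_mode must be 'synthetic' or 'mask-files', got {cfg.input_mode!r}")
    if cfg.input_mode == "mask-files" and not cfg.frames_csv:
        errors.append("mask-files mode requires frames_csv")
    if cfg.input_mode == "synthetic" and cfg.n_videos_per_group < 2:
        errors.append("n_videos_per_group must be >= 2 (held-out evaluation needs both)")
    w, h = cfg.synth.image_width, cfg.synth.image_height
    if cfg.grid_size <= 0 or cfg.grid_size > min(w, h):
        errors.append(
            f"grid_size {cfg.grid_size} invalid for image {w}x{h} "
            f"(must be in (0, {min(w, h)}])"
        )
    if cfg.ripley_radius is not None and cfg.ripley_radius <= 0:
        errors.append("ripley_radius must be positive")
    if cfg.ripley_correction not in ("none", "translation"):
        errors.append(f"ripley_correction must be 'none' or 'translation', got {cfg.ripley_correction!r}")
    if cfg.bootstrap_B < 100:
        errors.append("bootstrap_B must be >= 100")
    if not 0 < cfg.bootstrap_alpha < 1:
        errors.append("bootstrap_alpha must lie in (0, 1)")
    if errors:
        raise PipelineConfigError(errors)
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _generate_all(cfg: PipelineConfig) -> list[FrameTable]:
    """Synthetic movies for both genotypes, seeded from the master seed."""
    wt_params = dataclasses.replace(cfg.synth, seed=cfg.seed & 0x7FFFFFFF)
    mut_params = S.mutant_variant(wt_params)
    frames: list[FrameTable] = []
    for geno_idx, (genotype, params) in enumerate(zip(GENOTYPES, (wt_params, mut_params))):
        for v in range(cfg.n_videos_per_group):
            frames.extend(
                S.generate_series(
                    params,
                    video_id=f"{genotype}_v{v}",
                    genotype=genotype,
                    video_index=geno_idx * 1000 + v,
                )
            )
    return frames


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the full pipeline and return the run report (also written to
    ``<outdir>/report.json``).

    Stages, in order: input (generate or load frame tables), featurization at
    the configured grid size, stage averaging, leave-one-video-out training +
    evaluation per genotype, and group comparison (bootstrap CIs and
    mixed-effects contrasts) on the per-(video, stage) axis maes. Deterministic
    for a fixed config + seed.
    """
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": [],
    }

    stage_name = "input"
    try:
        if cfg.input_mode == "synthetic":
            frames = _generate_all(cfg)
        else:
            frames = read_frames_csv(cfg.frames_csv)
            if not frames:
                raise ValueError(f"no frames in {cfg.frames_csv}")
        write_frames_csv(frames, outdir / "frames.csv")
        report["stages"].append({"stage": stage_name, "n_frames": len(frames)})

        stage_name = "featurize"
        grid = F.make_grid(frames[0].image_width, frames[0].image_height, cfg.grid_size)
        radius = cfg.ripley_radius if cfg.ripley_radius is not None else cfg.grid_size / 2
        ripley = F.RipleyConfig(
            radius_r=radius,
            window_width=cfg.grid_size,
            window_height=cfg.grid_size,
            correction=cfg.ripley_correction,
        )
        feats = F.featurize_series(frames, grid, ripley)
        feats.to_csv(outdir / "features.csv", index=False)
        stage_matrix = F.stage_aggregate(feats)
        stage_matrix.to_csv(outdir / "stage_features.csv", index=False)
        report["stages"].append(
            {"stage": stage_name, "grid": grid.shape, "n_feature_rows": len(feats)}
        )

        stage_name = "supervise"
        dataset = F.build_supervised(stage_matrix, grid)
        dataset.frame.to_csv(outdir / "supervised.csv", index=False)
        report["stages"].append({"stage": stage_name, "n_rows": len(dataset)})

        stage_name = "evaluate"
        model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed & 0x7FFFFFFF)
        metrics = E.leave_one_video_out(stage_matrix, grid, model_cfg, kl_axis=cfg.kl_axis)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        report["stages"].append(
            {"stage": stage_name, "n_records": len(metrics),
             "mean_mae": float(metrics["mae"].mean()),
             "mean_rmse": float(metrics["rmse"].mean()),
             "mean_kl": float(metrics["kl_divergence"].mean())}
        )

        stage_name = "compare"
        comparison: dict | None = None
        if metrics["genotype"].nunique() >= 2:
            records = G.metric_records(metrics)
            records.to_csv(outdir / "metric_records.csv", index=False)
            table = G.compare_groups(
                records, B=cfg.bootstrap_B, alpha=cfg.bootstrap_alpha,
                seed=cfg.seed & 0x7FFFFFFF,
            )
            table.to_csv(outdir / "comparison.csv", index=False)
            comparison = table.to_dict(orient="records")
        report["stages"].append({"stage": stage_name, "comparison": comparison})
    except Exception as exc:
        # partial outputs stay on disk for debugging
        report["failed_stage"] = stage_name
        report["error"] = str(exc)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc

    report["metrics_summary"] = {
        "per_genotype_mae": metrics.groupby("genotype")["mae"].mean().to_dict(),
        "per_genotype_dv_mae": metrics.groupby("genotype")["dv_mae"].mean().to_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _versions() -> dict:
    import xgboost

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "xgboost": xgboost.__version__,
    }
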