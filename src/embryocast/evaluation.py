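"""Scoring predicted against actual per-grid count matrices.

Three whole-grid metrics — rmse, mae and the Kullback–Leibler divergence of
the (smoothed, normalized) DV marginal profiles — plus the axis-marginal maes
used for genotype comparisons: ap_mae and dv_mae between the marginal count
profiles along each axis, and their average mean_mae. Marginal profiles are
per-row (DV) or per-column (AP) means of the count matrix, i.e. the average
number of active nuclei per grid cell at that axis position.

The module also hosts the two experiment harnesses: the grid-size sweep
(re-running featurization, training and evaluation at several grid side
lengths) and the feature-ablation sweep (cross-validated mae per named feature
subset on identical folds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as F
from . import model as M
from .features import GridSpec, SupervisedDataset
from .types import FrameTable, stage_index

#: Additive smoothing applied to both profiles before normalization in the KL
#: computation; keeps empty bins finite with negligible bias.
KL_EPSILON = 1e-9


def _check_shapes(pred: np.ndarray, actual: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    return pred, actual


def grid_errors(pred: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """(rmse, mae) over all grid cells."""
    pred, actual = _check_shapes(pred, actual)
    err = pred - actual
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return rmse, mae


def marginal_profile(counts: np.ndarray, axis: str) -> np.ndarray:
    """Average count per grid cell along one body axis.

    DV profile = per-row mean across columns (length n_rows); AP profile =
    per-column mean across rows (length n_cols).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    axis = axis.upper()
    if axis == "DV":
        return counts.mean(axis=1)
    if axis == "AP":
        return counts.mean(axis=0)
    raise ValueError(f"axis must be 'AP' or 'DV', got {axis!r}")


def kl_divergence(
    p_actual: np.ndarray, q_pred: np.ndarray, epsilon: float = KL_EPSILON
) -> float:
    """KL(actual ‖ predicted) in nats between two non-negative profiles.

    Both profiles are shifted by ``epsilon`` and normalized to sum 1 before
    computing sum p ln(p/q); the result is invariant to rescaling either
    profile by a positive constant (up to the epsilon smoothing).
    """
    p = np.asarray(p_actual, dtype=float)
    q = np.asarray(q_pred, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile shape mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("profiles must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    # normalize first so the smoothing is scale-invariant, then re-normalize
    p = p / p.sum() if p.sum() > 0 else np.full_like(p, 1.0 / len(p))
    q = q / q.sum() if q.sum() > 0 else np.full_like(q, 1.0 / len(q))
    p = (p + epsilon) / (p + epsilon).sum()
    q = (q + epsilon) / (q + epsilon).sum()
    return float(np.sum(p * np.log(p / q)))


def combine_axis_maes(ap_mae: float, dv_mae: float) -> float:
    """mean mae = arithmetic mean of the two axis maes."""
    return (ap_mae + dv_mae) / 2.0


def axis_maes(pred: np.ndarray, actual: np.ndarray) -> tuple[float, float, float]:
    """(ap_mae, dv_mae, mean_mae) between marginal count profiles."""
    pred, actual = _check_shapes(pred, actual)
    ap = float(np.mean(np.abs(
        marginal_profile(pred, "AP") - marginal_profile(actual, "AP"))))
    dv = float(np.mean(np.abs(
        marginal_profile(pred, "DV") - marginal_profile(actual, "DV"))))
    return ap, dv, combine_axis_maes(ap, dv)


@dataclass
class EvalMetrics:
    """All scores for one predicted (video, stage) grid."""

    video_id: str
    stage: str
    genotype: str
    rmse: float
    mae: float
    kl_divergence: float
    ap_mae: float
    dv_mae: float
    mean_mae: float


def evaluate_prediction(
    pred: np.ndarray,
    actual: np.ndarray,
    *,
    video_id: str = "",
    stage: str = "NC14A",
    genotype: str = "sogD",
    kl_axis: str = "DV",
    epsilon: float = KL_EPSILON,
) -> EvalMetrics:
    """Full metric set for one prediction; KL is taken on the DV marginal by
    default (``kl_axis="full"`` uses the whole grid distribution instead)."""
    rmse, mae = grid_errors(pred, actual)
    if kl_axis.lower() == "full":
        kl = kl_divergence(np.asarray(actual, float).ravel(),
                           np.asarray(pred, float).ravel(), epsilon)
    else:
        kl = kl_divergence(
            marginal_profile(actual, kl_axis), marginal_profile(pred, kl_axis), epsilon
        )
    ap, dv, mean = axis_maes(pred, actual)
    return EvalMetrics(video_id, stage, genotype, rmse, mae, kl, ap, dv, mean)


def metrics_table(metrics: Sequence[EvalMetrics]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in metrics])


# ---------------------------------------------------------------------------
# Held-out evaluation of a trained model over a video's stage chain


def evaluate_video(
    model: M.TrainedModel,
    stage_matrix: pd.DataFrame,
    video_id: str,
    grid: GridSpec,
    *,
    ripley_sentinel: float = 0.0,
    kl_axis: str = "DV",
) -> list[EvalMetrics]:
    """Score next-stage predictions for every consecutive stage pair of one
    video, against the actual stage-averaged counts."""
    sub = stage_matrix[stage_matrix["video_id"] == video_id]
    if sub.empty:
        raise KeyError(f"video {video_id!r} not present in the stage matrix")
    genotype = sub["genotype"].iloc[0]
    stages = sorted(sub["stage"].unique(), key=stage_index)
    out: list[EvalMetrics] = []
    for prev, cur in zip(stages[:-1], stages[1:]):
        feats = sub[sub["stage"] == prev].copy()
        feats["ripley_k"] = feats["ripley_k"].fillna(ripley_sentinel)
        pred = M.predict(model, feats, grid)
        actual = F.actual_counts_matrix(stage_matrix, video_id, cur, grid)
        out.append(
            evaluate_prediction(
                pred, actual, video_id=video_id, stage=cur, genotype=genotype,
                kl_axis=kl_axis,
            )
        )
    return out


def leave_one_video_out(
    stage_matrix: pd.DataFrame,
    grid: GridSpec,
    config: M.ModelConfig,
    *,
    kl_axis: str = "DV",
) -> pd.DataFrame:
    """Per-(video, stage) metrics where each video is scored by a model
    trained on the remaining videos of the same genotype."""
    records: list[EvalMetrics] = []
    for genotype, sub in stage_matrix.groupby("genotype", sort=False):
        videos = list(sub["video_id"].unique())
        if len(videos) < 2:
            raise ValueError(
                f"genotype {genotype!r} needs >= 2 videos for held-out evaluation"
            )
        for held_out in videos:
            train_matrix = sub[sub["video_id"] != held_out]
            ds = F.build_supervised(train_matrix, grid)
            model = M.train(ds, config)
            records.extend(
                evaluate_video(model, sub, held_out, grid, kl_axis=kl_axis)
            )
    return metrics_table(records)


# ---------------------------------------------------------------------------
# Sweeps


def grid_size_sweep(
    frames: Sequence[FrameTable],
    sizes: Sequence[float] = F.STANDARD_GRID_SIZES,
    config: M.ModelConfig | None = None,
    *,
    test_videos: Sequence[str] | None = None,
    ripley_correction: str = "none",
    kl_axis: str = "DV",
) -> pd.DataFrame:
    """Re-run featurize → train → evaluate at each grid size.

    Training uses every video not in ``test_videos`` (default: the last video
    of the collection is held out); the reported rmse/mae/kl per size are the
    means over all held-out (video, stage) predictions. Returns one row per
    grid size.
    """
    config = config or M.ModelConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    width = frames[0].image_width
    height = frames[0].image_height
    all_videos = list(dict.fromkeys(f.video_id for f in frames))
    if test_videos is None:
        test_videos = [all_videos[-1]]
    test_videos = list(test_videos)
    train_videos = [v for v in all_videos if v not in test_videos]
    if not train_videos:
        raise ValueError("no training videos left after holding out test videos")

    rows = []
    for g in sizes:
        grid = F.make_grid(width, height, g)
        ripley = F.default_ripley_config(grid, correction=ripley_correction)
        feats = F.featurize_series(frames, grid, ripley)
        stage_matrix = F.stage_aggregate(feats)
        train_ds = F.build_supervised(
            stage_matrix[stage_matrix["video_id"].isin(train_videos)], grid
        )
        model = M.train(train_ds, config)
        metrics: list[EvalMetrics] = []
        for v in test_videos:
            metrics.extend(
                evaluate_video(model, stage_matrix, v, grid, kl_axis=kl_axis)
            )
        tbl = metrics_table(metrics)
        rows.append(
            {
                "grid_size": float(g),
                "n_rows": grid.n_rows,
                "n_cols": grid.n_cols,
                "rmse": float(tbl["rmse"].mean()),
                "mae": float(tbl["mae"].mean()),
                "kl_divergence": float(tbl["kl_divergence"].mean()),
            }
        )
    return pd.DataFrame(rows)


def ablation_sweep(
    dataset: SupervisedDataset,
    feature_sets: Mapping[str, Sequence[str]] | None = None,
    config: M.ModelConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated mae per named feature subset, on identical folds."""
    config = config or M.ModelConfig()
    if feature_sets is None:
        feature_sets = F.ablation_feature_sets()
    folds = M.fold_assignments(dataset, config.k_folds, config.seed)
    rows = []
    for name, feats in feature_sets.items():
        unknown = set(feats) - set(dataset.frame.columns)
        if unknown:
            raise KeyError(f"unknown features {sorted(unknown)} in set {name!r}")
        cfg = M.ModelConfig(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            seed=config.seed,
            k_folds=config.k_folds,
            features=tuple(feats),
        )
        cv_mae, per_fold = M.kfold_mae(dataset, cfg, folds=folds)
        rows.append({"feature_set": name, "cv_mae": cv_mae,
                     "per_fold": json.dumps(per_fold)})
    return pd.DataFrame(rows)


def plot_dv_profiles(
    actual: np.ndarray,
    pred: np.ndarray,
    path,
    title: str = "",
) -> None:
    """Overlay actual (solid red) and predicted (dashed blue) DV profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = marginal_profile(actual, "DV")
    p = marginal_profile(pred, "DV")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(len(a)), a, "-", color="crimson", label="actual")
    ax.plot(np.arange(len(p)), p, "--", color="royalblue", label="predicted")
    ax.set_xlabel("grid index along DV")
    ax.set_ylabel("mean active nuclei per grid")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
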