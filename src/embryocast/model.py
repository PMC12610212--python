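"""Gradient-boosted regression of next-stage per-grid active counts.

A single XGBoost regressor maps the stage t-1 feature vector of each grid cell
to the stage-t stage-averaged active count in that cell. Training pools all
stage pairs and videos in the supervised dataset; evaluation is done at the
video level (held-out movies), and K-fold cross-validation groups rows by
video whenever enough videos exist so that no movie straddles a fold's
train/test boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, GridSpec, SupervisedDataset


@dataclass(frozen=True)
class ModelConfig:
    """Booster hyperparameters and the evaluation protocol knobs.

    Defaults (300 trees, depth 4, learning rate 0.1) are modest settings for
    tabular count regression with a handful of features; all are fixed together
    with the seed for reproducibility. ``features`` names the columns used for
    training — the handle the ablation harness turns.
    """

    n_estimators: int = 300
    max_depth: int = 4
    learning_rate: float = 0.1
    seed: int = 0
    k_folds: int = 5
    features: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.features:
            raise ValueError("feature subset must be non-empty")


class _BoosterPredictor:
    """Prediction-only wrapper around a raw xgboost Booster (used after
    loading a persisted model)."""

    def __init__(self, booster) -> None:
        self._booster = booster

    def predict(self, X) -> np.ndarray:
        import xgboost

        dmat = xgboost.DMatrix(
            np.asarray(X, dtype=float),
            feature_names=list(self._booster.feature_names or []) or None,
        )
        return self._booster.predict(dmat)

    def get_booster(self):
        return self._booster


@dataclass
class TrainedModel:
    """A fitted booster plus the metadata needed to apply it safely."""

    booster: object  # xgboost.XGBRegressor or _BoosterPredictor
    feature_names: tuple[str, ...]
    config: ModelConfig
    data_fingerprint: str

    def save(self, path: str | Path) -> None:
        """Persist as <path>.json (booster) + <path>.meta.json (self-description)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.get_booster().save_model(str(path.with_suffix(".json")))
        meta = {
            "feature_names": list(self.feature_names),
            "config": asdict(self.config),
            "data_fingerprint": self.data_fingerprint,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        import xgboost

        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        booster = xgboost.Booster()
        booster.load_model(str(path.with_suffix(".json")))
        cfg = dict(meta["config"])
        cfg["features"] = tuple(cfg["features"])
        return cls(
            booster=_BoosterPredictor(booster),
            feature_names=tuple(meta["feature_names"]),
            config=ModelConfig(**cfg),
            data_fingerprint=meta["data_fingerprint"],
        )


def _fingerprint(X: pd.DataFrame, y: pd.Series) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(dtype=float)).tobytes())
    h.update(np.ascontiguousarray(y.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


def _make_regressor(config: ModelConfig):
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        objective="reg:squarederror",
        verbosity=0,
    )


def train(dataset: SupervisedDataset, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the booster on a supervised dataset (deterministic for fixed seed)."""
    config = config or ModelConfig()
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    unknown = set(config.features) - set(dataset.frame.columns)
    if unknown:
        raise KeyError(f"unknown feature names {sorted(unknown)}")
    X = dataset.frame[list(config.features)]
    y = dataset.y
    reg = _make_regressor(config)
    reg.fit(X, y)
    return TrainedModel(
        booster=reg,
        feature_names=tuple(config.features),
        config=config,
        data_fingerprint=_fingerprint(X, y),
    )


def predict(
    model: TrainedModel,
    features: pd.DataFrame,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Predicted per-cell counts for one stage's feature rows.

    ``features`` must contain the training feature columns plus ``row``/``col``
    cell indices. Predictions are clipped below at zero (counts) but not
    rounded — targets are stage averages and real-valued. Returns the
    (n_rows, n_cols) matrix when a grid is given (or row/col extents define
    it), otherwise the flat prediction vector aligned with the input rows.
    """
    missing = set(model.feature_names) - set(features.columns)
    if missing:
        raise KeyError(f"feature columns missing at predict time: {sorted(missing)}")
    X = features[list(model.feature_names)]
    yhat = np.clip(model.booster.predict(X), 0.0, None)
    if grid is None:
        return yhat
    if not {"row", "col"}.issubset(features.columns):
        raise KeyError("grid reshaping requires 'row' and 'col' columns")
    mat = np.zeros(grid.shape)
    mat[features["row"].to_numpy(), features["col"].to_numpy()] = yhat
    return mat


# ---------------------------------------------------------------------------
# Cross-validation


def fold_assignments(
    dataset: SupervisedDataset, k_folds: int, seed: int
) -> np.ndarray:
    """Seed-deterministic fold ids, one per dataset row.

    Folds are grouped so no group straddles train/test: by video when at least
    ``k_folds`` videos exist, else by (video, stage_to) pair when enough pairs
    exist, else by plain rows.
    """
    n = len(dataset)
    if k_folds > n:
        raise ValueError(f"k_folds={k_folds} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    frame = dataset.frame
    videos = frame["video_id"].unique()
    if len(videos) >= k_folds:
        group_key = frame["video_id"]
        groups = videos
    else:
        pairs = frame[["video_id", "stage_to"]].astype(str).agg("|".join, axis=1)
        if pairs.nunique() >= k_folds:
            group_key = pairs
            groups = pairs.unique()
        else:
            group_key = pd.Series(np.arange(n), index=frame.index).astype(str)
            groups = group_key.unique()
    groups = np.array(sorted(groups))
    rng.shuffle(groups)
    fold_of_group = {g: i % k_folds for i, g in enumerate(groups)}
    return group_key.map(fold_of_group).to_numpy()


def kfold_mae(
    dataset: SupervisedDataset,
    config: ModelConfig | None = None,
    folds: np.ndarray | None = None,
) -> tuple[float, list[float]]:
    """Mean held-out mae over K folds (plus the per-fold values).

    Passing precomputed ``folds`` lets sweeps reuse identical splits across
    feature subsets.
    """
    config = config or ModelConfig()
    if len(dataset) == 0:
        raise ValueError("cannot cross-validate an empty dataset")
    if folds is None:
        folds = fold_assignments(dataset, config.k_folds, config.seed)
    per_fold: list[float] = []
    for fold in range(config.k_folds):
        test = folds == fold
        if not test.any() or test.all():
            continue
        train_ds = SupervisedDataset(
            dataset.frame.loc[~test].reset_index(drop=True),
            dataset.feature_names,
            dataset.grid,
        )
        model = train(train_ds, config)
        yhat = predict(model, dataset.frame.loc[test])
        err = np.abs(yhat - dataset.frame.loc[test, "y"].to_numpy())
        per_fold.append(float(err.mean()))
    if not per_fold:
        raise ValueError("no usable folds (all rows in one fold?)")
    return float(np.mean(per_fold)), per_fold


# ---------------------------------------------------------------------------
# Reference baselines


def persistence_mae(dataset: SupervisedDataset) -> float:
    """mae of predicting the previous stage's count unchanged (y_hat = n)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    return float(np.abs(dataset.frame["n"] - dataset.frame["y"]).mean())


def global_mean_mae(
    train_ds: SupervisedDataset, test_ds: SupervisedDataset
) -> float:
    """mae of predicting the training-set mean target everywhere."""
    if len(train_ds) == 0 or len(test_ds) == 0:
        raise ValueError("empty dataset")
    mean_y = float(train_ds.y.mean())
    return float(np.abs(test_ds.y.to_numpy() - mean_y).mean())
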