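"""Spatial featurization: grid counts, axis moments, Ripley's K, stage
averaging, and the one-stage-shifted supervised dataset.

The feature set per (frame, grid cell) is

* ``n`` — the number of active nuclei whose centroid falls in the cell,
* ``ripley_K`` — Ripley's K evaluated on the active points inside the cell,
  with the cell itself as the observation window,
* ``m1_ap``/``m1_dv`` and ``m2_ap``/``m2_dv`` — frame-global first moments and
  second central moments of the active positions along each body axis,
  attached identically to every cell of the frame.

Ripley's K for a point set of size n in a window of area A is

    K(r) = A / (n (n - 1)) * sum_i sum_{j != i} 1(d_ij <= r) / e_ij

over ordered pairs, where d_ij is Euclidean distance and e_ij an edge-
correction weight (1 when no correction is applied; the translation correction
uses e_ij = (W - |dx|)(H - |dy|) / (W H) for a W×H window). Under complete
spatial randomness E[K(r)] = pi r^2.

Features are averaged per (video, stage, cell), then paired one stage ahead:
the supervised dataset maps stage t-1 features to the stage-t per-cell count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import FrameTable, stage_index

logger = logging.getLogger(__name__)

#: Feature columns produced per (frame, cell), in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "n",
    "m1_ap",
    "m1_dv",
    "m2_ap",
    "m2_dv",
    "ripley_k",
)

#: The grid side lengths (pixels) used in the grid-size sweep.
STANDARD_GRID_SIZES: tuple[float, ...] = (250.0, 125.0, 62.5, 31.25)


class RipleyUndefinedError(ValueError):
    """Ripley's K needs at least two points (the formula divides by n(n-1))."""


# ---------------------------------------------------------------------------
# Grid geometry


@dataclass(frozen=True)
class GridSpec:
    """Square tiling of the image into half-open cells [k·g, (k+1)·g).

    The last row/column may be partial when g does not divide the image
    dimensions. Every in-bounds point maps to exactly one cell; a point on a
    cell boundary belongs to the higher-index cell.
    """

    image_width: float
    image_height: float
    grid_size_g: float

    @property
    def n_cols(self) -> int:
        return int(math.ceil(self.image_width / self.grid_size_g))

    @property
    def n_rows(self) -> int:
        return int(math.ceil(self.image_height / self.grid_size_g))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of points; raises on out-of-bounds input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if ((x < 0) | (x >= self.image_width) | (y < 0) | (y >= self.image_height)).any():
            raise ValueError("point outside the grid bounds")
        col = np.floor(x / self.grid_size_g).astype(int)
        row = np.floor(y / self.grid_size_g).astype(int)
        return row, col


def make_grid(image_width: float, image_height: float, grid_size_g: float) -> GridSpec:
    """Validated :class:`GridSpec` constructor."""
    if image_width <= 0 or image_height <= 0:
        raise ValueError("image dimensions must be positive")
    if grid_size_g <= 0:
        raise ValueError(f"grid size must be positive, got {grid_size_g}")
    if grid_size_g > min(image_width, image_height):
        raise ValueError(
            f"grid size {grid_size_g} exceeds the smaller image dimension "
            f"{min(image_width, image_height)}"
        )
    return GridSpec(float(image_width), float(image_height), float(grid_size_g))


def grid_counts(
    frame: FrameTable, grid: GridSpec, active_only: bool = True
) -> np.ndarray:
    """Per-cell nucleus counts (integer-valued float matrix, rows = DV bins).

    The matrix sums to the number of (active) nuclei in the frame.
    """
    nuclei = frame.nuclei
    if active_only:
        nuclei = nuclei.loc[nuclei["active"]]
    counts = np.zeros(grid.shape, dtype=float)
    if len(nuclei):
        row, col = grid.cell_of(nuclei["x_ap"].to_numpy(), nuclei["y_dv"].to_numpy())
        np.add.at(counts, (row, col), 1.0)
    return counts


# ---------------------------------------------------------------------------
# Moments and Ripley's K


def axis_moments(frame: FrameTable, axis: str) -> tuple[float, float]:
    """First moment and second central moment of active positions on an axis.

    ``axis`` is ``"AP"`` (x) or ``"DV"`` (y). With zero active nuclei the
    moments are undefined and returned as NaN with a warning.
    """
    col = {"AP": "x_ap", "DV": "y_dv"}.get(axis.upper())
    if col is None:
        raise ValueError(f"axis must be 'AP' or 'DV', got {axis!r}")
    coords = frame.active_positions()[col].to_numpy()
    if coords.size == 0:
        warnings.warn(
            f"frame {frame.video_id}/{frame.frame_id} has no active nuclei; "
            f"{axis} moments undefined",
            stacklevel=2,
        )
        return (float("nan"), float("nan"))
    m1 = float(np.mean(coords))
    m2 = float(np.mean((coords - m1) ** 2))
    return m1, m2


@dataclass(frozen=True)
class RipleyConfig:
    """Observation window and radius for Ripley's K.

    ``correction="none"`` sets every pair weight e_ij = 1; ``"translation"``
    applies the translation edge correction for a rectangular window.
    """

    radius_r: float
    window_width: float
    window_height: float
    correction: str = "none"

    @property
    def window_area_A(self) -> float:
        return self.window_width * self.window_height

    def __post_init__(self) -> None:
        if self.radius_r <= 0:
            raise ValueError("radius_r must be positive")
        if self.window_width <= 0 or self.window_height <= 0:
            raise ValueError("window dimensions must be positive")
        if self.correction not in ("none", "translation"):
            raise ValueError(
                f"correction must be 'none' or 'translation', got {self.correction!r}"
            )


def ripley_k(points: np.ndarray, config: RipleyConfig) -> float:
    """Ripley's K at one radius for points in a rectangular window.

    ``points`` is (n, 2) with columns (x, y) in window coordinates. Pairs are
    found with a KD-tree rather than the O(n²) double loop; the two agree to
    floating tolerance. Fewer than two points raise
    :class:`RipleyUndefinedError` — callers decide on a sentinel.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        raise RipleyUndefinedError(
            f"Ripley's K needs >= 2 points, got {n}"
        )
    tree = cKDTree(pts)
    pairs = tree.query_pairs(config.radius_r, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    if config.correction == "none":
        weighted = float(len(pairs))  # e_ij = 1 for every pair
    else:
        d = np.abs(pts[pairs[:, 0]] - pts[pairs[:, 1]])
        w, h = config.window_width, config.window_height
        e = (w - d[:, 0]) * (h - d[:, 1]) / (w * h)
        weighted = float(np.sum(1.0 / e))
    # query_pairs returns unordered pairs; the sum runs over ordered pairs.
    return config.window_area_A / (n * (n - 1)) * 2.0 * weighted


# ---------------------------------------------------------------------------
# Per-frame feature rows


def default_ripley_config(grid: GridSpec, correction: str = "none") -> RipleyConfig:
    """Per-cell window with radius g/2 — one constant radius per grid size."""
    g = grid.grid_size_g
    return RipleyConfig(radius_r=g / 2.0, window_width=g, window_height=g,
                        correction=correction)


def frame_features(
    frame: FrameTable,
    grid: GridSpec,
    ripley: RipleyConfig | None = None,
) -> pd.DataFrame:
    """One feature row per grid cell of one frame.

    ``n`` and ``ripley_k`` are local (computed on the cell's active points,
    window = the cell); the axis moments are frame-global and repeated on
    every row. Cells with fewer than two points get ``ripley_k = NaN`` (the
    undefined case), resolved to a sentinel when the supervised dataset is
    assembled.
    """
    if ripley is None:
        ripley = default_ripley_config(grid)
    counts = grid_counts(frame, grid, active_only=True)
    m1_ap, m2_ap = _moments_quiet(frame, "AP")
    m1_dv, m2_dv = _moments_quiet(frame, "DV")

    n_rows, n_cols = grid.shape
    k_matrix = np.full(grid.shape, np.nan)
    active = frame.active_positions()
    if len(active) >= 2:
        x = active["x_ap"].to_numpy()
        y = active["y_dv"].to_numpy()
        row, col = grid.cell_of(x, y)
        cell_id = row * n_cols + col
        order = np.argsort(cell_id, kind="stable")
        cid_sorted = cell_id[order]
        boundaries = np.flatnonzero(np.diff(cid_sorted)) + 1
        g = grid.grid_size_g
        for chunk in np.split(order, boundaries):
            if len(chunk) < 2:
                continue
            r, c = row[chunk[0]], col[chunk[0]]
            local = np.column_stack((x[chunk] - c * g, y[chunk] - r * g))
            k_matrix[r, c] = ripley_k(local, ripley)

    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return pd.DataFrame(
        {
            "video_id": frame.video_id,
            "frame_id": frame.frame_id,
            "stage": frame.stage,
            "genotype": frame.genotype,
            "row": rows.ravel(),
            "col": cols.ravel(),
            "n": counts.ravel(),
            "m1_ap": m1_ap,
            "m1_dv": m1_dv,
            "m2_ap": m2_ap,
            "m2_dv": m2_dv,
            "ripley_k": k_matrix.ravel(),
        }
    )


def _moments_quiet(frame: FrameTable, axis: str) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return axis_moments(frame, axis)


def featurize_series(
    frames: Iterable[FrameTable],
    grid: GridSpec,
    ripley: RipleyConfig | None = None,
) -> pd.DataFrame:
    """Concatenate :func:`frame_features` over a collection of frames."""
    parts = [frame_features(f, grid, ripley) for f in frames]
    if not parts:
        raise ValueError("no frames to featurize")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage averaging and the one-stage shift


def stage_aggregate(feature_rows: pd.DataFrame) -> pd.DataFrame:
    """Average feature rows per (video, genotype, stage, cell).

    Every feature (including the count) is the arithmetic mean over that
    stage's frames. NaN Ripley values (cells with < 2 points in a frame) are
    excluded from the mean; a cell undefined in every frame stays NaN here and
    receives the sentinel downstream.
    """
    required = {"video_id", "stage", "row", "col", *FEATURE_NAMES}
    missing = required - set(feature_rows.columns)
    if missing:
        raise ValueError(f"feature rows missing columns {sorted(missing)}")
    keys = ["video_id", "genotype", "stage", "row", "col"]
    agg = (
        feature_rows.groupby(keys, sort=False, dropna=False)[list(FEATURE_NAMES)]
        .mean()  # pandas mean skips NaN per cell
        .reset_index()
    )
    agg["stage_rank"] = agg["stage"].map(stage_index)
    return agg.sort_values(keys[:3] + ["row", "col"]).reset_index(drop=True)


@dataclass
class SupervisedDataset:
    """Stage-shifted supervised pairs: X = features at stage t-1 per cell,
    y = stage-averaged active count at stage t in the same (video, cell)."""

    frame: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    grid: GridSpec | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    @property
    def y(self) -> pd.Series:
        return self.frame["y"]

    def subset_videos(self, videos: Sequence[str]) -> "SupervisedDataset":
        keep = self.frame["video_id"].isin(list(videos))
        return SupervisedDataset(
            self.frame.loc[keep].reset_index(drop=True), self.feature_names, self.grid
        )


def build_supervised(
    stage_matrix: pd.DataFrame,
    grid: GridSpec | None = None,
    ripley_sentinel: float = 0.0,
) -> SupervisedDataset:
    """Pair consecutive stages of each video into supervised rows.

    For each adjacent stage pair (t-1, t) present in a video and each grid
    cell: X = stage-averaged features at t-1, y = stage-averaged count at t.
    The earliest stage contributes only features, the latest only targets.
    Ripley NaNs are replaced by ``ripley_sentinel`` (with the original
    definedness kept in ``ripley_defined``). A single-stage video contributes
    nothing (warned).
    """
    rows = []
    for vid, sub in stage_matrix.groupby("video_id", sort=False):
        stages = sorted(sub["stage"].unique(), key=stage_index)
        if len(stages) < 2:
            warnings.warn(
                f"video {vid!r} has a single stage; no supervised pairs",
                stacklevel=2,
            )
            continue
        by_stage = {s: g.set_index(["row", "col"]) for s, g in sub.groupby("stage")}
        for prev, cur in zip(stages[:-1], stages[1:]):
            xdf = by_stage[prev]
            ydf = by_stage[cur]
            joined = xdf[list(FEATURE_NAMES)].join(
                ydf["n"].rename("y"), how="inner"
            )
            joined = joined.reset_index()
            joined.insert(0, "video_id", vid)
            joined.insert(1, "genotype", xdf["genotype"].iloc[0])
            joined.insert(2, "stage_from", prev)
            joined.insert(3, "stage_to", cur)
            rows.append(joined)
    if not rows:
        warnings.warn("no supervised pairs could be built", stacklevel=2)
        frame = pd.DataFrame(
            columns=["video_id", "genotype", "stage_from", "stage_to", "row", "col",
                     *FEATURE_NAMES, "y", "ripley_defined"]
        )
        return SupervisedDataset(frame, FEATURE_NAMES, grid)
    frame = pd.concat(rows, ignore_index=True)
    frame["ripley_defined"] = frame["ripley_k"].notna()
    n_missing = int((~frame["ripley_defined"]).sum())
    if n_missing:
        logger.info(
            "ripley_k undefined for %d/%d supervised rows; sentinel %.3g applied",
            n_missing, len(frame), ripley_sentinel,
        )
    frame["ripley_k"] = frame["ripley_k"].fillna(ripley_sentinel)
    return SupervisedDataset(frame, FEATURE_NAMES, grid)


def actual_counts_matrix(
    stage_matrix: pd.DataFrame, video_id: str, stage: str, grid: GridSpec
) -> np.ndarray:
    """Stage-averaged per-cell count matrix for one (video, stage)."""
    sub = stage_matrix[
        (stage_matrix["video_id"] == video_id) & (stage_matrix["stage"] == stage)
    ]
    if sub.empty:
        raise KeyError(f"no rows for video {video_id!r} stage {stage!r}")
    mat = np.zeros(grid.shape)
    mat[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["n"].to_numpy()
    return mat


def ablation_feature_sets() -> Mapping[str, tuple[str, ...]]:
    """The named feature subsets of the ablation study. "m2" denotes both
    axis second moments jointly."""
    return {
        "n, ripley_k": ("n", "ripley_k"),
        "m2, n, ripley_k": ("m2_ap", "m2_dv", "n", "ripley_k"),
        "m2, m1_ap, n, ripley_k": ("m2_ap", "m2_dv", "m1_ap", "n", "ripley_k"),
        "ripley_k": ("ripley_k",),
        "m2, m1_ap, m1_dv, ripley_k": ("m2_ap", "m2_dv", "m1_ap", "m1_dv", "ripley_k"),
    }
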