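"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import embryocast as ec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)


def ripley_oracle(points: np.ndarray, config: ec.RipleyConfig) -> float:
    """Direct double-loop evaluation of the K formula over ordered pairs."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    assert n >= 2
    total = 0.0
    w, h = config.window_width, config.window_height
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(pts[i] - pts[j])))
            if d <= config.radius_r:
                if config.correction == "none":
                    e = 1.0
                else:
                    dx, dy = np.abs(pts[i] - pts[j])
                    e = (w - dx) * (h - dy) / (w * h)
                total += 1.0 / e
    return config.window_area_A / (n * (n - 1)) * total


def loop_grid_counts(frame: ec.FrameTable, grid: ec.GridSpec) -> np.ndarray:
    """Per-point loop assignment of active nuclei to half-open grid cells."""
    counts = np.zeros(grid.shape)
    for rec in frame.nuclei.itertuples(index=False):
        if not rec.active:
            continue
        row = int(rec.y_dv // grid.grid_size_g)
        col = int(rec.x_ap // grid.grid_size_g)
        counts[row, col] += 1
    return counts


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_params() -> ec.SynthParams:
    """A quick-to-generate movie: 600×600 px, 120 nuclei, 2 frames/stage."""
    return ec.SynthParams(
        image_width=600,
        image_height=600,
        n_nuclei=120,
        nucleus_radius_px=10.0,
        frames_per_stage=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_series(small_params) -> list[ec.FrameTable]:
    return ec.generate_series(small_params)


@pytest.fixture(scope="session")
def small_grid(small_params) -> ec.GridSpec:
    return ec.make_grid(small_params.image_width, small_params.image_height, 75.0)


@pytest.fixture(scope="session")
def small_stage_matrix(small_series, small_grid) -> pd.DataFrame:
    feats = ec.featurize_series(small_series, small_grid)
    return ec.stage_aggregate(feats)


@pytest.fixture(scope="session")
def small_dataset(small_stage_matrix, small_grid) -> ec.SupervisedDataset:
    return ec.build_supervised(small_stage_matrix, small_grid)


@pytest.fixture(scope="session")
def multi_video_series(small_params) -> list[ec.FrameTable]:
    """Four wild-type movies from the same parameters (distinct substreams)."""
    frames: list[ec.FrameTable] = []
    for v in range(4):
        frames.extend(
            ec.generate_series(small_params, video_id=f"v{v}", video_index=v)
        )
    return frames
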