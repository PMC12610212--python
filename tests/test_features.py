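"""Grid geometry, moments, Ripley's K (against a double-loop oracle and its
CSR closed form), and the stage-shift dataset construction."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import embryocast as ec
from conftest import loop_grid_counts, ripley_oracle
from embryocast.features import (
    RipleyUndefinedError,
    STANDARD_GRID_SIZES,
    actual_counts_matrix,
    default_ripley_config,
)


class TestGrid:
    @pytest.mark.parametrize(
        "g, expected", [(250.0, (8, 8)), (125.0, (16, 16)), (62.5, (32, 32)),
                        (31.25, (64, 64))]
    )
    def test_cell_counts_for_2000px_image(self, g, expected):
        grid = ec.make_grid(2000, 2000, g)
        assert grid.shape == expected

    def test_boundary_point_goes_to_higher_cell(self):
        grid = ec.make_grid(100, 100, 25)
        row, col = grid.cell_of(np.array([25.0]), np.array([50.0]))
        assert (row[0], col[0]) == (2, 1)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ec.make_grid(100, 100, 0)
        with pytest.raises(ValueError):
            ec.make_grid(100, 100, 150)

    def test_partial_last_row(self):
        grid = ec.make_grid(110, 110, 25)
        assert grid.shape == (5, 5)

    @given(st.floats(0, 99.999), st.floats(0, 99.999))
    def test_every_point_maps_to_exactly_one_cell(self, x, y):
        grid = ec.make_grid(100, 100, 30)
        row, col = grid.cell_of(np.array([x]), np.array([y]))
        assert 0 <= row[0] < grid.n_rows and 0 <= col[0] < grid.n_cols

    def test_halving_g_quadruples_cells(self):
        coarse = ec.make_grid(2000, 2000, 125)
        fine = ec.make_grid(2000, 2000, 62.5)
        assert fine.n_rows * fine.n_cols == 4 * coarse.n_rows * coarse.n_cols


class TestGridCounts:
    def test_empty_frame_all_zero(self, small_params):
        f = ec.FrameTable("v0", 0, "NC13", "sogD", 600, 600)
        grid = ec.make_grid(600, 600, 75)
        assert ec.grid_counts(f, grid).sum() == 0

    def test_conservation(self, small_series, small_grid):
        for f in small_series:
            counts = ec.grid_counts(f, small_grid)
            assert counts.sum() == f.n_active
            total = ec.grid_counts(f, small_grid, active_only=False)
            assert total.sum() == len(f.nuclei)

    def test_matches_per_point_loop(self, small_series, small_grid):
        for f in small_series[:4]:
            np.testing.assert_array_equal(
                ec.grid_counts(f, small_grid), loop_grid_counts(f, small_grid)
            )


class TestAxisMoments:
    def _frame_at(self, coords_dv):
        nuclei = pd.DataFrame({
            "nucleus_id": np.arange(1, len(coords_dv) + 1),
            "x_ap": np.full(len(coords_dv), 10.0),
            "y_dv": np.asarray(coords_dv, dtype=float),
            "area_px": 100.0, "green_fraction": 1.0, "active": True,
        })
        return ec.FrameTable("v0", 0, "NC13", "sogD", 600, 600, nuclei)

    def test_single_point(self):
        m1, m2 = ec.axis_moments(self._frame_at([40.0]), "DV")
        assert (m1, m2) == (40.0, 0.0)

    def test_symmetric_pair(self):
        m1, m2 = ec.axis_moments(self._frame_at([0.0, 100.0]), "DV")
        assert (m1, m2) == (50.0, 2500.0)

    def test_matches_two_pass_computation(self):
        rng = np.random.default_rng(1)
        ys = rng.uniform(0, 599, 200)
        m1, m2 = ec.axis_moments(self._frame_at(ys), "DV")
        assert m1 == pytest.approx(ys.mean())
        assert m2 == pytest.approx(np.mean((ys - ys.mean()) ** 2))

    def test_zero_active_warns_and_is_nan(self, small_params):
        f = ec.FrameTable("v0", 0, "NC13", "sogD", 600, 600)
        with pytest.warns(UserWarning, match="no active"):
            m1, m2 = ec.axis_moments(f, "AP")
        assert math.isnan(m1) and math.isnan(m2)


class TestRipleyK:
    def test_two_points_hand_value(self):
        # A=100, n=2, one ordered-pair distance 3 <= r=5 counted twice
        cfg = ec.RipleyConfig(5.0, 10.0, 10.0, "none")
        pts = np.array([[1.0, 1.0], [4.0, 1.0]])
        assert ec.ripley_k(pts, cfg) == pytest.approx(100.0)

    def test_radius_below_min_distance_gives_zero(self):
        cfg = ec.RipleyConfig(0.5, 10.0, 10.0)
        pts = np.array([[1.0, 1.0], [4.0, 1.0], [8.0, 8.0]])
        assert ec.ripley_k(pts, cfg) == 0.0

    def test_fewer_than_two_points_undefined(self):
        cfg = ec.RipleyConfig(1.0, 10.0, 10.0)
        with pytest.raises(RipleyUndefinedError):
            ec.ripley_k(np.array([[1.0, 1.0]]), cfg)

    @pytest.mark.parametrize("correction", ["none", "translation"])
    def test_matches_double_loop_oracle(self, correction):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 200))
            pts = rng.uniform(0, 50, size=(n, 2))
            cfg = ec.RipleyConfig(float(rng.uniform(1, 25)), 50.0, 50.0, correction)
            assert ec.ripley_k(pts, cfg) == pytest.approx(
                ripley_oracle(pts, cfg), rel=1e-9
            )

    def test_csr_mean_matches_pi_r_squared(self):
        # E[K(r)] = pi r^2 under CSR with the translation correction
        cfg = ec.RipleyConfig(0.05, 1.0, 1.0, "translation")
        rng = np.random.default_rng(11)
        ks = [ec.ripley_k(rng.uniform(0, 1, size=(500, 2)), cfg) for _ in range(50)]
        assert np.mean(ks) == pytest.approx(math.pi * 0.05**2, rel=0.05)


class TestFrameFeatures:
    def test_row_count_is_grid_shape(self, small_series, small_grid):
        rows = ec.frame_features(small_series[0], small_grid)
        assert len(rows) == small_grid.n_rows * small_grid.n_cols

    def test_n_column_equals_grid_counts(self, small_series, small_grid):
        f = small_series[0]
        rows = ec.frame_features(f, small_grid)
        mat = rows.sort_values(["row", "col"])["n"].to_numpy().reshape(small_grid.shape)
        np.testing.assert_array_equal(mat, ec.grid_counts(f, small_grid))

    def test_local_activity_confined_to_one_cell(self):
        nuclei = pd.DataFrame({
            "nucleus_id": [1, 2, 3],
            "x_ap": [10.0, 12.0, 14.0],
            "y_dv": [10.0, 12.0, 14.0],
            "area_px": 100.0, "green_fraction": 1.0, "active": True,
        })
        f = ec.FrameTable("v0", 0, "NC13", "sogD", 100, 100, nuclei)
        grid = ec.make_grid(100, 100, 25)
        rows = ec.frame_features(f, grid)
        hot = rows[(rows["row"] == 0) & (rows["col"] == 0)]
        assert hot["n"].iloc[0] == 3
        assert not np.isnan(hot["ripley_k"].iloc[0])
        cold = rows[(rows["row"] != 0) | (rows["col"] != 0)]
        assert (cold["n"] == 0).all()
        assert cold["ripley_k"].isna().all()  # < 2 points: undefined

    def test_per_cell_ripley_matches_direct_call(self, small_series, small_grid):
        f = small_series[0]
        rows = ec.frame_features(f, small_grid)
        cfg = default_ripley_config(small_grid)
        g = small_grid.grid_size_g
        active = f.active_positions()
        r, c = small_grid.cell_of(active["x_ap"].to_numpy(), active["y_dv"].to_numpy())
        checked = 0
        for (ri, ci), grp in active.groupby([r, c]):
            if len(grp) < 2:
                continue
            local = np.column_stack(
                (grp["x_ap"] - ci * g, grp["y_dv"] - ri * g))
            expected = ec.ripley_k(local, cfg)
            got = rows[(rows["row"] == ri) & (rows["col"] == ci)]["ripley_k"].iloc[0]
            assert got == pytest.approx(expected)
            checked += 1
        assert checked > 0


class TestStageAggregate:
    def test_single_frame_stage_is_identity(self, small_grid):
        p = ec.SynthParams(image_width=600, image_height=600, n_nuclei=80,
                           nucleus_radius_px=10, frames_per_stage=1, seed=9)
        frames = ec.generate_series(p)
        feats = ec.featurize_series(frames, small_grid)
        agg = ec.stage_aggregate(feats)
        one = feats[feats["stage"] == "NC13"].sort_values(["row", "col"])
        agg_one = agg[agg["stage"] == "NC13"].sort_values(["row", "col"])
        np.testing.assert_allclose(agg_one["n"].to_numpy(), one["n"].to_numpy())

    def test_forced_arithmetic_mean(self, small_grid):
        rows = []
        for fid, count in ((0, 2.0), (1, 4.0)):
            rows.append({
                "video_id": "v0", "frame_id": fid, "stage": "NC13",
                "genotype": "sogD", "row": 0, "col": 0, "n": count,
                "m1_ap": 1.0, "m1_dv": 1.0, "m2_ap": 1.0, "m2_dv": 1.0,
                "ripley_k": np.nan,
            })
        agg = ec.stage_aggregate(pd.DataFrame(rows))
        assert agg["n"].iloc[0] == 3.0
        assert np.isnan(agg["ripley_k"].iloc[0])  # all-missing stays missing

    def test_nan_ripley_excluded_from_mean(self):
        rows = [
            {"video_id": "v0", "frame_id": 0, "stage": "NC13", "genotype": "sogD",
             "row": 0, "col": 0, "n": 1.0, "m1_ap": 0.0, "m1_dv": 0.0,
             "m2_ap": 0.0, "m2_dv": 0.0, "ripley_k": 8.0},
            {"video_id": "v0", "frame_id": 1, "stage": "NC13", "genotype": "sogD",
             "row": 0, "col": 0, "n": 1.0, "m1_ap": 0.0, "m1_dv": 0.0,
             "m2_ap": 0.0, "m2_dv": 0.0, "ripley_k": np.nan},
        ]
        agg = ec.stage_aggregate(pd.DataFrame(rows))
        assert agg["ripley_k"].iloc[0] == 8.0

    def test_permutation_invariance(self, small_series, small_grid):
        feats = ec.featurize_series(small_series, small_grid)
        shuffled = feats.sample(frac=1.0, random_state=0)
        a = ec.stage_aggregate(feats)
        b = ec.stage_aggregate(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestBuildSupervised:
    def test_five_stages_give_four_pairs(self, small_dataset, small_grid):
        pairs = small_dataset.frame[["stage_from", "stage_to"]].drop_duplicates()
        assert len(pairs) == 4
        n_cells = small_grid.n_rows * small_grid.n_cols
        assert len(small_dataset) == 4 * n_cells

    def test_two_stages_one_pair(self, small_grid):
        p = ec.SynthParams(image_width=600, image_height=600, n_nuclei=80,
                           nucleus_radius_px=10, frames_per_stage=1,
                           stages=("NC13", "NC14A"),
                           band_center_dv=0.5, band_sigma_dv=0.1, seed=5)
        feats = ec.featurize_series(ec.generate_series(p), small_grid)
        ds = ec.build_supervised(ec.stage_aggregate(feats), small_grid)
        assert len(ds) == small_grid.n_rows * small_grid.n_cols
        assert set(ds.frame["stage_to"]) == {"NC14A"}

    def test_y_equals_next_stage_counts(self, small_stage_matrix, small_dataset,
                                        small_grid):
        sub = small_dataset.frame[small_dataset.frame["stage_to"] == "NC14B"]
        expected = actual_counts_matrix(
            small_stage_matrix, sub["video_id"].iloc[0], "NC14B", small_grid)
        got = np.zeros(small_grid.shape)
        got[sub["row"], sub["col"]] = sub["y"]
        np.testing.assert_allclose(got, expected)

    def test_single_stage_video_warns_empty(self, small_grid):
        p = ec.SynthParams(image_width=600, image_height=600, n_nuclei=50,
                           nucleus_radius_px=10, frames_per_stage=1,
                           stages=("NC13",), band_center_dv=0.5,
                           band_sigma_dv=0.1, seed=6)
        feats = ec.featurize_series(ec.generate_series(p), small_grid)
        with pytest.warns(UserWarning, match="single stage"):
            ds = ec.build_supervised(ec.stage_aggregate(feats), small_grid)
        assert len(ds) == 0

    def test_ripley_sentinel_and_flag(self, small_dataset):
        frame = small_dataset.frame
        assert frame["ripley_k"].notna().all()
        assert (frame.loc[~frame["ripley_defined"], "ripley_k"] == 0.0).all()


def test_conservation_across_standard_grid_sizes():
    p = ec.SynthParams(image_width=2000, image_height=2000, n_nuclei=300,
                       nucleus_radius_px=18, frames_per_stage=1, seed=8)
    frames = ec.generate_series(p)
    for g in STANDARD_GRID_SIZES:
        grid = ec.make_grid(2000, 2000, g)
        for f in frames:
            assert ec.grid_counts(f, grid).sum() == f.n_active
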