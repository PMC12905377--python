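"""Trace quantification: normalization, window statistics, ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catrace.data import TimeGrid, TraceMatrix
from catrace.metrics import (first_lh_minute, group_mean_traces, heatmap_order,
                             inactive_fraction, normalize_df_f0, window_auc,
                             window_total_change, window_stats)
from catrace.simulate import generate_cohort


def _matrix(values, grid, labels=None):
    values = np.atleast_2d(values)
    n = values.shape[0]
    labels = labels if labels is not None else np.array(["HET"] * n)
    return TraceMatrix(values=values, labels=labels,
                       animal_id=np.array(["a1"] * n), grid=grid)


class TestNormalize:
    def test_constant_trace_normalizes_to_zero(self, small_grid):
        raw = np.full((3, small_grid.n_frames), 42.0)
        assert np.allclose(normalize_df_f0(raw, small_grid), 0.0)

    def test_single_frame_arithmetic(self, small_grid):
        raw = np.full((1, small_grid.n_frames), 100.0)
        raw[0, 150] = 150.0  # outside the basal window
        out = normalize_df_f0(raw, small_grid)
        assert out[0, 150] == pytest.approx(0.5)

    def test_matches_per_element_formula(self, small_grid):
        rng = np.random.default_rng(0)
        raw = rng.uniform(50, 150, size=(10, small_grid.n_frames))
        out = normalize_df_f0(raw, small_grid)
        for i in range(10):
            f0 = raw[i, :small_grid.lh_start].mean()
            assert np.allclose(out[i], (raw[i] - f0) / f0)

    @given(c=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        grid = TimeGrid(n_frames=50, rate=2.0, lh_start=20, lh_end=30)
        rng = np.random.default_rng(1)
        raw = rng.uniform(10, 20, size=(4, 50))
        assert np.allclose(normalize_df_f0(c * raw, grid),
                           normalize_df_f0(raw, grid))

    def test_degenerate_baseline_names_cell(self, small_grid):
        raw = np.full((2, small_grid.n_frames), 10.0)
        raw[1, :small_grid.lh_start] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_df_f0(raw, small_grid)


class TestWindowStats:
    def test_zero_trace_zero_everywhere(self, small_grid):
        tm = _matrix(np.zeros((2, small_grid.n_frames)), small_grid)
        for window in ("BASAL", "LH", "WASH"):
            assert (window_total_change(tm, window)["total_change"] == 0).all()
            assert (window_auc(tm, window)["auc"] == 0).all()

    def test_lh_indicator_trace(self, small_grid):
        v = np.zeros((1, small_grid.n_frames))
        lo, hi = small_grid.window_bounds("LH")
        v[0, lo:hi] = 1.0
        tm = _matrix(v, small_grid)
        assert window_total_change(tm, "LH")["total_change"][0] == pytest.approx(1.0)
        assert window_total_change(tm, "BASAL")["total_change"][0] == 0.0

    def test_constant_auc_closed_form(self, small_grid):
        v = np.full((1, small_grid.n_frames), 0.3)
        tm = _matrix(v, small_grid)
        lo, hi = small_grid.window_bounds("LH")
        expected = 0.3 * (hi - lo - 1) / small_grid.rate
        assert window_auc(tm, "LH")["auc"][0] == pytest.approx(expected)

    def test_triangle_pulse_auc_closed_form(self):
        grid = TimeGrid(n_frames=100, rate=2.0, lh_start=30, lh_end=60)
        k, h = 21, 0.8
        v = np.zeros((1, 100))
        v[0, 30:30 + k] = h * np.bartlett(k)
        tm = _matrix(v, grid)
        lo, hi = grid.window_bounds("LH")
        assert hi - lo > k  # pulse fully inside the window
        expected = 0.5 * h * (k - 1) / grid.rate
        assert window_auc(tm, "LH")["auc"][0] == pytest.approx(expected)

    def test_window_auc_additivity_with_boundary_trapezoids(self, small_grid):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, size=(3, small_grid.n_frames))
        tm = _matrix(v, small_grid)
        parts = sum(window_auc(tm, w)["auc"].to_numpy()
                    for w in ("BASAL", "LH", "WASH"))
        whole = np.trapezoid(v, dx=small_grid.dt, axis=1)
        # half-open windows omit the two boundary-crossing trapezoids
        for a in (small_grid.lh_start, small_grid.lh_end):
            parts = parts + 0.5 * (v[:, a - 1] + v[:, a]) * small_grid.dt
        assert np.allclose(parts, whole)

    def test_empty_window_rejected(self):
        grid = TimeGrid(n_frames=100, rate=2.0, lh_start=100, lh_end=100)
        tm = _matrix(np.zeros((1, 100)), grid)
        with pytest.raises(ValueError, match="empty"):
            window_total_change(tm, "LH")

    def test_responders_raise_lh_over_basal(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        het = tm.subset(tm.labels == "HET")  # 90% responders
        lh = window_total_change(het, "LH")["total_change"].to_numpy()
        basal = window_total_change(het, "BASAL")["total_change"].to_numpy()
        # >90% of responder cells, i.e. >~0.81 of all cells even if every
        # non-responder (10%) fails the comparison
        assert np.mean(lh > basal) >= 0.85


class TestGroupTraces:
    def test_single_cell_group(self, small_grid):
        v = np.random.default_rng(3).normal(size=(1, small_grid.n_frames))
        tm = _matrix(v, small_grid)
        gt, = group_mean_traces(tm)
        assert np.allclose(gt.mean, v[0])
        assert np.allclose(gt.sd, 0.0)
        assert gt.peak == pytest.approx(v[0].max())
        assert gt.peak_frame == int(np.argmax(v[0]))

    def test_peak_is_max_of_mean(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        for gt in group_mean_traces(tm):
            assert gt.peak == np.max(gt.mean)
            assert np.all(gt.sd >= 0)


class TestHeatmapOrder:
    def test_explicit_ordering(self, small_grid):
        lo, hi = small_grid.window_bounds("LH")
        v = np.zeros((3, small_grid.n_frames))
        v[0, lo:hi], v[1, lo:hi], v[2, lo:hi] = 0.1, 0.9, 0.5
        order = heatmap_order(_matrix(v, small_grid))
        assert order.tolist() == [1, 2, 0]

    def test_ties_keep_row_order(self, small_grid):
        v = np.ones((4, small_grid.n_frames))
        order = heatmap_order(_matrix(v, small_grid))
        assert order.tolist() == [0, 1, 2, 3]

    def test_is_permutation_with_nonincreasing_stats(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        order = heatmap_order(tm)
        assert sorted(order.tolist()) == list(range(tm.n_cells))
        stat = window_total_change(tm, "LH")["total_change"].to_numpy()
        assert np.all(np.diff(stat[order]) <= 1e-12)


class TestInactiveFraction:
    def test_all_zero_cohort_fully_inactive(self, small_grid):
        tm = _matrix(np.zeros((5, small_grid.n_frames)), small_grid)
        assert inactive_fraction(tm, "LH")["HET"] == 1.0

    def test_suprathreshold_cells_active(self, small_grid):
        v = np.full((5, small_grid.n_frames), 0.5)
        tm = _matrix(v, small_grid)
        assert inactive_fraction(tm, "LH")["HET"] == 0.0

    def test_explicit_window_bounds_checked(self, small_grid):
        tm = _matrix(np.zeros((2, small_grid.n_frames)), small_grid)
        with pytest.raises(ValueError):
            inactive_fraction(tm, (200, 200))

    def test_first_lh_minute_is_120_frames_at_2hz(self):
        grid = TimeGrid()
        assert first_lh_minute(grid) == (600, 720)


def test_window_stats_tidy_table(small_cohort_config):
    tm = generate_cohort(small_cohort_config)
    df = window_stats(tm)
    assert len(df) == 3 * tm.n_cells
    assert set(df["window"]) == {"BASAL", "LH", "WASH"}
    assert {"cell_id", "group", "total_change", "auc"} <= set(df.columns)
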