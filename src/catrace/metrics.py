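"""Windowed trace quantification: ΔF/F₀ normalization, per-window response
statistics, group mean ± SD traces, heatmap ordering, inactive-cell fractions.

Windows are the half-open frame ranges defined by the TimeGrid (BASAL =
[0, lh_start), LH = [lh_start, lh_end), WASH = [lh_end, n_frames)).  The
"total change" statistic is the per-frame mean ΔF/F₀ within a window, so
windows of unequal length (600-frame basal vs 360-frame application) are
directly comparable; the raw sum is carried alongside.  AUC is the
trapezoidal integral over the frames of the window with time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TimeGrid, TraceMatrix


@dataclass(frozen=True)
class GroupTrace:
    group: str
    mean: np.ndarray
    sd: np.ndarray
    peak: float
    peak_frame: int


def normalize_df_f0(raw: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """ΔF/F₀(t) = (F(t) − F₀) / F₀ with F₀ the cell's mean basal-window raw value."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != grid.n_frames:
        raise ValueError("raw must be cells × n_frames")
    b0, b1 = grid.window_bounds("BASAL")
    if b1 - b0 < 1:
        raise ValueError("basal window is empty")
    f0 = raw[:, b0:b1].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"degenerate baseline (F0 <= 0) for cell rows {bad.tolist()}")
    return (raw - f0[:, None]) / f0[:, None]


def _window_slice(traces: TraceMatrix, window: str) -> tuple[int, int]:
    start, end = traces.grid.window_bounds(window)
    if end - start < 1:
        raise ValueError(f"window {window!r} is empty on this grid")
    return start, end


def window_total_change(traces: TraceMatrix, window: str) -> pd.DataFrame:
    """Per-cell per-frame mean ΔF/F₀ (and raw sum) within a named window."""
    start, end = _window_slice(traces, window)
    seg = traces.values[:, start:end]
    return pd.DataFrame({
        "cell_id": traces.cell_id,
        "group": traces.labels,
        "window": window,
        "total_change": seg.mean(axis=1),
        "total_sum": seg.sum(axis=1),
    })


def window_auc(traces: TraceMatrix, window: str) -> pd.DataFrame:
    """Per-cell trapezoidal AUC (ΔF/F₀ · s) over frames [start, end) of a window."""
    start, end = _window_slice(traces, window)
    seg = traces.values[:, start:end]
    auc = np.trapezoid(seg, dx=traces.grid.dt, axis=1)
    return pd.DataFrame({
        "cell_id": traces.cell_id,
        "group": traces.labels,
        "window": window,
        "auc": auc,
    })


def window_stats(traces: TraceMatrix) -> pd.DataFrame:
    """Tidy table of total_change and AUC for all three windows."""
    frames = []
    for window in ("BASAL", "LH", "WASH"):
        tc = window_total_change(traces, window)
        tc["auc"] = window_auc(traces, window)["auc"]
        frames.append(tc)
    return pd.concat(frames, ignore_index=True)


def group_mean_traces(traces: TraceMatrix) -> list[GroupTrace]:
    """Frame-wise mean and SD per group, with the peak of the mean trace."""
    out = []
    for group in traces.group_names():
        sel = traces.values[traces.labels == group]
        if sel.shape[0] == 0:
            raise ValueError(f"group {group} is empty")
        mean = sel.mean(axis=0)
        sd = sel.std(axis=0, ddof=0)
        peak_frame = int(np.argmax(mean))
        out.append(GroupTrace(group=group, mean=mean, sd=sd,
                              peak=float(mean[peak_frame]), peak_frame=peak_frame))
    return out


def group_traces_frame(traces: TraceMatrix) -> pd.DataFrame:
    """Group mean ± SD traces as a tidy (group, frame, mean, sd) table."""
    rows = []
    for gt in group_mean_traces(traces):
        rows.append(pd.DataFrame({
            "group": gt.group,
            "frame": np.arange(gt.mean.size),
            "mean": gt.mean,
            "sd": gt.sd,
        }))
    return pd.concat(rows, ignore_index=True)


def heatmap_order(traces: TraceMatrix) -> np.ndarray:
    """Row permutation sorting cells by LH-window total_change, descending.

    Ties are broken by original row index ascending, so the order is a
    deterministic permutation.
    """
    stat = window_total_change(traces, "LH")["total_change"].to_numpy()
    # stable sort on -stat keeps ascending row index within ties
    return np.argsort(-stat, kind="stable")


def inactive_fraction(traces: TraceMatrix, window: tuple[int, int] | str,
                      threshold: float = 0.1) -> dict[str, float]:
    """Per-group fraction of cells whose max ΔF/F₀ in the window is < threshold.

    ``window`` is a named window or an explicit half-open (start, end) frame
    range — e.g. the first minute of ligand application.
    """
    if isinstance(window, str):
        start, end = _window_slice(traces, window)
    else:
        start, end = window
        if not (0 <= start < end <= traces.n_frames):
            raise ValueError(f"window ({start}, {end}) out of range or empty")
    peak = traces.values[:, start:end].max(axis=1)
    return {
        group: float(np.mean(peak[traces.labels == group] < threshold))
        for group in traces.group_names()
    }


def first_lh_minute(grid: TimeGrid) -> tuple[int, int]:
    """Frame range of the first 60 s of ligand application."""
    n = int(round(60.0 * grid.rate))
    return grid.lh_start, min(grid.lh_start + n, grid.lh_end)
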