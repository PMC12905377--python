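"""Core containers for single-cell calcium-trace cohorts.

A recording is a matrix of per-cell ΔF/F₀ traces sampled on a shared
:class:`TimeGrid`: a basal (pre-ligand) window, a ligand bath-application
window, and a washout tail.  Cells carry a group label (``HET`` control,
``HOM`` mutant, or ``HOM_TREATED`` pharmacologically rescued mutant), an
animal id, and a cohort-level sex tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

GROUPS = ("HET", "HOM", "HOM_TREATED")

#: Named analysis windows on a TimeGrid.
WINDOWS = ("BASAL", "LH", "WASH")


@dataclass(frozen=True)
class TimeGrid:
    """Frame layout of a recording.

    Defaults describe a 12.5-min recording at 2 Hz: 1500 frames, with the
    ligand applied on frames [600, 960) (minutes 5–8) and washout after.
    """

    n_frames: int = 1500
    rate: float = 2.0  # frames per second
    lh_start: int = 600
    lh_end: int = 960  # half-open

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        # lh_start == lh_end encodes an absent ligand window (basal-only grid)
        if not (0 <= self.lh_start <= self.lh_end <= self.n_frames):
            raise ValueError(
                f"require 0 <= lh_start <= lh_end <= n_frames, got "
                f"lh_start={self.lh_start}, lh_end={self.lh_end}, n_frames={self.n_frames}"
            )

    @property
    def dt(self) -> float:
        """Seconds between frames."""
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds from recording start."""
        return np.arange(self.n_frames) / self.rate

    def window_bounds(self, window: str) -> Tuple[int, int]:
        """Half-open frame range [start, end) of a named window."""
        if window == "BASAL":
            return 0, self.lh_start
        if window == "LH":
            return self.lh_start, self.lh_end
        if window == "WASH":
            return self.lh_end, self.n_frames
        raise ValueError(f"unknown window {window!r}; expected one of {WINDOWS}")


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one experimental group.

    Response kinetics (latency, rise/decay time constants) are in seconds;
    amplitudes are in ΔF/F₀ units; oscillation frequencies in Hz.
    """

    responder_fraction: float
    peak_amp_mean: float
    peak_amp_sd: float
    latency_mean: float
    latency_sd: float
    rise_tau: float
    decay_tau: float
    basal_osc_amp: float
    basal_osc_freq_range: Tuple[float, float]
    drift_amp: float
    noise_sd: float

    def __post_init__(self) -> None:
        vals = {
            "responder_fraction": self.responder_fraction,
            "peak_amp_mean": self.peak_amp_mean,
            "peak_amp_sd": self.peak_amp_sd,
            "latency_mean": self.latency_mean,
            "latency_sd": self.latency_sd,
            "rise_tau": self.rise_tau,
            "decay_tau": self.decay_tau,
            "basal_osc_amp": self.basal_osc_amp,
            "drift_amp": self.drift_amp,
            "noise_sd": self.noise_sd,
        }
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        for name in ("peak_amp_sd", "latency_sd", "rise_tau", "decay_tau",
                     "basal_osc_amp", "drift_amp", "noise_sd"):
            if vals[name] < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.basal_osc_freq_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi < lo:
            raise ValueError("basal_osc_freq_range must be finite with 0 <= lo <= hi")


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``groups`` maps a group label to ``(GroupParams, n_cells, n_animals)``.
    """

    grid: TimeGrid
    groups: Dict[str, Tuple[GroupParams, int, int]]
    seed: int = 0
    sex: str = "female"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for label, (params, n_cells, n_animals) in self.groups.items():
            if label not in GROUPS:
                raise ValueError(f"unknown group label {label!r}; expected one of {GROUPS}")
            if n_cells < 1:
                raise ValueError(f"group {label}: n_cells must be >= 1")
            if n_animals < 1:
                raise ValueError(f"group {label}: n_animals must be >= 1")


@dataclass
class TraceMatrix:
    """Cells × frames ΔF/F₀ matrix with per-cell annotations."""

    values: np.ndarray  # (n_cells, n_frames) float
    labels: np.ndarray  # (n_cells,) str group labels
    animal_id: np.ndarray  # (n_cells,) str
    grid: TimeGrid = field(default_factory=TimeGrid)
    sex: str = "female"
    cell_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.animal_id = np.asarray(self.animal_id)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells × frames)")
        if self.values.shape[1] != self.grid.n_frames:
            raise ValueError(
                f"trace length {self.values.shape[1]} does not match grid "
                f"n_frames {self.grid.n_frames}"
            )
        n = self.values.shape[0]
        if self.labels.shape != (n,) or self.animal_id.shape != (n,):
            raise ValueError("labels/animal_id length must equal the number of cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.cell_id is None:
            self.cell_id = np.array([f"cell{str(i).zfill(4)}" for i in range(n)])
        else:
            self.cell_id = np.asarray(self.cell_id)
            if self.cell_id.shape != (n,):
                raise ValueError("cell_id length must equal the number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def group_names(self) -> list[str]:
        """Group labels present, in canonical HET/HOM/HOM_TREATED order."""
        present = set(self.labels.tolist())
        return [g for g in GROUPS if g in present]

    def subset(self, mask: np.ndarray) -> "TraceMatrix":
        """Row subset (boolean mask or index array); grid is shared."""
        return TraceMatrix(
            values=self.values[mask],
            labels=self.labels[mask],
            animal_id=self.animal_id[mask],
            grid=self.grid,
            sex=self.sex,
            cell_id=self.cell_id[mask],
        )

    def with_grid(self, grid: TimeGrid, values: np.ndarray) -> "TraceMatrix":
        return TraceMatrix(
            values=values,
            labels=self.labels.copy(),
            animal_id=self.animal_id.copy(),
            grid=grid,
            sex=self.sex,
            cell_id=self.cell_id.copy(),
        )


def replace_group(config: CohortConfig, label: str, **updates) -> CohortConfig:
    """Return a config with one group's GroupParams fields replaced."""
    params, n_cells, n_animals = config.groups[label]
    groups = dict(config.groups)
    groups[label] = (replace(params, **updates), n_cells, n_animals)
    return replace(config, groups=groups)
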