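"""Plain-text persistence.

Traces travel as a pair of CSVs: a wide trace table (cell_id, f0000 …
fNNNN) and a metadata table (cell_id, group, animal_id, sex).  Grid
parameters ride along in the metadata as constant columns.  Cohort
configs round-trip through YAML (or JSON) with an explicit schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CohortConfig, GroupParams, TimeGrid, TraceMatrix

_GRID_COLS = ("n_frames", "rate", "lh_start", "lh_end")


def save_traces(traces: TraceMatrix, trace_path: str | Path,
                meta_path: str | Path) -> None:
    n_frames = traces.n_frames
    width = max(4, len(str(n_frames - 1)))
    cols = [f"f{str(i).zfill(width)}" for i in range(n_frames)]
    df = pd.DataFrame(traces.values, columns=cols)
    df.insert(0, "cell_id", traces.cell_id)
    df.to_csv(trace_path, index=False)
    meta = pd.DataFrame({
        "cell_id": traces.cell_id,
        "group": traces.labels,
        "animal_id": traces.animal_id,
        "sex": traces.sex,
        "n_frames": traces.grid.n_frames,
        "rate": traces.grid.rate,
        "lh_start": traces.grid.lh_start,
        "lh_end": traces.grid.lh_end,
    })
    meta.to_csv(meta_path, index=False)


def load_traces(trace_path: str | Path, meta_path: str | Path) -> TraceMatrix:
    df = pd.read_csv(trace_path)
    meta = pd.read_csv(meta_path)
    if "cell_id" not in df.columns:
        raise ValueError("trace CSV is missing the cell_id column")
    required = {"cell_id", "group", "animal_id", "sex", *_GRID_COLS}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata CSV is missing columns: {sorted(missing)}")
    if len(df) != len(meta):
        raise ValueError(
            f"row count mismatch: {len(df)} trace rows vs {len(meta)} metadata rows")
    if not (df["cell_id"].to_numpy() == meta["cell_id"].to_numpy()).all():
        raise ValueError("cell_id order differs between trace and metadata CSVs")
    frame_cols = [c for c in df.columns if c != "cell_id"]
    grid = TimeGrid(n_frames=int(meta["n_frames"].iloc[0]),
                    rate=float(meta["rate"].iloc[0]),
                    lh_start=int(meta["lh_start"].iloc[0]),
                    lh_end=int(meta["lh_end"].iloc[0]))
    return TraceMatrix(
        values=df[frame_cols].to_numpy(dtype=float),
        labels=meta["group"].to_numpy(),
        animal_id=meta["animal_id"].to_numpy(),
        grid=grid,
        sex=str(meta["sex"].iloc[0]),
        cell_id=df["cell_id"].to_numpy(),
    )


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "grid": asdict(config.grid),
        "seed": config.seed,
        "sex": config.sex,
        "groups": {
            label: {"params": asdict(params), "n_cells": n_cells,
                    "n_animals": n_animals}
            for label, (params, n_cells, n_animals) in config.groups.items()
        },
    }


def config_from_dict(d: dict) -> CohortConfig:
    grid = TimeGrid(**d["grid"])
    groups = {}
    for label, g in d["groups"].items():
        p = dict(g["params"])
        p["basal_osc_freq_range"] = tuple(p["basal_osc_freq_range"])
        groups[label] = (GroupParams(**p), int(g["n_cells"]), int(g["n_animals"]))
    return CohortConfig(grid=grid, groups=groups, seed=int(d.get("seed", 0)),
                        sex=str(d.get("sex", "female")))


def save_config(config: CohortConfig, path: str | Path) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> CohortConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(d)


def save_embedding_csv(path: str | Path, cell_id: np.ndarray, coords: np.ndarray,
                       labels: np.ndarray, assignments: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"cell_id": cell_id, "dim1": coords[:, 0],
                       "dim2": coords[:, 1], "group": labels})
    if assignments is not None:
        df["cluster"] = assignments
    df.to_csv(path, index=False)
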