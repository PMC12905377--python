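"""End-to-end desk-scale run of the whole analysis from one config.

Stages: cohort generation → trace metrics and heatmap → 2-D embeddings →
K-means over a range of K (on the t-SNE map and on the full-dimensional
traces) → classical baselines + feature net (full-trace and basal-only) →
transfer evaluation of treated cells → Grad-CAM saliency and feature-space
projection → JSON report with a manifest of everything written.

All stage seeds are derived from one master seed by hashing the stage
name, so a rerun with the same config is byte-identical while stages stay
decoupled.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (LABEL_CODES, encode_labels, reports_frame,
                       run_baseline_suite, stratified_split, train_feature_net,
                       transfer_fraction_control, truncate_basal)
from .cluster import cluster_with_scores
from .data import CohortConfig, TraceMatrix
from .embedding import embed_pca, embed_tsne, embed_umap
from .metrics import (first_lh_minute, group_traces_frame, heatmap_order,
                      inactive_fraction, window_stats)
from .network import FeatureNetConfig
from .saliency import grad_cam_saliency, project_feature_space
from .simulate import generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    cohort: CohortConfig
    out_dir: str | Path
    seed: int = 0
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    tsne_steps: int = 1000
    tsne_perplexity: float = 30.0
    net_max_epochs: int = 500
    basal_only: bool = True
    render_heatmaps: bool = True

    def __post_init__(self) -> None:
        n_cells = sum(n for _, n, _ in self.cohort.groups.values())
        for k in self.k_range:
            if not 2 <= k < n_cells:
                raise ValueError(f"K={k} outside [2, n_cells={n_cells})")


@dataclass
class RunReport:
    out_dir: Path
    artifacts: list[str] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _write(report: RunReport, name: str, df: pd.DataFrame) -> None:
    path = report.out_dir / name
    df.to_csv(path, index=False)
    report.artifacts.append(name)
    logger.info("stage output %s: %d rows", name, len(df))


def _render_heatmap(report: RunReport, traces: TraceMatrix, name: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = heatmap_order(traces)
    fig, ax = plt.subplots(figsize=(8, 5))
    vmax = max(float(np.percentile(traces.values, 99.5)), 0.1)
    im = ax.imshow(traces.values[order], aspect="auto", cmap="viridis",
                   vmin=-0.1, vmax=vmax, interpolation="nearest")
    ax.axvline(traces.grid.lh_start, color="w", lw=0.8)
    ax.axvline(traces.grid.lh_end, color="w", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("cells (descending LH response)")
    fig.colorbar(im, ax=ax, label="ΔF/F₀")
    fig.savefig(report.out_dir / name, dpi=120)
    plt.close(fig)
    report.artifacts.append(name)


def _classification_block(report: RunReport, traces: TraceMatrix, tag: str,
                          seed: int, max_epochs: int,
                          treated: TraceMatrix | None) -> dict:
    split = stratified_split(traces.labels, test_fraction=0.2, seed=seed)
    reports = run_baseline_suite(traces, split, seed=seed)
    cfg = FeatureNetConfig(input_dim=traces.n_frames,
                           output_dim=int(np.unique(traces.labels).size),
                           max_epochs=max_epochs, seed=seed)
    net, net_report = train_feature_net(traces, split, cfg)
    if treated is not None and net.config.output_dim == 2:
        # re-train binary model on Het/Hom only if the suite itself was binary
        net_report.treated_as_control_pct = transfer_fraction_control(
            net, treated.values[:, :traces.n_frames])
    reports.append(net_report)
    table = reports_frame(reports)
    _write(report, f"classification_{tag}.csv", table)
    report.tables[f"classification_{tag}"] = table

    y = encode_labels(traces.labels)
    pred = net.predict(traces.values[split.test_indices])
    pred_df = pd.DataFrame({
        "cell_id": traces.cell_id[split.test_indices],
        "true": y[split.test_indices],
        "pred": pred,
    })
    _write(report, f"featurenet_predictions_{tag}.csv", pred_df)
    acc_recomputed = 100.0 * float(np.mean(pred_df["true"] == pred_df["pred"]))
    assert abs(acc_recomputed - net_report.accuracy) < 1e-9
    return {"net": net, "split": split, "accuracy": net_report.accuracy,
            "treated_as_control_pct": net_report.treated_as_control_pct}


def run_full(config: RunConfig) -> RunReport:
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)
    master = config.seed

    # --- simulate ---------------------------------------------------------
    cohort_cfg = config.cohort
    traces = generate_cohort(cohort_cfg)
    cio.save_traces(traces, out / "traces.csv", out / "metadata.csv")
    cio.save_config(cohort_cfg, out / "cohort_config.yaml")
    report.artifacts += ["traces.csv", "metadata.csv", "cohort_config.yaml"]
    logger.info("simulate: %d cells, groups %s", traces.n_cells, traces.group_names())

    # --- metrics ----------------------------------------------------------
    _write(report, "window_stats.csv", window_stats(traces))
    _write(report, "group_traces.csv", group_traces_frame(traces))
    inact = inactive_fraction(traces, first_lh_minute(traces.grid))
    if config.render_heatmaps:
        _render_heatmap(report, traces, "heatmap.png")

    # --- embeddings -------------------------------------------------------
    emb_seed = stage_seed(master, "embed")
    pca = embed_pca(traces.values)
    tsne = embed_tsne(traces.values, perplexity=config.tsne_perplexity,
                      n_steps=config.tsne_steps, seed=emb_seed)
    cio.save_embedding_csv(out / "embedding_pca.csv", traces.cell_id,
                           pca.coords, traces.labels)
    cio.save_embedding_csv(out / "embedding_tsne.csv", traces.cell_id,
                           tsne.coords, traces.labels)
    report.artifacts += ["embedding_pca.csv", "embedding_tsne.csv"]
    umap_res = embed_umap(traces.values, seed=emb_seed)
    if umap_res is not None:
        cio.save_embedding_csv(out / "embedding_umap.csv", traces.cell_id,
                               umap_res.coords, traces.labels)
        report.artifacts.append("embedding_umap.csv")

    # --- clustering -------------------------------------------------------
    clus_seed = stage_seed(master, "cluster")
    comp_rows = []
    for space, points in (("tsne", tsne.coords), ("full", traces.values)):
        for k in config.k_range:
            res = cluster_with_scores(points, traces.labels, k, seed=clus_seed)
            for cluster_id, row in res.composition.iterrows():
                entry = {"space": space, "K": k, "cluster": cluster_id,
                         "silhouette": res.silhouette_clusters[int(cluster_id)],
                         "purity": float(row.max())}
                entry.update({f"frac_{g}": float(v) for g, v in row.items()})
                comp_rows.append(entry)
    comp = pd.DataFrame(comp_rows)
    _write(report, "cluster_composition.csv", comp)
    report.tables["cluster_composition"] = comp

    # --- classification (full trace, then basal-only) ---------------------
    cls_seed = stage_seed(master, "classify")
    groups = traces.group_names()
    treated = None
    core = traces
    if "HOM_TREATED" in groups:
        treated = traces.subset(traces.labels == "HOM_TREATED")
        core = traces.subset(np.isin(traces.labels, ["HET", "HOM"]))
    full_block = _classification_block(report, core, "full", cls_seed,
                                       config.net_max_epochs, treated)
    basal_block = None
    if config.basal_only:
        basal_core = truncate_basal(core)
        basal_treated = truncate_basal(treated) if treated is not None else None
        basal_block = _classification_block(report, basal_core, "basal",
                                            stage_seed(master, "classify-basal"),
                                            config.net_max_epochs, basal_treated)

    # --- explainability ---------------------------------------------------
    net = full_block["net"]
    smap = grad_cam_saliency(net, core)
    # keep the saliency artifact compact: per-frame group means
    sal_mean = (pd.DataFrame(smap.values, index=core.labels)
                .groupby(level=0).mean().T.reset_index(names="frame"))
    _write(report, "saliency_group_mean.csv", sal_mean)
    proj = project_feature_space(net, traces, perplexity=config.tsne_perplexity,
                                 n_steps=config.tsne_steps,
                                 seed=stage_seed(master, "project"))
    cio.save_embedding_csv(out / "feature_space_tsne.csv", traces.cell_id,
                           proj.coords, traces.labels)
    report.artifacts.append("feature_space_tsne.csv")

    # --- report -----------------------------------------------------------
    report.metadata = {
        "master_seed": master,
        "stage_seeds": {s: stage_seed(master, s)
                        for s in ("embed", "cluster", "classify",
                                  "classify-basal", "project")},
        "k_range": list(config.k_range),
        "groups": groups,
        "n_cells": int(traces.n_cells),
        "inactive_first_lh_minute": inact,
        "featurenet_accuracy_full_pct": full_block["accuracy"],
        "featurenet_accuracy_basal_pct": (basal_block["accuracy"]
                                          if basal_block else None),
        "treated_as_control_pct": full_block["treated_as_control_pct"],
        "tsne_final_kl": float(tsne.objective_trace[-1]),
        "wall_time_s": round(time.time() - t0, 2),
    }
    (out / "report.json").write_text(json.dumps(report.metadata, indent=2))
    report.artifacts.append("report.json")
    missing = [a for a in report.artifacts if not (out / a).exists()]
    if missing:
        raise RuntimeError(f"missing artifacts: {missing}")
    return report
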