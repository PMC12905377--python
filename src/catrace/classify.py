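"""Supervised genotype classification.

Runs the classical benchmark suite (eight scikit-learn models with the
study's printed hyperparameters) and the feature-learning network on an
80:20 stratified split, reports accuracy and macro-F1, extracts 128-dim
hidden features, and evaluates transfer of the Het/Hom-trained model to
chaperone-treated cells.  Inputs are raw ΔF/F₀ vectors; no per-feature
standardization is applied by default (a ``standardize`` flag is exposed
for the scale-sensitive baselines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_recall_fscore_support
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import GROUPS, TimeGrid, TraceMatrix
from .network import FeatureNet, FeatureNetConfig

logger = logging.getLogger(__name__)

#: Fixed class encoding (argmax ties resolve to the lower index).
LABEL_CODES = {"HET": 0, "HOM": 1, "HOM_TREATED": 2}


def encode_labels(labels: np.ndarray) -> np.ndarray:
    return np.array([LABEL_CODES[l] for l in np.asarray(labels)], dtype=int)


@dataclass(frozen=True)
class SplitSpec:
    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    stratified: bool
    seed: int


@dataclass
class ClassifierReport:
    model: str
    hyperparameters: dict
    accuracy: float  # percent
    macro_f1: float
    per_class: pd.DataFrame | None = None
    treated_as_control_pct: float | None = None
    extras: dict = field(default_factory=dict)


def stratified_split(labels: np.ndarray, test_fraction: float = 0.2,
                     seed: int = 0) -> SplitSpec:
    """Deterministic stratified train/test split.

    Each class contributes round(test_fraction · n_class) cells to the test
    set, so per-class test proportions are within one cell of the target.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 cells")
        idx = idx[rng.permutation(idx.size)]
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return SplitSpec(
        train_indices=np.sort(np.concatenate(train)),
        test_indices=np.sort(np.concatenate(test)),
        test_fraction=test_fraction, stratified=True, seed=seed)


def truncate_basal(traces: TraceMatrix) -> TraceMatrix:
    """Restrict traces to the basal window [0, lh_start) — the
    spontaneous-activity-only variant of the dataset."""
    grid = traces.grid
    if grid.lh_start >= grid.n_frames or grid.lh_start < 1:
        raise ValueError("grid has no basal window to truncate to")
    if traces.values.shape[1] < grid.lh_start:
        raise ValueError("traces shorter than the basal window")
    # the truncated grid has an empty ligand window (lh_start == lh_end)
    new_grid = TimeGrid(n_frames=grid.lh_start, rate=grid.rate,
                        lh_start=grid.lh_start, lh_end=grid.lh_start)
    return traces.with_grid(new_grid, traces.values[:, :grid.lh_start].copy())


# ---- classical baselines -------------------------------------------------

def _baseline_models(seed: int, mlp_width: int) -> list[tuple[str, dict, object]]:
    return [
        ("SVM (RBF kernel)", {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
         SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)),
        ("SVM (linear kernel)", {"kernel": "linear", "C": 1.0, "max_iter": 10000},
         SVC(kernel="linear", C=1.0, max_iter=10000, random_state=seed)),
        ("Logistic regression", {"penalty": "l2", "C": 1.0, "solver": "lbfgs",
                                 "max_iter": 5000},
         LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=5000)),
        ("Decision tree", {"criterion": "gini", "max_depth": None},
         DecisionTreeClassifier(criterion="gini", max_depth=None, random_state=seed)),
        ("K-nearest neighbors", {"n_neighbors": 5, "metric": "minkowski", "p": 2},
         KNeighborsClassifier(n_neighbors=5, weights="uniform", metric="minkowski", p=2)),
        ("Gaussian Naive Bayes", {"priors": None, "var_smoothing": 1e-9},
         GaussianNB(priors=None, var_smoothing=1e-9)),
        ("Random forest", {"n_estimators": 50, "criterion": "gini",
                           "max_features": "sqrt"},
         RandomForestClassifier(n_estimators=50, criterion="gini", max_depth=None,
                                max_features="sqrt", random_state=seed)),
        ("Multi-layer perceptron", {"hidden_layer_sizes": (mlp_width,),
                                    "activation": "relu", "solver": "adam",
                                    "alpha": 1e-4, "max_iter": 200},
         MLPClassifier(hidden_layer_sizes=(mlp_width,), activation="relu",
                       solver="adam", alpha=1e-4, max_iter=200, random_state=seed)),
    ]


def _evaluate(name: str, hyper: dict, y_true: np.ndarray,
              y_pred: np.ndarray) -> ClassifierReport:
    acc = 100.0 * accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, average="macro")
    prec, rec, f1c, support = precision_recall_fscore_support(
        y_true, y_pred, labels=np.unique(y_true), zero_division=0)
    per_class = pd.DataFrame({
        "class": np.unique(y_true), "precision": prec, "recall": rec,
        "f1": f1c, "support": support})
    return ClassifierReport(model=name, hyperparameters=hyper,
                            accuracy=float(acc), macro_f1=float(f1),
                            per_class=per_class)


def run_baseline_suite(traces: TraceMatrix, split: SplitSpec, seed: int = 0,
                       mlp_width: int = 400, standardize: bool = False
                       ) -> list[ClassifierReport]:
    """Train and evaluate the eight classical baselines on the split."""
    y = encode_labels(traces.labels)
    x_train, y_train = traces.values[split.train_indices], y[split.train_indices]
    x_test, y_test = traces.values[split.test_indices], y[split.test_indices]
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    if standardize:
        scaler = StandardScaler().fit(x_train)
        x_train, x_test = scaler.transform(x_train), scaler.transform(x_test)
        logger.info("baseline inputs standardized per feature")
    reports = []
    for name, hyper, model in _baseline_models(seed, mlp_width):
        model.fit(x_train, y_train)
        reports.append(_evaluate(name, hyper, y_test, model.predict(x_test)))
    return reports


# ---- feature-learning network -------------------------------------------

def train_feature_net(traces: TraceMatrix, split: SplitSpec,
                      config: FeatureNetConfig | None = None,
                      val_fraction: float = 0.1
                      ) -> tuple[FeatureNet, ClassifierReport]:
    """Train the feature net on the split's training set and evaluate on test.

    Early stopping monitors a stratified validation carve-out (default 10%
    of the training set); the test set never influences stopping.
    """
    y = encode_labels(traces.labels)
    classes = np.unique(y[split.train_indices])
    if config is None:
        config = FeatureNetConfig(input_dim=traces.n_frames,
                                  output_dim=int(classes.size))
    if config.input_dim != traces.n_frames:
        raise ValueError("config.input_dim does not match trace length")
    train_idx = split.train_indices
    inner = stratified_split(y[train_idx], test_fraction=val_fraction,
                             seed=config.seed)
    fit_idx = train_idx[inner.train_indices]
    val_idx = train_idx[inner.test_indices]
    net = FeatureNet(config)
    net.fit(traces.values[fit_idx], y[fit_idx],
            traces.values[val_idx], y[val_idx])
    y_pred = net.predict(traces.values[split.test_indices])
    report = _evaluate("Feature-learning network",
                       {"hidden": (config.hidden1, config.hidden2),
                        "dropout": (config.dropout1, config.dropout2),
                        "lr": config.lr, "batch_size": config.batch_size,
                        "patience": config.patience, "seed": config.seed},
                       y[split.test_indices], y_pred)
    report.extras["best_epoch"] = net.history.best_epoch
    report.extras["stopped_epoch"] = net.history.stopped_epoch
    return net, report


def extract_features(net: FeatureNet, traces: TraceMatrix) -> np.ndarray:
    """z2 pre-activation features for every cell (dropout disabled)."""
    return net.features(traces.values)


def transfer_fraction_control(net: FeatureNet, treated: TraceMatrix | np.ndarray
                              ) -> float:
    """Percentage of treated cells a binary Het/Hom model calls control (Het)."""
    if net.config.output_dim != 2:
        raise ValueError("transfer evaluation requires a binary HET/HOM model")
    x = treated.values if isinstance(treated, TraceMatrix) else np.asarray(treated)
    pred = net.predict(x)
    return float(100.0 * np.mean(pred == LABEL_CODES["HET"]))


def reports_frame(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Flatten reports to a table mirroring the study's benchmark layout."""
    rows = []
    for r in reports:
        rows.append({
            "model": r.model,
            "hyperparameters": "; ".join(f"{k}={v}" for k, v in r.hyperparameters.items()),
            "accuracy_pct": round(r.accuracy, 2),
            "macro_f1": round(r.macro_f1, 4),
            "treated_as_control_pct": (round(r.treated_as_control_pct, 2)
                                       if r.treated_as_control_pct is not None else None),
        })
    return pd.DataFrame(rows)
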