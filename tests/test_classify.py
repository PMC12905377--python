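"""Splits, baselines, feature net training, feature extraction, transfer."""

import numpy as np
import pytest

from catrace.classify import (LABEL_CODES, encode_labels, run_baseline_suite,
                              stratified_split, train_feature_net,
                              transfer_fraction_control, truncate_basal)
from catrace.network import FeatureNet, FeatureNetConfig, softmax
from catrace.simulate import generate_cohort

from conftest import small_group
from catrace.data import CohortConfig, TraceMatrix


def confusion_matrix_oracle(y_true, y_pred, n_classes):
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    acc = 100.0 * np.trace(cm) / cm.sum()
    f1s = []
    for c in range(n_classes):
        tp = cm[c, c]
        prec = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
        rec = tp / cm[c].sum() if cm[c].sum() else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return acc, float(np.mean(f1s))


class TestSplit:
    def test_eighty_twenty_counts(self):
        labels = np.array(["A"] * 60 + ["B"] * 40)
        sp = stratified_split(labels, test_fraction=0.2, seed=0)
        test_labels = labels[sp.test_indices]
        assert (np.sum(test_labels == "A"), np.sum(test_labels == "B")) == (12, 8)

    def test_deterministic(self):
        labels = np.array(["A", "B"] * 50)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        assert np.array_equal(a.train_indices, b.train_indices)

    def test_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["HET", "HOM", "HOM_TREATED"], size=1000)
        sp = stratified_split(labels, seed=1)
        train, test = set(sp.train_indices), set(sp.test_indices)
        assert train.isdisjoint(test)
        assert train | test == set(range(1000))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array(["A", "A", "B"]), seed=0)


class TestFeatureNet:
    def test_softmax_rows_sum_to_one(self):
        net = FeatureNet(FeatureNetConfig(input_dim=20, output_dim=3, seed=0))
        x = np.random.default_rng(0).normal(size=(7, 20))
        p = net.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_zero_weight_model_features_are_bias(self):
        net = FeatureNet(FeatureNetConfig(input_dim=10, output_dim=2, seed=0))
        net.W1[:] = 0.0
        net.W2[:] = 0.0
        net.b2[:] = 1.5
        feats = net.features(np.ones((4, 10)))
        assert np.allclose(feats, 1.5)

    def test_features_deterministic_without_dropout(self):
        net = FeatureNet(FeatureNetConfig(input_dim=15, output_dim=2, seed=1))
        x = np.random.default_rng(1).normal(size=(5, 15))
        assert np.array_equal(net.features(x), net.features(x))

    def test_dim_mismatch_rejected(self):
        net = FeatureNet(FeatureNetConfig(input_dim=15, output_dim=2, seed=1))
        with pytest.raises(ValueError):
            net.features(np.zeros((3, 14)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FeatureNetConfig(input_dim=0)
        with pytest.raises(ValueError):
            FeatureNetConfig(dropout1=1.0)

    def test_training_learns_separable_cohort(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        sp = stratified_split(tm.labels, seed=0)
        cfg = FeatureNetConfig(input_dim=tm.n_frames, output_dim=2,
                               max_epochs=60, seed=0)
        net, report = train_feature_net(tm, sp, cfg)
        assert report.accuracy >= 75.0
        # reported metrics match an independent confusion-matrix oracle
        y = encode_labels(tm.labels)
        pred = net.predict(tm.values[sp.test_indices])
        acc, f1 = confusion_matrix_oracle(y[sp.test_indices], pred, 2)
        assert report.accuracy == pytest.approx(acc, abs=1e-9)
        assert report.macro_f1 == pytest.approx(f1, abs=1e-9)

    def test_early_stopping_bounds_epochs(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        sp = stratified_split(tm.labels, seed=0)
        cfg = FeatureNetConfig(input_dim=tm.n_frames, output_dim=2,
                               max_epochs=200, patience=5, seed=0)
        net, report = train_feature_net(tm, sp, cfg)
        assert report.extras["stopped_epoch"] < 199


class TestBaselines:
    def test_suite_composition_and_metrics(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        sp = stratified_split(tm.labels, seed=0)
        reports = run_baseline_suite(tm, sp, seed=0, mlp_width=100)
        assert len(reports) == 8
        names = {r.model for r in reports}
        assert {"SVM (RBF kernel)", "Random forest",
                "Gaussian Naive Bayes"} <= names
        for r in reports:
            assert 0.0 <= r.accuracy <= 100.0
            assert 0.0 <= r.macro_f1 <= 1.0

    def test_linear_svm_perfect_on_separable_blobs(self, small_grid):
        rng = np.random.default_rng(0)
        n = 40
        v = rng.normal(0, 0.05, size=(2 * n, small_grid.n_frames))
        v[n:] += 1.0  # constant offset: linearly separable
        tm = TraceMatrix(values=v, labels=np.array(["HET"] * n + ["HOM"] * n),
                         animal_id=np.array(["a"] * 2 * n), grid=small_grid)
        sp = stratified_split(tm.labels, seed=0)
        reports = run_baseline_suite(tm, sp, seed=0, mlp_width=50)
        linear = next(r for r in reports if r.model == "SVM (linear kernel)")
        assert linear.accuracy == 100.0

    def test_single_class_training_rejected(self, small_grid):
        v = np.zeros((10, small_grid.n_frames))
        tm = TraceMatrix(values=v, labels=np.array(["HET"] * 10),
                         animal_id=np.array(["a"] * 10), grid=small_grid)
        sp = SplitLike = stratified_split(np.array(["HET"] * 10), seed=0)
        with pytest.raises(ValueError):
            run_baseline_suite(tm, sp, seed=0)


@pytest.fixture(scope="module")
def trained():
    from catrace.data import CohortConfig, TimeGrid
    grid = TimeGrid(n_frames=300, rate=2.0, lh_start=120, lh_end=192)
    het = small_group()
    hom = small_group(responder_fraction=0.2, peak_amp_mean=0.2,
                      latency_mean=15.0, rise_tau=25.0,
                      basal_osc_freq_range=(0.10, 0.16))
    cfg = CohortConfig(grid=grid, groups={"HET": (het, 60, 3),
                                          "HOM": (hom, 60, 3)}, seed=4)
    tm = generate_cohort(cfg)
    sp = stratified_split(tm.labels, seed=4)
    net, report = train_feature_net(
        tm, sp, FeatureNetConfig(input_dim=300, output_dim=2,
                                 max_epochs=60, seed=4))
    return net, tm, sp, report


class TestTransfer:

    def test_het_copy_recovers_het_recall(self, trained):
        net, tm, sp, _ = trained
        y = encode_labels(tm.labels)
        test_het = sp.test_indices[y[sp.test_indices] == LABEL_CODES["HET"]]
        recall = 100.0 * np.mean(net.predict(tm.values[test_het]) == 0)
        pct = transfer_fraction_control(net, tm.values[test_het])
        assert pct == pytest.approx(recall, abs=1e-9)

    def test_hom_copy_is_complement_of_hom_recall(self, trained):
        net, tm, sp, _ = trained
        y = encode_labels(tm.labels)
        test_hom = sp.test_indices[y[sp.test_indices] == LABEL_CODES["HOM"]]
        hom_recall = 100.0 * np.mean(net.predict(tm.values[test_hom]) == 1)
        pct = transfer_fraction_control(net, tm.values[test_hom])
        assert pct == pytest.approx(100.0 - hom_recall, abs=1e-9)

    def test_non_binary_model_rejected(self):
        net = FeatureNet(FeatureNetConfig(input_dim=10, output_dim=3, seed=0))
        with pytest.raises(ValueError):
            transfer_fraction_control(net, np.zeros((3, 10)))

    def test_z2_embedding_separates_classes_better_than_raw(self, trained):
        from catrace.classify import extract_features
        from catrace.cluster import cluster_with_scores
        net, tm, sp, _ = trained
        feats = extract_features(net, tm)
        purity_feat = cluster_with_scores(feats, tm.labels, 2, seed=0).purity.max()
        purity_raw = cluster_with_scores(tm.values, tm.labels, 2, seed=0).purity.max()
        assert purity_feat >= purity_raw - 1e-9


class TestTruncateBasal:
    def test_restricts_to_basal_frames(self, small_cohort_config):
        tm = generate_cohort(small_cohort_config)
        b = truncate_basal(tm)
        assert b.n_frames == tm.grid.lh_start
        assert b.n_cells == tm.n_cells
        assert np.array_equal(b.values, tm.values[:, :tm.grid.lh_start])
        assert np.array_equal(b.labels, tm.labels)

    def test_retruncation_rejected(self, small_cohort_config):
        b = truncate_basal(generate_cohort(small_cohort_config))
        with pytest.raises(ValueError):
            truncate_basal(b)
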