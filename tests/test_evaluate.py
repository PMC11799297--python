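"""Stratified splits, logistic baseline, metric panel, and the evaluation loop."""

from dataclasses import replace

import numpy as np
import pytest

import tcrmotif as tm
import tcrmotif.evaluate as ev
import tcrmotif.features as feat
from tcrmotif.io import PeptideRecord


def _balanced_labels(n_per_class):
    return np.array([1] * n_per_class + [0] * n_per_class)


class TestStratifiedSplits:
    def test_exact_divisibility_preserves_class_counts(self):
        y = _balanced_labels(100)
        splits = ev.stratified_splits(y, ev.SplitSpec(n_repeats=10, test_fraction=0.2, seed=0))
        for _, test_idx in splits:
            assert len(test_idx) == 40
            assert y[test_idx].sum() == 20

    def test_deterministic_given_seed(self):
        y = _balanced_labels(30)
        a = ev.stratified_splits(y, ev.SplitSpec(seed=5))
        b = ev.stratified_splits(y, ev.SplitSpec(seed=5))
        assert all((t1 == t2).all() and (s1 == s2).all() for (t1, s1), (t2, s2) in zip(a, b))

    def test_per_class_proportions_on_indivisible_sizes(self):
        y = _balanced_labels(98)
        splits = ev.stratified_splits(y, ev.SplitSpec(n_repeats=10, test_fraction=0.2, seed=1))
        for _, test_idx in splits:
            for cls in (0, 1):
                frac = np.mean(y[test_idx] == cls) * len(test_idx) / 98
                assert abs(frac - 0.2) < 1 / 98

    def test_train_test_disjoint(self):
        y = _balanced_labels(25)
        for train_idx, test_idx in ev.stratified_splits(y, ev.SplitSpec(seed=2)):
            assert not set(train_idx) & set(test_idx)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.stratified_splits(np.ones(10), ev.SplitSpec())


class TestLogisticBaseline:
    def test_separable_data_fits_perfectly(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = ev.fit_logistic(X, y)
        pred, _ = ev.predict(model, X)
        assert (pred == y).all()

    def test_null_data_scores_near_half(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(400, 3))
        y = _balanced_labels(200)
        rng.shuffle(y)
        _, scores = ev.predict(ev.fit_logistic(X, y), X)
        assert abs(scores.mean() - 0.5) <= 0.05

    def test_label_flip_flips_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(60, 2))
        y = (X[:, 0] > 0.5).astype(int)
        p1, _ = ev.predict(ev.fit_logistic(X, y), X)
        p2, _ = ev.predict(ev.fit_logistic(X, 1 - y), X)
        assert (p2 == 1 - p1).all()

    def test_zero_feature_matrix_rejected(self):
        with pytest.raises(ValueError, match="lower the LASSO penalty"):
            ev.fit_logistic(np.empty((4, 0)), np.array([0, 1, 0, 1]))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0])
        row = ev.compute_metrics(y, y, y.astype(float))
        assert all(row[m] == 1.0 for m in ("accuracy", "recall", "f1", "mcc", "auc"))

    def test_hand_computed_contingency(self):
        # TP=3, FP=1, TN=3, FN=1
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        row = ev.compute_metrics(y_true, y_pred)
        assert row["accuracy"] == pytest.approx(0.75)
        assert row["mcc"] == pytest.approx(0.5)
        assert row["f1"] == pytest.approx(0.75)

    def test_constant_predictor_on_balanced_data(self):
        y = _balanced_labels(10)
        row = ev.compute_metrics(y, np.ones_like(y))
        assert row["accuracy"] == 0.5
        assert row["mcc"] == 0.0

    def test_weighted_recall_equals_accuracy_on_balanced_data(self):
        rng = np.random.default_rng(2)
        y = _balanced_labels(50)
        for _ in range(5):
            pred = rng.integers(0, 2, size=100)
            row = ev.compute_metrics(y, pred)
            assert abs(row["recall"] - row["accuracy"]) <= 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = _balanced_labels(30)
        s = rng.uniform(size=60)
        a1 = ev.compute_metrics(y, (s > 0.5).astype(int), s)["auc"]
        a2 = ev.compute_metrics(y, (s > 0.5).astype(int), np.exp(5 * s))["auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_truth_reports_missing_auc(self):
        row = ev.compute_metrics(np.ones(4), np.ones(4), np.linspace(0, 1, 4))
        assert np.isnan(row["auc"])
        assert row["accuracy"] == 1.0


def _ground_truth_records(n_per_class, seed, plant_prob=1.0):
    spec = tm.SyntheticSpec(
        n_strong=n_per_class,
        n_weak=n_per_class,
        planted_motifs=(tm.PlantedMotif("AFF", 3, plant_prob),),
        seed=seed,
    )
    recs = tm.generate_library(spec)
    return [replace(r, label=1 if r.id.startswith("strong") else 0) for r in recs]


class TestRunEvaluation:
    def test_planted_library_is_separable(self):
        recs = _ground_truth_records(60, seed=0)
        report = ev.run_evaluation(
            recs,
            categories=("ngram",),
            split_spec=ev.SplitSpec(n_repeats=5, seed=0),
            fixed_lambda=0.01,
        )
        mean_auc = report[report["repeat"] == "mean"]["auc"].iloc[0]
        assert mean_auc >= 0.95

    def test_label_shuffle_destroys_signal(self):
        # null band needs enough rows/repeats to concentrate: 100/class, 10 splits
        recs = _ground_truth_records(100, seed=1)
        rng = np.random.default_rng(7)
        labels = np.array([r.label for r in recs])
        rng.shuffle(labels)
        shuffled = [replace(r, label=int(l)) for r, l in zip(recs, labels)]
        report = ev.run_evaluation(
            shuffled,
            categories=("ngram",),
            split_spec=ev.SplitSpec(n_repeats=10, seed=1),
            fixed_lambda=0.01,
        )
        mean_auc = report[report["repeat"] == "mean"]["auc"].iloc[0]
        assert 0.4 <= mean_auc <= 0.6

    def test_identical_seed_gives_identical_report(self):
        recs = _ground_truth_records(30, seed=2)
        kw = dict(categories=("tripeptide",), split_spec=ev.SplitSpec(n_repeats=3, seed=9),
                  fixed_lambda=0.01)
        assert ev.run_evaluation(recs, **kw).equals(ev.run_evaluation(recs, **kw))

    def test_normalization_never_sees_test_rows(self, monkeypatch):
        recs = _ground_truth_records(30, seed=3)
        labels = np.array([r.label for r in recs])
        split_spec = ev.SplitSpec(n_repeats=3, seed=4)
        expected_train_sizes = {len(tr) for tr, _ in ev.stratified_splits(labels, split_spec)}
        seen_sizes = []
        real_fit = feat.fit_normalizer

        def spy(train):
            seen_sizes.append(train.shape[0])
            return real_fit(train)

        monkeypatch.setattr(feat, "fit_normalizer", spy)
        ev.run_evaluation(
            recs, categories=("ngram",), split_spec=split_spec, fixed_lambda=0.01
        )
        assert seen_sizes  # the spy was exercised
        assert set(seen_sizes) == expected_train_sizes
        assert all(s < len(recs) for s in seen_sizes)

    def test_report_layout_has_mean_row_per_category(self):
        recs = _ground_truth_records(30, seed=5)
        report = ev.run_evaluation(
            recs,
            categories=("ngram", "tripeptide"),
            split_spec=ev.SplitSpec(n_repeats=2, seed=0),
            fixed_lambda=0.01,
        )
        mean_rows = report[report["repeat"] == "mean"]
        assert list(mean_rows["category"]) == ["ngram", "tripeptide"]
        assert len(report) == 2 * 2 + 2
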