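"""Balanced, stratified, repeated-split evaluation of a logistic baseline.

For each repeat: stratified 80/20 shuffle split, min-max normalization
fitted on the training rows only, L1 feature selection on the training
rows, a logistic-regression fit on the selected columns, and the metric
panel (Accuracy, weighted Recall, weighted F1, MCC, AUC) on the held-out
rows. On balanced test sets weighted Recall equals Accuracy, which is
why those two columns pair up in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from . import features as feat
from . import select as sel

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "recall", "f1", "mcc", "auc")


@dataclass
class SplitSpec:
    n_repeats: int = 10
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def stratified_splits(labels, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified shuffle splits preserving per-class proportions.

    Test sets may overlap across repeats; train/test are disjoint within
    a repeat.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("stratified splitting needs both classes present")
    splitter = StratifiedShuffleSplit(
        n_splits=spec.n_repeats, test_size=spec.test_fraction, random_state=spec.seed
    )
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros_like(y), y)]


def fit_logistic(X_train, y_train) -> LogisticRegression:
    """Maximum-likelihood logistic fit with a tiny ridge stabilizer.

    The near-vanishing L2 term (C = 1e8) only guarantees a finite
    optimum under complete separation.
    """
    Xa = np.asarray(X_train, dtype=float)
    if Xa.ndim != 2 or Xa.shape[1] == 0:
        raise ValueError(
            "no feature columns selected; lower the LASSO penalty to retain features"
        )
    if len(np.unique(np.asarray(y_train))) < 2:
        raise ValueError("training data must contain both classes")
    model = LogisticRegression(C=1e8, solver="lbfgs", max_iter=10_000, tol=1e-10)
    model.fit(Xa, np.asarray(y_train))
    return model


def predict(model: LogisticRegression, X) -> tuple[np.ndarray, np.ndarray]:
    """(hard labels at the 0.5 probability cutoff, class-1 probability scores)."""
    scores = model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return (scores >= 0.5).astype(int), scores


def matthews_corrcoef(y_true, y_pred) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 when any factor is 0."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def compute_metrics(y_true, y_pred, y_score=None) -> dict[str, float]:
    """One metric-panel row; AUC reported as NaN when undefined (single-class truth)."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    row = {
        "accuracy": float(np.mean(yt == yp)),
        "recall": float(recall_score(yt, yp, average="weighted", zero_division=0)),
        "f1": float(f1_score(yt, yp, average="weighted", zero_division=0)),
        "mcc": matthews_corrcoef(yt, yp),
    }
    if y_score is None or len(np.unique(yt)) < 2:
        row["auc"] = float("nan")
    else:
        row["auc"] = float(roc_auc_score(yt, np.asarray(y_score, dtype=float)))
    return row


def run_evaluation(
    records,
    categories=feat.FEATURE_CATEGORIES,
    lasso_config: sel.LassoConfig | None = None,
    split_spec: SplitSpec | None = None,
    fixed_lambda: float | None = None,
    select_once: bool = False,
    encoder_spec: feat.EncoderSpec | None = None,
) -> pd.DataFrame:
    """Full repeated-split evaluation per feature category.

    ``records`` must be labeled and (nominally) class-balanced. Per
    repeat, normalization and feature selection see training rows only;
    with ``select_once`` the selection is instead fitted once on the full
    matrix before splitting (figure-reproduction mode, leakier).
    ``fixed_lambda`` bypasses the CV search. Returns one row per
    (category, repeat) plus a per-category mean row (repeat = 'mean').
    """
    split_spec = split_spec or SplitSpec()
    labels = np.array([r.label for r in records])
    if any(label is None for label in labels):
        raise ValueError("all records must be labeled before evaluation")
    sequences = [r.sequence for r in records]
    splits = stratified_splits(labels, split_spec)
    rows = []
    for category in categories:
        X = feat.encode_sequences(sequences, category=category, spec=encoder_spec)
        once_result = None
        if select_once:
            params_all = feat.fit_normalizer(X)
            X_all = feat.apply_normalizer(params_all, X)
            once_result = _select(X_all, labels, lasso_config, fixed_lambda)
        for rep, (train_idx, test_idx) in enumerate(splits):
            X_train_raw = X.iloc[train_idx]
            params = feat.fit_normalizer(X_train_raw)
            X_train = feat.apply_normalizer(params, X_train_raw)
            X_test = feat.apply_normalizer(params, X.iloc[test_idx])
            y_train, y_test = labels[train_idx], labels[test_idx]
            result = once_result if select_once else _select(X_train, y_train, lasso_config, fixed_lambda)
            selected = result.ranked_features
            if not selected:
                logger.warning(
                    "category %s repeat %d: no features selected; scoring with the null model",
                    category,
                    rep,
                )
                y_pred = np.full(len(test_idx), int(round(float(y_train.mean()))))
                y_score = np.full(len(test_idx), 0.5)
            else:
                model = fit_logistic(X_train[selected], y_train)
                y_pred, y_score = predict(model, X_test[selected])
            row = compute_metrics(y_test, y_pred, y_score)
            rows.append({"category": category, "repeat": rep, **row})
    report = pd.DataFrame(rows)
    means = (
        report.groupby("category", sort=False)[list(METRIC_NAMES)].mean().reset_index()
    )
    means.insert(1, "repeat", "mean")
    return pd.concat([report, means], ignore_index=True)


def _select(X, y, config, fixed_lambda):
    if fixed_lambda is not None:
        return sel.fit_at_lambda(X, y, fixed_lambda)
    return sel.cv_lambda(X, y, config)
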