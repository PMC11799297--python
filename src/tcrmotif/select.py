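"""L1-regularized feature selection.

Fits w, b minimizing (1/(2n)) * sum_i (y_i - x_i.w - b)^2 + lambda * ||w||_1
on [0,1]-normalized feature columns, with the 0/1 binder label treated
as a real-valued response. The regularization strength is chosen on a
grid by k-fold cross-validation on held-out mean squared error; nonzero
weights define the selected features and |w| their importance ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


def default_lambda_grid() -> np.ndarray:
    """30 log-spaced penalties in [1e-4, 1]."""
    return np.logspace(-4, 0, 30)


@dataclass
class LassoConfig:
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    k_folds: int = 5
    seed: int = 0
    standardize_columns: bool = False

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("lambda grid must be nonempty")
        if np.any(grid <= 0):
            raise ValueError("lambda grid must be strictly positive")
        if np.any(np.diff(grid) < 0):
            raise ValueError("lambda grid must be sorted ascending")
        self.lambda_grid = grid
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class LassoResult:
    """Fitted weights plus the cross-validation record behind the chosen penalty."""

    chosen_lambda: float
    cv_mse: dict[float, float]
    weights: pd.Series
    intercept: float

    @property
    def ranked_features(self) -> list[str]:
        """Nonzero features by descending |w|, ties broken by feature name."""
        nz = self.weights[self.weights != 0.0]
        order = sorted(nz.index, key=lambda name: (-abs(nz[name]), name))
        return order


def _as_array(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError(f"X has {Xa.shape[0]} rows but y has {ya.shape[0]}")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("NaN values in X or y")
    return Xa, ya, names


def lambda_max(X, y) -> float:
    """Smallest penalty at which the all-zero weight vector is optimal (KKT).

    lambda_max = max_j |x_j^T (y - y_bar)| / n.
    """
    Xa, ya, _ = _as_array(X, y)
    resid = ya - ya.mean()
    return float(np.max(np.abs(Xa.T @ resid)) / Xa.shape[0])


def fit_lasso(X, y, lam: float) -> tuple[pd.Series, float]:
    """Minimize (1/(2n))||y - Xw - b||^2 + lam * ||w||_1; returns (weights, intercept).

    lam = 0 reduces to ordinary least squares (minimum-norm solution).
    Deterministic for fixed inputs.
    """
    Xa, ya, names = _as_array(X, y)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        Xc = np.column_stack([np.ones(Xa.shape[0]), Xa])
        coef, *_ = np.linalg.lstsq(Xc, ya, rcond=None)
        return pd.Series(coef[1:], index=names), float(coef[0])
    if lam >= lambda_max(Xa, ya):
        # KKT: zero vector is stationary; return it exactly.
        return pd.Series(np.zeros(Xa.shape[1]), index=names), float(ya.mean())
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
    model.fit(Xa, ya)
    coef = model.coef_.copy()
    # coordinate descent can leave O(eps) residue on collinear columns;
    # snap it to an exact zero so sparsity semantics are clean
    coef[np.abs(coef) < 1e-12] = 0.0
    return pd.Series(coef, index=names), float(model.intercept_)


def lasso_objective(X, y, w, b: float, lam: float) -> float:
    Xa, ya, _ = _as_array(X, y)
    wa = np.asarray(w, dtype=float)
    resid = ya - Xa @ wa - b
    return float(resid @ resid / (2 * Xa.shape[0]) + lam * np.abs(wa).sum())


def cv_lambda(X, y, config: LassoConfig | None = None) -> LassoResult:
    """Choose lambda by k-fold CV on held-out MSE; refit on all rows at the winner.

    Ties in mean CV error resolve to the larger (sparser) penalty. Grid
    values whose fits fail to converge are recorded as NaN and skipped
    with a warning.
    """
    config = config or LassoConfig()
    Xa, ya, names = _as_array(X, y)
    if Xa.shape[0] < config.k_folds:
        raise ValueError("need at least k_folds rows")
    folds = list(
        KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed).split(Xa)
    )
    cv_mse: dict[float, float] = {}
    for lam in config.lambda_grid:
        errs = []
        failed = False
        for train_idx, test_idx in folds:
            Xtr, ytr = Xa[train_idx], ya[train_idx]
            Xte, yte = Xa[test_idx], ya[test_idx]
            if config.standardize_columns:
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                w, b = fit_lasso(Xtr, ytr, float(lam))
                if any(issubclass(c.category, ConvergenceWarning) for c in caught):
                    failed = True
                    break
            pred = Xte @ w.to_numpy() + b
            errs.append(float(np.mean((yte - pred) ** 2)))
        if failed:
            logger.warning("lambda=%g did not converge; skipped", lam)
            cv_mse[float(lam)] = float("nan")
        else:
            cv_mse[float(lam)] = float(np.mean(errs))
    valid = {lam: m for lam, m in cv_mse.items() if np.isfinite(m)}
    if not valid:
        raise RuntimeError("no lambda on the grid converged")
    best_mse = min(valid.values())
    chosen = max(lam for lam, m in valid.items() if m == best_mse)
    w, b = fit_lasso(Xa, ya, chosen)
    w.index = pd.Index(names)
    return LassoResult(chosen_lambda=chosen, cv_mse=cv_mse, weights=w, intercept=b)


def fit_at_lambda(X, y, lam: float) -> LassoResult:
    """Fit at one fixed penalty (figure-reproduction mode); no CV curve."""
    w, b = fit_lasso(X, y, lam)
    return LassoResult(chosen_lambda=float(lam), cv_mse={}, weights=w, intercept=b)


def select_features(result: LassoResult, top_k: int | None = None) -> list[str]:
    """Nonzero features ranked by |w| descending (stable name tie-break)."""
    ranked = result.ranked_features
    return ranked if top_k is None else ranked[:top_k]


def export_ranked_features(result: LassoResult) -> pd.DataFrame:
    """CSV-ready table: feature, weight, rank (1 = largest |w|)."""
    ranked = result.ranked_features
    return pd.DataFrame(
        {
            "feature": ranked,
            "weight": [result.weights[f] for f in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
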