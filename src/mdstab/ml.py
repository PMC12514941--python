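"""Lightweight learned re-ranking of mutations from scaled metrics.

The module's contribution is the evaluation harness, not the estimators:
any scikit-learn style classifier (``fit`` + ``predict_proba``) or
regressor (``fit`` + ``predict``) can be plugged in.  Models are scored
with repeated stratified k-fold cross-validation (4 splits, 10 repeats
by default); test-fold predictions are pooled per repeat and the mean
unweighted and ΔTm-weighted AUCs across repeats are reported.  Grid
search optimizes the average of the two AUCs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import roc, weighted_roc

__all__ = [
    "FeatureMatrix",
    "CrossValResult",
    "default_estimators",
    "cross_validate",
    "grid_search",
]


@dataclass
class FeatureMatrix:
    """Scaled metric columns (rows = mutations) plus labels.

    Classification uses binary stabilizing/not labels for every mutation;
    regression uses measured ΔTm on the labeled subset only.
    """

    features: pd.DataFrame
    delta_tm: pd.Series  # NaN allowed only for classification rows with labels
    labels: pd.Series | None = None  # binary; derived from delta_tm when absent
    threshold: float = 0.0

    def __post_init__(self):
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is None:
            self.labels = (self.delta_tm > self.threshold).astype(int)

    @classmethod
    def from_metric_table(cls, table: pd.DataFrame, delta_tm: pd.Series, **kw) -> "FeatureMatrix":
        cols = [c for c in table.columns if c.startswith("scaled:")]
        return cls(features=table[cols], delta_tm=delta_tm.reindex(table.index), **kw)


@dataclass
class CrossValResult:
    mean_auc: float
    mean_weighted_auc: float
    per_repeat_auc: list[float]
    per_repeat_weighted_auc: list[float]

    @property
    def objective(self) -> float:
        """The tuning objective: average of unweighted and weighted AUC."""
        return 0.5 * (self.mean_auc + self.mean_weighted_auc)


def default_estimators(task: str, seed: int = 0) -> dict[str, object]:
    """The six stock estimators: SVC/KNC/RFC and SVR/Ridge/RFR."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.linear_model import Ridge
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC, SVR

    if task == "classify":
        return {
            "svc": SVC(probability=True, random_state=seed),
            "knc": KNeighborsClassifier(),
            "rfc": RandomForestClassifier(random_state=seed),
        }
    if task == "regress":
        return {
            "svr": SVR(),
            "ridge": Ridge(),
            "rfr": RandomForestRegressor(random_state=seed),
        }
    raise ValueError(f"unknown task {task!r}; use 'classify' or 'regress'")


def _predict_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.predict(X)


def cross_validate(
    features,
    labels,
    estimator,
    n_splits: int = 4,
    n_repeats: int = 10,
    seed: int = 0,
    delta_tm=None,
) -> CrossValResult:
    """Repeated stratified k-fold evaluation of one estimator.

    Fold assignment depends only on the labels and the seed.  Rankings
    come from class probabilities (classifiers) or predicted ΔTm
    (regressors); regression labels are stratified by their binary
    stabilizing/non-stabilizing bin.  Weighted AUC is reported when
    ``delta_tm`` is given (required for regression, where it is also the
    training target).
    """
    from sklearn.base import clone, is_classifier
    from sklearn.model_selection import RepeatedStratifiedKFold

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    dtm = None if delta_tm is None else np.asarray(delta_tm, dtype=float)
    strata = y if set(np.unique(y)) <= {0, 1} else (y > 0).astype(int)
    classification = is_classifier(estimator)
    target = y if classification else dtm
    if target is None:
        raise ValueError("regression needs delta_tm as the training target")
    counts = np.bincount((y if classification else (dtm > 0).astype(int)))
    if counts.min() < n_splits:
        raise ValueError(
            f"infeasible stratification: class counts {counts.tolist()} < {n_splits} splits"
        )
    if not classification:
        strata = (dtm > 0).astype(int)

    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    aucs, w_aucs = [], []
    pooled_scores = np.empty(len(y))
    for rep, splits in enumerate(_grouped(cv.split(X, strata), n_splits)):
        pooled_scores[:] = np.nan
        for train, test in splits:
            est = clone(estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=seed + rep)
            est.fit(X[train], target[train])
            pooled_scores[test] = _predict_scores(est, X[test])
        positive = y.astype(bool)
        aucs.append(roc(pooled_scores, positive).auc)
        if dtm is not None:
            w_aucs.append(weighted_roc(pooled_scores, positive, delta_tm=dtm).auc)
    return CrossValResult(
        mean_auc=float(np.mean(aucs)),
        mean_weighted_auc=float(np.mean(w_aucs)) if w_aucs else float("nan"),
        per_repeat_auc=aucs,
        per_repeat_weighted_auc=w_aucs,
    )


def _grouped(split_iter, n_splits: int):
    batch = []
    for item in split_iter:
        batch.append(item)
        if len(batch) == n_splits:
            yield batch
            batch = []


def grid_search(
    features,
    labels,
    estimator,
    grid: dict[str, list],
    seed: int = 0,
    delta_tm=None,
    **cv_kwargs,
) -> tuple[dict, CrossValResult]:
    """Exhaustive hyperparameter search maximizing (AUC + weighted AUC)/2
    (plain AUC when no ΔTm is available); ties keep the first grid entry."""
    if not grid:
        raise ValueError("grid must be non-empty")
    from sklearn.base import clone

    best = None
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        est = clone(estimator).set_params(**params)
        result = cross_validate(features, labels, est, seed=seed, delta_tm=delta_tm, **cv_kwargs)
        objective = result.objective if np.isfinite(result.objective) else result.mean_auc
        if best is None or objective > best[2]:
            best = (params, result, objective)
    return best[0], best[1]
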