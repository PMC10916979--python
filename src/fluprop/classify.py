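"""Subject-level probabilistic discrimination.

A logistic-regression harness for small clinical cohorts: stratified 5-fold
cross-validation repeated over many random partitions (1000 by default),
with min-max normalization and K-nearest-neighbor imputation (uniform
weights, K = 5) fitted on the training folds only and applied to the test
fold.  Performance is the mean and SD over iterations of the pooled
out-of-fold AUC and of accuracy at a 0.5 decision boundary; feature
importances are mean absolute logistic coefficients over all fold models;
each subject's output score is its out-of-fold probability averaged over
iterations.

Classifier hyperparameters are pinned explicitly (L2 penalty, C = 1.0,
fitted intercept, lbfgs, iteration cap 1000) so behavior does not drift
with library defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from fluprop.featurize import PROPERTIES, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    folds: int = 5
    iterations: int = 1000
    knn_k: int = 5
    seed: int = 0
    C: float = 1.0
    penalty: str = "l2"
    max_iter: int = 1000


@dataclass
class ClassifierReport:
    """Aggregated results of one iterated cross-validation run."""

    feature_set: str
    feature_names: list[str]
    auc_mean: float
    auc_sd: float
    accuracy_mean: float
    accuracy_sd: float
    importances: pd.Series  # mean |coefficient| per feature
    subject_scores: pd.Series  # iteration-averaged out-of-fold score in [0, 1]
    n_iterations: int
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "importances": self.importances.to_dict(),
            "subject_scores": self.subject_scores.to_dict(),
            "n_iterations": self.n_iterations,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def preprocess_fold(
    X_train: np.ndarray, X_test: np.ndarray, knn_k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max scale then KNN-impute, fitting on the training rows only.

    Test values are clipped to [0, 1] after scaling; observed cells are
    never altered by imputation.  Exposed as a standalone step so the fit
    scope (no test-fold leakage) is directly checkable.
    """
    scaler = MinMaxScaler()
    Xtr = scaler.fit_transform(X_train)
    Xte = np.clip(scaler.transform(X_test), 0.0, 1.0)
    imputer = KNNImputer(n_neighbors=min(knn_k, len(X_train)), weights="uniform")
    Xtr = imputer.fit_transform(Xtr)
    Xte = imputer.transform(Xte)
    return Xtr, Xte


def _resolve_features(matrix: FeatureMatrix, feature_set: str) -> list[str]:
    if feature_set == "all":
        return matrix.property_columns
    if feature_set in PROPERTIES:
        meta = matrix.column_meta
        cols = list(meta.index[(meta["kind"] == "property") & (meta["property"] == feature_set)])
        if not cols:
            raise ValueError(f"no columns for property {feature_set!r}")
        return cols
    raise ValueError(f"feature_set must be 'all' or one of {PROPERTIES}, got {feature_set!r}")


def run_classifier(
    matrix: FeatureMatrix,
    labels: pd.Series,
    feature_set: str = "all",
    config: ClassifierConfig | None = None,
) -> ClassifierReport:
    """Iterated stratified cross-validated logistic regression.

    ``labels`` maps participant id to one of two group labels; participants
    absent from ``labels`` are excluded.  Per iteration a fresh random
    stratified partition is drawn; per fold, scaling and imputation are
    fitted on the training folds and applied to the held-out fold, the
    logistic model is fitted, and out-of-fold probabilities are pooled
    within the iteration for AUC and accuracy (0.5 boundary).
    """
    config = config or ClassifierConfig()
    labels = labels.dropna()
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    ids = [pid for pid in matrix.data.index if pid in set(labels.index)]
    cols = _resolve_features(matrix, feature_set)
    X = matrix.data.loc[ids, cols].to_numpy(dtype=float)
    y = (labels.loc[ids] == classes[1]).to_numpy(dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < config.folds:
        raise ValueError(
            f"each class needs at least {config.folds} participants for {config.folds}-fold CV"
        )
    drop = np.isnan(X).all(axis=0)
    if drop.any():
        logger.warning("dropping %d all-missing feature columns", int(drop.sum()))
        cols = [c for c, d in zip(cols, drop) if not d]
        X = X[:, ~drop]

    rng = np.random.default_rng(config.seed)
    n = len(y)
    aucs = np.empty(config.iterations)
    accs = np.empty(config.iterations)
    coef_sum = np.zeros(X.shape[1])
    coef_n = 0
    score_sum = np.zeros(n)

    for it in range(config.iterations):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=fold_seed)
        scores = np.empty(n)
        for train_idx, test_idx in skf.split(X, y):
            # stratification guarantees both classes in every training split
            Xtr, Xte = preprocess_fold(X[train_idx], X[test_idx], config.knn_k)
            # L2 penalty is the sklearn default; passing `penalty` explicitly
            # is deprecated, so only non-default choices are forwarded
            kw = {} if config.penalty == "l2" else {"penalty": config.penalty}
            clf = LogisticRegression(
                C=config.C,
                fit_intercept=True,
                solver="lbfgs",
                max_iter=config.max_iter,
                **kw,
            )
            clf.fit(Xtr, y[train_idx])
            scores[test_idx] = clf.predict_proba(Xte)[:, 1]
            coef_sum += np.abs(clf.coef_[0])
            coef_n += 1
        aucs[it] = roc_auc_score(y, scores)
        accs[it] = float(np.mean((scores >= 0.5) == y))
        score_sum += scores

    return ClassifierReport(
        feature_set=feature_set,
        feature_names=cols,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if config.iterations > 1 else 0.0,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if config.iterations > 1 else 0.0,
        importances=pd.Series(coef_sum / coef_n, index=cols).sort_values(ascending=False),
        subject_scores=pd.Series(score_sum / config.iterations, index=pd.Index(ids)),
        n_iterations=config.iterations,
        n_folds=config.folds,
        seed=config.seed,
    )


def feature_set_battery(
    matrix: FeatureMatrix,
    labels: pd.Series,
    config: ClassifierConfig | None = None,
) -> list[ClassifierReport]:
    """One classifier per word property plus the all-features classifier.

    Returns 7 reports (6 single-property, 7 features each; one combined,
    42 features), the input for a radar plot of per-property AUC.
    """
    reports = [run_classifier(matrix, labels, prop, config) for prop in PROPERTIES]
    reports.append(run_classifier(matrix, labels, "all", config))
    return reports
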