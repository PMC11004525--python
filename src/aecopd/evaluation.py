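"""Stratified cross-validated comparison of predictors across phase variants.

Each (predictor, phase variant, extractor set) cell is evaluated with
stratified k-fold cross-validation (default k = 5).  Feature selection is
re-fitted inside every training fold by default; ``paper_mode=True``
reproduces the original study's fit-on-all-patients behaviour.  Models are
re-initialized in every fold.  Metrics: accuracy, macro-averaged precision and
F1 (per-class values kept alongside), and the rank-based AUC (ties counted
one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import amgnn as ag
from .feature_table import FeatureTable, PhaseVariant, apply_phase_variant
from .selection import glm_rank_risk_factors, make_lasso_selector

__all__ = [
    "stratified_folds",
    "metrics",
    "baseline_fit_predict",
    "run_experiment",
    "MetricsReport",
    "paired_ttest",
    "BASELINES",
]

BASELINES = ("RF", "MLP", "LDA", "SVM")
METRIC_NAMES = ("accuracy", "precision", "f1", "auc")


class EvaluationError(ValueError):
    pass


def stratified_folds(labels, k: int = 5, seed: int = 0) -> List[np.ndarray]:
    """k disjoint row-index sets partitioning all rows, stratified by label."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise EvaluationError("k must be >= 2 (k=1 leaves no held-out data)")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise EvaluationError(
            f"smallest class has {counts.min()} rows; need at least k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def metrics(y_true, y_pred, y_score):
    """(accuracy, macro precision, macro F1, AUC) for a binary outcome.

    AUC is the Mann-Whitney rank statistic of the class-1 scores (ties count
    one half); with a single-class ``y_true`` it is undefined and reported as
    NaN with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if not len(y_true) == len(y_pred) == len(y_score):
        raise EvaluationError("y_true, y_pred, y_score must have equal length")
    acc = accuracy_score(y_true, y_pred)
    prec = precision_score(y_true, y_pred, average="macro", zero_division=0)
    f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
    if len(np.unique(y_true)) < 2:
        warnings.warn("AUC undefined for single-class y_true; reporting NaN")
        auc = float("nan")
    else:
        auc = roc_auc_score(y_true, y_score)
    return float(acc), float(prec), float(f1), float(auc)


def baseline_fit_predict(name: str, X_train, y_train, X_test, seed: int = 0):
    """Fit one classic ML baseline and score the test rows.

    Fixed hyperparameters: RF 200 trees; MLP one 64-unit hidden layer;
    LDA (svd solver); RBF-SVM with Platt-scaled probabilities.  Features are
    standardized with training statistics for the scale-sensitive models.
    Returns ``(predictions, class-1 probabilities)``.
    """
    if name not in BASELINES:
        raise EvaluationError(
            f"unknown baseline {name!r}; options: {', '.join(BASELINES)}"
        )
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if name == "RF":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif name == "MLP":
        clf = MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=800, random_state=seed
        )
    elif name == "LDA":
        clf = LinearDiscriminantAnalysis()
    else:  # SVM
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    if name in ("MLP", "LDA", "SVM"):
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, 1]
    preds = (scores > 0.5).astype(int)
    return preds, scores


@dataclass
class MetricsReport:
    """Per-fold and aggregated metrics for one experiment cell."""

    predictor: str
    variant: str
    extractor_set: str
    seed: int
    fold_metrics: List[Dict[str, float]] = field(default_factory=list)
    mean: Dict[str, float] = field(default_factory=dict)
    sd: Dict[str, float] = field(default_factory=dict)

    def aggregate(self):
        for m in METRIC_NAMES:
            vals = np.array([f[m] for f in self.fold_metrics], dtype=float)
            vals = vals[np.isfinite(vals)]
            self.mean[m] = float(vals.mean()) if vals.size else float("nan")
            self.sd[m] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return self


def _amgnn_fold(matrix, labels, train_rows, test_rows, seed, amgnn_config, k_risk):
    y_train = labels[train_rows]
    X_train = matrix[train_rows]
    kk = min(k_risk, X_train.shape[1])
    risk = glm_rank_risk_factors(X_train, y_train, k=kk)
    cfg_kw = dict(amgnn_config or {})
    cfg_kw.setdefault("seed", seed)
    cfg = ag.AMGNNConfig(**cfg_kw)
    model = ag.train(X_train, y_train, risk, cfg)
    probs, preds = ag.predict(model, matrix[test_rows], seed=seed + 1)
    return preds, probs[:, 1]


def run_experiment(
    table: FeatureTable,
    predictors: Sequence[str],
    variants: Sequence[PhaseVariant],
    extractor_sets: Optional[Sequence[str]] = None,
    k: int = 5,
    seed: int = 0,
    paper_mode: bool = False,
    cv_folds_selection: int = 10,
    amgnn_config: Optional[dict] = None,
    k_risk: int = 3,
) -> List[MetricsReport]:
    """Cross-validated grid over predictors x variants (x extractor sets).

    All cells share the same stratified folds (one seed).  Within a fold the
    selector sees training rows only unless ``paper_mode``; every model is
    re-initialized per fold.
    """
    labels = table.labels
    folds = stratified_folds(labels, k=k, seed=seed)
    all_rows = np.arange(table.n_patients)
    selector = make_lasso_selector(cv_folds=cv_folds_selection, seed=seed)
    reports = []
    for variant in variants:
        if extractor_sets is not None and variant.extractor_set not in extractor_sets:
            continue
        # cache variant assembly per fold (shared by all predictors)
        per_fold = []
        for test_rows in folds:
            train_rows = np.setdiff1d(all_rows, test_rows)
            sel_rows = None if paper_mode else train_rows
            res = apply_phase_variant(table, variant, selector, train_rows=sel_rows)
            per_fold.append((train_rows, test_rows, res))
        for predictor in predictors:
            rep = MetricsReport(
                predictor=predictor,
                variant=variant.name,
                extractor_set=variant.extractor_set,
                seed=seed,
            )
            for train_rows, test_rows, res in per_fold:
                try:
                    if predictor.upper() == "AMGNN":
                        preds, scores = _amgnn_fold(
                            res.matrix, labels, train_rows, test_rows,
                            seed, amgnn_config, k_risk,
                        )
                    else:
                        preds, scores = baseline_fit_predict(
                            predictor.upper(),
                            res.matrix[train_rows],
                            labels[train_rows],
                            res.matrix[test_rows],
                            seed=seed,
                        )
                except Exception as exc:
                    raise EvaluationError(
                        f"cell (predictor={predictor}, variant={variant.name}, "
                        f"extractors={variant.extractor_set}) failed: {exc}"
                    ) from exc
                acc, prec, f1, auc = metrics(labels[test_rows], preds, scores)
                rep.fold_metrics.append(
                    {"accuracy": acc, "precision": prec, "f1": f1, "auc": auc}
                )
            reports.append(rep.aggregate())
    return reports


def paired_ttest(report_a: MetricsReport, report_b: MetricsReport, metric: str = "accuracy"):
    """Paired two-sided t-test over per-fold metric values of two cells."""
    a = np.array([f[metric] for f in report_a.fold_metrics])
    b = np.array([f[metric] for f in report_b.fold_metrics])
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)
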