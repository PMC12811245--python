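"""Treatment-response prediction from the 132 mPFC→PCC EC connections.

Classification (responder vs non-responder): within every training fold the
features are z-scored, recursive feature elimination (RFE) with an
L1-regularized linear model prunes the 132 connections down to 38, and a
linear SVM (C = 5, balanced class weights) is trained; test-fold metrics
(accuracy, AUC, sensitivity, specificity, f1, MCC) are averaged over the
five stratified folds and over repeated reshuffles (100 repeats by
default). Significance comes from a label-permutation test that reruns the
whole pipeline — selection included — per shuffle.

Regression (HAMD-17 change = pre − post): linear-kernel SVR (C = 9), same
within-fold scaling and RFE, metrics (Pearson r, MAE, RMSE) on pooled
out-of-fold predictions.

Scaling and feature selection are always refit inside the training fold;
a leakage-prone "global" selection mode exists only as an explicit flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "PredictionReport",
    "rfe_select",
    "cv_classify",
    "permutation_test",
    "cv_regress",
    "classification_metrics",
]

_CLS_METRICS = ("accuracy", "auc", "sensitivity", "specificity", "f1", "mcc")


@dataclass
class PredictionReport:
    """Cross-validated prediction results.

    ``metrics`` are means over all folds of all repeats; ``metric_sd`` the
    standard deviation of the per-repeat means; ``per_fold`` keeps every
    fold's raw metrics and selected feature indices.
    """

    task: str
    metrics: dict[str, float]
    metric_sd: dict[str, float] = field(default_factory=dict)
    per_fold: list[dict] = field(default_factory=list)
    selected_feature_indices: list[list[int]] = field(default_factory=list)
    n_subjects: int = 0
    n_features: int = 0
    params: dict = field(default_factory=dict)
    permutation_p: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task, "metrics": self.metrics,
            "metric_sd": self.metric_sd, "n_subjects": self.n_subjects,
            "n_features": self.n_features, "params": self.params,
            "permutation_p": self.permutation_p, "seed": self.seed,
        }


def _selection_weights(x: np.ndarray, y: np.ndarray, task: str) -> np.ndarray:
    if task == "classify":
        model = LogisticRegression(penalty="l1", solver="liblinear", C=1.0,
                                   class_weight="balanced", tol=1e-3,
                                   max_iter=200, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
        return np.abs(model.coef_).ravel()
    model = Lasso(alpha=0.01, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return np.abs(model.coef_).ravel()


def rfe_select(features: np.ndarray, labels: np.ndarray, n_keep: int = 38,
               task: str = "classify") -> np.ndarray:
    """Recursive feature elimination with L1-regularized linear weights.

    The model is refit each round and the feature with the smallest
    absolute weight is dropped until ``n_keep`` remain; weight ties are
    broken by dropping the lowest column index. Deterministic given the
    data.

    Returns the retained column indices, ascending.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, p = x.shape
    if n < 20:
        raise ValueError(f"need n ≥ 20 subjects, got {n}")
    if task == "classify" and np.unique(y).size < 2:
        raise ValueError("need two classes for classification RFE")
    if n_keep >= p:
        raise ValueError(f"n_keep={n_keep} must be smaller than the "
                         f"{p} available features")
    active = list(range(p))
    while len(active) > n_keep:
        w = _selection_weights(x[:, active], y, task)
        drop_pos = int(np.flatnonzero(w == w.min())[0])
        del active[drop_pos]
    return np.array(active)


def classification_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """Standard binary metrics; responder (1) is the positive class.

    AUC is the rank statistic over decision scores. MCC uses the convention
    that a zero denominator factor yields 0. Single-class truth makes
    sensitivity/specificity/AUC undefined — returned as NaN with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    single_class = (tp + fn == 0) or (tn + fp == 0)
    if single_class:
        warnings.warn("single-class truth: sensitivity/specificity/AUC undefined")
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    if scores is not None and not single_class:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    else:
        auc = np.nan
    return {"accuracy": acc, "auc": auc, "sensitivity": sens,
            "specificity": spec, "f1": f1, "mcc": float(mcc)}


def _check_classes(y: np.ndarray, folds: int) -> None:
    values, counts = np.unique(y, return_counts=True)
    if values.size != 2:
        raise ValueError(f"need exactly 2 classes, got {values.tolist()}")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need ≥ {folds} "
            "for stratified folding"
        )


def _drop_constant(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.flatnonzero(x.std(axis=0) > 0)
    if keep.size < x.shape[1]:
        warnings.warn(f"dropping {x.shape[1] - keep.size} constant feature column(s)")
    return x[:, keep], keep


def cv_classify(
    features: np.ndarray, labels: np.ndarray, n_keep: int = 38, C: float = 5.0,
    folds: int = 5, repeats: int = 100, seed: int = 0,
    selection: str = "per_fold",
) -> PredictionReport:
    """Repeated stratified 5-fold linear-SVM classification (see module
    docstring). ``selection="global"`` reproduces the leakage-prone variant
    that selects features once on the full sample before cross-validation.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_classes(y, folds)
    x, kept_cols = _drop_constant(x)
    global_sel = None
    if selection == "global":
        global_sel = rfe_select(StandardScaler().fit_transform(x), y, n_keep)
    elif selection != "per_fold":
        raise ValueError(f"unknown selection mode {selection!r}")

    per_fold, selected, repeat_means = [], [], []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + rep) % 2**31)
        fold_rows = []
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            scaler = StandardScaler().fit(x[tr])
            xtr, xte = scaler.transform(x[tr]), scaler.transform(x[te])
            sel = global_sel if global_sel is not None else rfe_select(xtr, y[tr], n_keep)
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            clf.fit(xtr[:, sel], y[tr])
            scores = clf.decision_function(xte[:, sel])
            m = classification_metrics(y[te], clf.predict(xte[:, sel]), scores)
            m.update(repeat=rep, fold=fold)
            fold_rows.append(m)
            selected.append(kept_cols[sel].tolist())
        per_fold.extend(fold_rows)
        repeat_means.append({k: np.nanmean([r[k] for r in fold_rows])
                             for k in _CLS_METRICS})
    metrics = {k: float(np.mean([r[k] for r in repeat_means])) for k in _CLS_METRICS}
    sds = {k: float(np.std([r[k] for r in repeat_means], ddof=1)) if repeats > 1
           else 0.0 for k in _CLS_METRICS}
    return PredictionReport(
        task="classify", metrics=metrics, metric_sd=sds, per_fold=per_fold,
        selected_feature_indices=selected, n_subjects=x.shape[0],
        n_features=x.shape[1],
        params={"n_keep": n_keep, "C": C, "folds": folds, "repeats": repeats,
                "selection": selection},
        seed=seed,
    )


def permutation_test(
    features: np.ndarray, labels: np.ndarray, observed_accuracy: float,
    n_perm: int = 1000, seed: int = 0, n_keep: int = 38, C: float = 5.0,
    folds: int = 5, repeats: int = 1,
) -> float:
    """Label-permutation significance of the cross-validated accuracy.

    Each permutation shuffles the response labels and reruns the full
    cross-validated pipeline, feature selection included; the p-value is
    the proportion of permuted accuracies strictly exceeding the observed
    one.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a minimum resolvable p of "
                      f"{1 / n_perm:.3g}; consider ≥ 100 permutations")
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    exceed = 0
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        rep = cv_classify(features, y_perm, n_keep=n_keep, C=C, folds=folds,
                          repeats=repeats, seed=(seed + 1 + i) % 2**31)
        if rep.metrics["accuracy"] > observed_accuracy:
            exceed += 1
    return exceed / n_perm


def cv_regress(
    features: np.ndarray, delta_hamd: np.ndarray, n_keep: int = 38,
    C: float = 9.0, folds: int = 5, seed: int = 0, epsilon: float = 0.1,
    selection: str = "per_fold",
) -> PredictionReport:
    """Linear-kernel SVR of the HAMD-17 change, 5-fold CV with within-fold
    scaling and RFE; Pearson r, MAE and RMSE on pooled out-of-fold
    predictions. ``selection="global"`` selects the connections once on the
    full sample before cross-validation (the leakage-prone protocol
    variant, kept for replication)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(delta_hamd, dtype=float)
    if x.shape[0] < 30:
        raise ValueError(f"need n ≥ 30 subjects, got {x.shape[0]}")
    if np.std(y) == 0:
        raise ValueError("constant target: regression undefined")
    x, kept_cols = _drop_constant(x)
    global_sel = None
    if selection == "global":
        global_sel = rfe_select(StandardScaler().fit_transform(x), y, n_keep,
                                task="regress")
    elif selection != "per_fold":
        raise ValueError(f"unknown selection mode {selection!r}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    pred = np.empty_like(y)
    per_fold, selected = [], []
    for fold, (tr, te) in enumerate(kf.split(x)):
        scaler = StandardScaler().fit(x[tr])
        xtr, xte = scaler.transform(x[tr]), scaler.transform(x[te])
        sel = global_sel if global_sel is not None else \
            rfe_select(xtr, y[tr], n_keep, task="regress")
        reg = SVR(kernel="linear", C=C, epsilon=epsilon)
        reg.fit(xtr[:, sel], y[tr])
        pred[te] = reg.predict(xte[:, sel])
        per_fold.append({"fold": fold, "n_test": te.size})
        selected.append(kept_cols[sel].tolist())
    resid = y - pred
    r = float(np.corrcoef(y, pred)[0, 1]) if np.std(pred) > 0 else 0.0
    metrics = {
        "pearson_r": r,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }
    return PredictionReport(
        task="regress", metrics=metrics, per_fold=per_fold,
        selected_feature_indices=selected, n_subjects=x.shape[0],
        n_features=x.shape[1],
        params={"n_keep": n_keep, "C": C, "folds": folds, "epsilon": epsilon,
                "selection": selection},
        seed=seed,
    )
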