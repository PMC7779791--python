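"""Linear-SVM discrimination of injured vs. healthy under repeated
stratified cross-validation, with vertically averaged ROC curves.

Protocol: 50 permutations of stratified 5-fold CV.  Per permutation the
test-fold decision scores are pooled, giving one confusion matrix, one ROC
and one AUC per permutation; metrics are then aggregated as mean +- STDV
over permutations.  Features are z-scored with training-fold statistics
only.  "Realistic balanced class priors" is implemented as inverse
class-frequency weighting inside the SVM loss; the regularization constant
is fixed at C=1 (not tuned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["CVReport", "balanced_accuracy", "standardize_train_test",
           "mean_roc", "run_cv_svm", "DEFAULT_FPR_GRID"]

POSITIVE_LABEL = "injured"

DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """(sensitivity + specificity) / 2 from confusion counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy undefined for an empty class")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def standardize_train_test(X_train: np.ndarray, X_test: np.ndarray):
    """z-score both sets using training statistics only.

    Returns ``(Z_train, Z_test, mean, sd)``; constant columns get sd 1 so
    they pass through centred (callers drop them beforehand).
    """
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    return ((X_train - mean) / sd_safe, (X_test - mean) / sd_safe, mean, sd)


def mean_roc(per_permutation_scores, per_permutation_labels,
             fpr_grid=DEFAULT_FPR_GRID):
    """Vertical ROC averaging over permutations.

    Per permutation: empirical ROC from pooled scores, TPR interpolated
    onto the shared FPR grid; AUC by trapezoid on that permutation's own
    curve.  Returns ``(mean_tpr, auc_mean, auc_std, per_perm_auc)``.
    """
    tprs, aucs = [], []
    for scores, y in zip(per_permutation_scores, per_permutation_labels):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("ROC undefined: scores cover a single class")
        fpr, tpr, _ = roc_curve(y, scores)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        aucs.append(_trapezoid_auc(fpr, tpr))
    if not tprs:
        raise ValueError("need at least one permutation")
    aucs = np.asarray(aucs)
    return (np.mean(tprs, axis=0), float(aucs.mean()),
            float(aucs.std(ddof=0)), aucs)


@dataclass
class CVReport:
    """Repeated-CV classification results."""

    folds: pd.DataFrame          # per (permutation, fold) confusion + metrics
    permutations: pd.DataFrame   # per permutation pooled metrics + AUC
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "folds": self.folds.to_dict(orient="list"),
            "permutations": self.permutations.to_dict(orient="list"),
            "roc": {"fpr": self.fpr_grid.tolist(),
                    "mean_tpr": self.mean_tpr.tolist()},
        }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def run_cv_svm(X, y, n_perm: int = 50, k: int = 5, seed: int = 0,
               C: float = 1.0, class_weight="balanced",
               fpr_grid=DEFAULT_FPR_GRID) -> CVReport:
    """Repeated stratified k-fold CV with a linear-kernel SVM.

    ``X`` is (n_subjects, n_features); ``y`` holds group labels where
    ``"injured"`` (or 1/True) is the positive class.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y01 = (y == POSITIVE_LABEL).astype(int)
    else:
        y01 = y.astype(int)
    counts = np.bincount(y01, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members, got counts {counts.tolist()}")

    const = X.std(axis=0) == 0.0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant feature(s)",
                      RuntimeWarning, stacklevel=2)
        X = X[:, ~const]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features remain")

    ss = np.random.SeedSequence(seed)
    perm_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_perm)]

    fold_rows, perm_rows = [], []
    perm_scores, perm_truth = [], []
    for perm, ps in enumerate(perm_seeds):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=ps)
        pooled_scores = np.empty(len(y01))
        pooled_pred = np.empty(len(y01), dtype=int)
        for fold, (tr, te) in enumerate(skf.split(X, y01)):
            Ztr, Zte, _, _ = standardize_train_test(X[tr], X[te])
            clf = SVC(kernel="linear", C=C, class_weight=class_weight)
            clf.fit(Ztr, y01[tr])
            pred = clf.predict(Zte)
            pooled_pred[te] = pred
            pooled_scores[te] = clf.decision_function(Zte)
            tp, fp, tn, fn = _confusion(y01[te], pred)
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (tn + fp) if tn + fp else np.nan
            fold_rows.append({
                "permutation": perm, "fold": fold,
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "sensitivity": sens, "specificity": spec,
                "balanced_accuracy": (sens + spec) / 2.0,
            })
        tp, fp, tn, fn = _confusion(y01, pooled_pred)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        perm_rows.append({
            "permutation": perm, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": balanced_accuracy(tp, fp, tn, fn),
        })
        perm_scores.append(pooled_scores)
        perm_truth.append(y01)

    mean_tpr, auc_mean, auc_std, aucs = mean_roc(perm_scores, perm_truth,
                                                 fpr_grid)
    permutations = pd.DataFrame(perm_rows)
    permutations["auc"] = aucs
    summary = {}
    for metric in ("balanced_accuracy", "sensitivity", "specificity", "auc"):
        vals = permutations[metric].to_numpy()
        summary[f"{metric}_mean"] = float(vals.mean())
        summary[f"{metric}_std"] = float(vals.std(ddof=0))
    return CVReport(pd.DataFrame(fold_rows), permutations,
                    np.asarray(fpr_grid, dtype=float), mean_tpr, summary)
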