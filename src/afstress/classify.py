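"""Outcome classification: recurrence prediction from patient signatures.

Four classifiers (KNN, SVM, random forest, logistic regression), each
with and without PCA preprocessing (components chosen to retain 95% of
the training-fold variance), compared over stratified k-fold
cross-validation on three nested feature sets. All preprocessing is fit
on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .battery import HISTORY_COLUMNS, IMAGING_COLUMNS

FEATURE_SETS = ("sim_imaging_history", "imaging_history", "history")
CLASSIFIERS = ("knn", "svm", "rf", "logreg")  # fixed tie-break order
PCA_VARIANCE = 0.95


def resolve_feature_set(columns, feature_set: str) -> list:
    """Columns belonging to a nested feature set, in signature order.

    ``history`` < ``imaging_history`` < ``sim_imaging_history`` as column
    sets; simulation columns are the per-setup ``s<i>_*`` metrics.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    history = [c for c in columns if c in HISTORY_COLUMNS]
    imaging = [c for c in columns if c in IMAGING_COLUMNS]
    sim = [c for c in columns
           if c.startswith("s") and ("_pre_" in c or "_post_" in c)]
    if feature_set == "history":
        return history
    if feature_set == "imaging_history":
        return imaging + history
    return sim + imaging + history


def _make_classifier(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "logreg":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def _scores_and_preds(clf, X):
    if hasattr(clf, "predict_proba"):
        s = clf.predict_proba(X)[:, 1]
        return s, (s >= 0.5).astype(int)
    s = clf.decision_function(X)
    return s, (s >= 0.0).astype(int)


def fit_evaluate(table: pd.DataFrame, labels, feature_set: str,
                 classifier: str, use_pca: bool, folds: int = 10,
                 seed: int = 0) -> dict:
    """Cross-validated metrics for one (feature set, classifier, pca) cell.

    Standardization and (optional) PCA are fit within each training fold
    only. Returns per-fold arrays of roc_auc/accuracy/recall/precision
    and the fold assignment of every sample. Raises if stratification
    cannot put both classes in every fold.
    """
    cols = resolve_feature_set(table.columns, feature_set)
    X = table[cols].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.isnan(X).any():
        raise ValueError("signature table contains missing cells")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < folds:
        raise ValueError("insufficient class balance: a fold would miss a class")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(len(y), -1)
    out = {m: [] for m in ("roc_auc", "accuracy", "recall", "precision")}
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fold_of[te] = k
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        if use_pca:
            pca = PCA(n_components=PCA_VARIANCE, svd_solver="full").fit(Xtr)
            Xtr, Xte = pca.transform(Xtr), pca.transform(Xte)
        clf = _make_classifier(classifier, seed).fit(Xtr, y[tr])
        scores, preds = _scores_and_preds(clf, Xte)
        yt = y[te]
        if len(np.unique(yt)) == 2:
            out["roc_auc"].append(roc_curve(scores, yt)["auc"])
        else:  # unreachable with stratified folds; keep metrics aligned
            out["roc_auc"].append(np.nan)
        out["accuracy"].append(float(np.mean(preds == yt)))
        tp = int(((preds == 1) & (yt == 1)).sum())
        out["recall"].append(tp / max(int((yt == 1).sum()), 1))
        out["precision"].append(tp / max(int((preds == 1).sum()), 1)
                                if (preds == 1).any() else 0.0)
    return {m: np.asarray(v) for m, v in out.items()} | {"fold_of": fold_of}


@dataclass
class ClassifierReport:
    """Cross-validated comparison grid and the selected model."""

    feature_set: str
    grid: pd.DataFrame            # rows: classifier x pca, mean/sd metrics
    selected_classifier: str
    selected_pca: bool
    folds: int
    seed: int

    @property
    def selected_auc(self) -> float:
        m = self.grid
        row = m[(m["classifier"] == self.selected_classifier)
                & (m["pca"] == self.selected_pca)]
        return float(row["roc_auc_mean"].iloc[0])


def compare_and_select(table: pd.DataFrame, labels, feature_set: str,
                       folds: int = 10, seed: int = 0) -> ClassifierReport:
    """Evaluate all 4 classifiers x {pca, no pca} on identical folds and
    select the largest mean ROC AUC (ties: higher accuracy, then fixed
    classifier order, no-PCA before PCA)."""
    records = []
    for name in CLASSIFIERS:
        for use_pca in (False, True):
            res = fit_evaluate(table, labels, feature_set, name, use_pca,
                               folds=folds, seed=seed)
            rec = {"classifier": name, "pca": use_pca}
            for m in ("roc_auc", "accuracy", "recall", "precision"):
                rec[f"{m}_mean"] = float(np.nanmean(res[m]))
                rec[f"{m}_sd"] = float(np.nanstd(res[m]))
            records.append(rec)
    grid = pd.DataFrame(records)
    order = grid.sort_values(
        by=["roc_auc_mean", "accuracy_mean"], ascending=False, kind="stable")
    best = order.iloc[0]
    return ClassifierReport(feature_set=feature_set, grid=grid,
                            selected_classifier=str(best["classifier"]),
                            selected_pca=bool(best["pca"]),
                            folds=folds, seed=seed)


def roc_curve(scores, labels) -> dict:
    """Empirical ROC curve and trapezoidal AUC.

    The AUC equals the normalized Mann-Whitney U statistic (pair-counting
    probability that a positive outranks a negative, ties counted half).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": auc}
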