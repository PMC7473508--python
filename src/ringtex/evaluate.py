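"""Cross-validated classification and its evaluation harness.

Three classifiers — kNN (5 neighbours, Euclidean, uniform weights),
SVM with RBF kernel (C = 1) and Random Forest (10 trees, no split of
subsets smaller than 5) — are evaluated under stratified 10-fold
cross-validation.  Features are z-scored with training-fold statistics
only.  The tumoral class is the positive class throughout.

Feature input comes in two modes: ``all`` (the full 63-feature table)
and ``top5`` (the five best-ranked features).  In ``top5`` mode the
ranking is recomputed inside each training fold by default, so the
selection never sees the held-out lesions; ``leaky_top5=True``
reproduces the simpler protocol of ranking once on the full table.

Metrics: AUC (trapezoidal over the pooled cross-validated scores,
equal to the Mann-Whitney statistic), classification accuracy (CA),
F1, precision and recall for the tumor class, plus the ROC points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ranking import rank_and_select

POSITIVE_CLASS = "tumor"
CLASSIFIERS = ("knn", "svm_rbf", "random_forest")
FEATURE_MODES = ("all", "top5")


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of one classifier.

    ``svm_epsilon`` is recorded for fidelity with the original analysis
    configuration but is a regression-loss parameter, inert for
    classification.
    """

    method: str = "random_forest"
    knn_k: int = 5
    knn_metric: str = "euclidean"
    knn_weights: str = "uniform"
    svm_c: float = 1.0
    svm_epsilon: float = 0.10
    rf_n_trees: int = 10
    rf_min_split: int = 5
    seed: int = 0

    def build(self, n_train: int | None = None):
        if self.method == "knn":
            k = self.knn_k if n_train is None else min(self.knn_k, n_train)
            return KNeighborsClassifier(n_neighbors=k,
                                        metric=self.knn_metric,
                                        weights=self.knn_weights)
        if self.method == "svm_rbf":
            return SVC(kernel="rbf", C=self.svm_c)
        if self.method == "random_forest":
            return RandomForestClassifier(n_estimators=self.rf_n_trees,
                                          min_samples_split=self.rf_min_split,
                                          random_state=self.seed)
        raise ValueError(f"unknown classifier method: {self.method!r}")


def stratified_kfold(labels: np.ndarray, k: int = 10,
                     seed: int = 0) -> np.ndarray:
    """Fold index per sample, stratified, deterministic under seed.

    If the smaller class has fewer than k members, k is reduced with a
    warning.  A single-class cohort raises ``ValueError``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cannot stratify a single-class cohort")
    min_count = int(counts.min())
    if min_count < k:
        warnings.warn(f"reducing folds from {k} to {min_count} "
                      f"(smallest class has {min_count} members)")
        k = min_count
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=np.int64)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                      labels)):
        folds[test_idx] = fold_id
    return folds


def _score_positive(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1]: vote fractions for kNN/RF,
    logistic-squashed decision values for the SVM (monotone in the margin)."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos = list(model.classes_).index(POSITIVE_CLASS)
        return proba[:, pos]
    d = model.decision_function(X)
    if list(model.classes_).index(POSITIVE_CLASS) == 0:
        d = -d
    return 1.0 / (1.0 + np.exp(-d))


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec,
                   folds: np.ndarray,
                   feature_columns: list[str] | None = None,
                   select_k: int | None = None,
                   leaky_top5: bool = False) -> pd.DataFrame:
    """Pooled cross-validated predictions for one classifier.

    ``select_k`` switches on fold-internal top-k feature selection;
    ``leaky_top5`` instead ranks once on the full table (the selection
    then leaks label information across folds — kept only as a
    compatibility protocol).

    Returns a frame with lesion_id, fold, y_true, y_pred, score.
    """
    if feature_columns is None:
        feature_columns = [c for c in table.columns
                           if c not in ("lesion_id", "label", "sequence")]
    y = table["label"].to_numpy()
    global_selection = None
    if select_k is not None and leaky_top5:
        global_selection = rank_and_select(
            table, k=select_k, feature_columns=feature_columns).selected

    records = []
    for fold_id in np.unique(folds[folds >= 0]):  # -1 marks train-only rows
        train = folds != fold_id
        test = ~train
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {fold_id} skipped: single-class training set")
            continue
        if select_k is not None:
            cols = global_selection if leaky_top5 else rank_and_select(
                table.loc[train], k=select_k,
                feature_columns=feature_columns).selected
        else:
            cols = feature_columns
        X = table[cols].to_numpy(dtype=float)
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        model = spec.build(n_train=int(train.sum())).fit(Xtr, y[train])
        pred = model.predict(Xte)
        score = _score_positive(model, Xte, np.unique(y))
        for lid, yt, yp, sc in zip(table["lesion_id"].to_numpy()[test],
                                   y[test], pred, score):
            records.append({"lesion_id": lid, "fold": int(fold_id),
                            "y_true": yt, "y_pred": yp, "score": float(sc)})
    return pd.DataFrame(records)


def confusion_metrics(cv: pd.DataFrame) -> dict[str, float]:
    """CA, F1, precision, recall with tumor as the positive class."""
    if len(cv) == 0:
        raise ValueError("no predictions")
    yt = cv["y_true"].to_numpy()
    yp = cv["y_pred"].to_numpy()
    tp = int(np.sum((yt == POSITIVE_CLASS) & (yp == POSITIVE_CLASS)))
    tn = int(np.sum((yt != POSITIVE_CLASS) & (yp != POSITIVE_CLASS)))
    fp = int(np.sum((yt != POSITIVE_CLASS) & (yp == POSITIVE_CLASS)))
    fn = int(np.sum((yt == POSITIVE_CLASS) & (yp != POSITIVE_CLASS)))
    ca = (tp + tn) / len(cv)

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "F1")
    return {"CA": ca, "F1": f1, "precision": precision, "recall": recall}


def roc_auc(cv: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """ROC points by threshold sweep and trapezoidal AUC.

    Equal scores are grouped at one threshold, so all-tied scores give
    the chance diagonal and AUC 0.5.
    """
    yt = cv["y_true"].to_numpy()
    scores = cv["score"].to_numpy(dtype=float)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr, thr = roc_curve(yt, scores, pos_label=POSITIVE_CLASS)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"FPR": fpr, "TPR": tpr, "threshold": thr})
    return points, auc


def holdout_split(labels: np.ndarray, test_fraction: float = 0.25,
                  seed: int = 0) -> np.ndarray:
    """Single stratified train/test split encoded as fold ids.

    Training samples get fold -1 (never held out), test samples fold 0,
    so the same cross-validation machinery evaluates the one split.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                 random_state=seed)
    folds = np.full(len(labels), -1, dtype=np.int64)
    _, test_idx = next(sss.split(np.zeros(len(labels)), labels))
    folds[test_idx] = 0
    return folds


def evaluate_all(table: pd.DataFrame, seed: int = 0, n_folds: int = 10,
                 feature_modes: tuple[str, ...] = FEATURE_MODES,
                 methods: tuple[str, ...] = CLASSIFIERS,
                 select_k: int = 5, leaky_top5: bool = False,
                 protocol: str = "kfold") -> pd.DataFrame:
    """Metric rows for every classifier x feature-mode combination.

    ``protocol`` is ``kfold`` (stratified, default) or ``holdout`` (one
    stratified 75/25 split).  Returns a frame with classifier,
    feature_mode, AUC, CA, F1, precision, recall; ROC points are
    attached in ``attrs['roc']`` keyed by (classifier, feature_mode).
    """
    labels = table["label"].to_numpy()
    if protocol == "kfold":
        folds = stratified_kfold(labels, k=n_folds, seed=seed)
    elif protocol == "holdout":
        folds = holdout_split(labels, seed=seed)
    else:
        raise ValueError(f"unknown CV protocol: {protocol!r}")
    rows, rocs = [], {}
    for method in methods:
        spec = ClassifierSpec(method=method, seed=seed)
        for mode in feature_modes:
            cv = cross_validate(
                table, spec, folds,
                select_k=select_k if mode == "top5" else None,
                leaky_top5=leaky_top5)
            metrics = confusion_metrics(cv)
            roc_points, auc = roc_auc(cv)
            rows.append({"classifier": method, "feature_mode": mode,
                         "AUC": auc, **metrics})
            rocs[(method, mode)] = roc_points
    report = pd.DataFrame(rows)
    report.attrs["roc"] = rocs
    return report


def write_report(report: pd.DataFrame, path: str | Path,
                 roc_path: str | Path | None = None) -> None:
    """JSON metric report; optionally a CSV of all ROC points."""
    path = Path(path)
    payload = report.drop(columns=[], errors="ignore").to_dict(orient="records")
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    if roc_path is not None:
        frames = []
        for (method, mode), pts in report.attrs.get("roc", {}).items():
            f = pts.copy()
            f.insert(0, "feature_mode", mode)
            f.insert(0, "classifier", method)
            frames.append(f)
        if frames:
            pd.concat(frames).to_csv(roc_path, index=False)


def plot_roc(report: pd.DataFrame, path: str | Path,
             feature_mode: str = "top5") -> None:
    """Save ROC curves of the three classifiers for one feature mode."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (method, mode), pts in report.attrs.get("roc", {}).items():
        if mode != feature_mode:
            continue
        auc = report.query("classifier == @method and feature_mode == @mode")[
            "AUC"].iloc[0]
        ax.plot(pts["FPR"], pts["TPR"], label=f"{method} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"ROC ({feature_mode} features)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
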