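"""Classifier training, stratified cross-validation, and evaluation metrics.

Three classifier families are supported: support vector machines (linear,
polynomial, RBF kernels), k-nearest neighbours (default k=1) and random
forests.  Evaluation is stratified 5-fold cross-validation in which *every*
data-dependent step — Bi-profile fitting, min-max normalization, t-test
feature ranking, classifier fitting and optional hyperparameter tuning — is
performed inside the training part of each fold.

Metrics follow the usual confusion-matrix closed forms

    Sen = TP/(TP+FN)         Spe = TN/(TN+FP)       Pre = TP/(TP+FP)
    ACC = (TP+TN)/n          F1  = 2*Pre*Sen/(Pre+Sen)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any 0/0 resolved to 0; AUC is the trapezoidal area under the ROC curve
with tied scores grouped (equivalently the Mann-Whitney U probability with
half-credit for ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import features as feat
from .encoders import FeatureMatrix, encode_windows, fit_biprofile
from .seqio import (
    POSITIVE,
    DegenerateComputationError,
    ProteinRecord,
    SiteAnnotation,
    SglutError,
    WindowSample,
    extract_labeled_windows,
)

logger = logging.getLogger("sglut")

#: Selected-feature counts used as per-scheme defaults (reference working
#: points for the eight encodings at window 15).
REFERENCE_K = {
    "physchem": 3,
    "reduced_comp": 6,
    "biprofile_bayes": 18,
    "binary_profile": 12,
    "single_aa": 3,
    "pair_aa": 21,
    "triplet_aa": 76,
    "reduced_triplet_aa": 71,
}

#: LIBSVM-style tuning grid (powers of 4 inside the classic ranges).
SVM_COST_GRID = [2.0**e for e in range(-5, 16, 2)]
SVM_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]
POLY_DEGREE_GRID = [2, 3]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and with what hyperparameters."""

    family: str = "svm"  # svm | knn | random_forest
    kernel: str = "rbf"  # svm only: linear | polynomial | rbf
    cost: float = 1.0
    # LIBSVM defaults: C=1, gamma = 1/n_features ("auto" in scikit-learn)
    gamma: float | str = "auto"
    degree: int = 3
    k_neighbors: int = 1
    n_trees: int = 500
    seed: int = 0


def make_estimator(spec: ClassifierSpec):
    if spec.family == "svm":
        kernels = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}
        if spec.kernel not in kernels:
            raise SglutError(f"unknown SVM kernel {spec.kernel!r}")
        return SVC(
            kernel=kernels[spec.kernel],
            C=spec.cost,
            gamma=spec.gamma,
            degree=spec.degree,
            random_state=spec.seed,
        )
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k_neighbors, metric="euclidean")
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed
        )
    raise SglutError(f"unknown classifier family {spec.family!r}")


def train(spec: ClassifierSpec, X: FeatureMatrix):
    """Fit a classifier on a (normalized) feature matrix; returns the handle.

    The handle exposes ``predict`` and continuous scores for ROC analysis via
    :func:`decision_scores` (SVM decision values, kNN vote fraction, random
    forest class probability).
    """
    y = X.y
    if len(set(y)) < 2:
        raise DegenerateComputationError("training data must contain both classes")
    est = make_estimator(spec)
    est.fit(X.values, y)
    return est


def decision_scores(estimator, values: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(values), dtype=float)
    return np.asarray(estimator.predict_proba(values)[:, 1], dtype=float)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sen: float
    spe: float
    pre: float
    f1: float
    mcc: float
    acc: float
    auc: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    METRIC_COLUMNS = ("auc", "spe", "pre", "sen", "f1", "mcc", "acc")

    def row(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRIC_COLUMNS}


def _safe_div(num: float, den: float) -> float:
    """0/0 -> 0 convention for degenerate confusion-matrix denominators."""
    return num / den if den != 0 else 0.0


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Compute the rate metrics from a confusion matrix."""
    if min(tp, fp, tn, fn) < 0:
        raise SglutError("confusion-matrix counts must be non-negative")
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    pre = _safe_div(tp, tp + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    f1 = _safe_div(2 * pre * sen, pre + sen)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    if mcc_den == 0:
        logger.debug("MCC denominator zero; reporting 0 by convention")
    return MetricsReport(tp, fp, tn, fn, sen, spe, pre, f1, float(mcc), acc)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """ROC points by sweeping all score thresholds, AUC by the trapezoid rule.

    Tied scores are grouped into a single threshold, which makes the
    trapezoidal area equal to the Mann-Whitney U probability with half-credit
    for ties.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise DegenerateComputationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> MetricsReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    report = confusion_metrics(tp, fp, tn, fn)
    report.auc, report.roc_points = roc_auc(scores, y_true)
    return report


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    fold_assignment: np.ndarray  # fold index per sample
    selected_features: list[list[str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        cols = MetricsReport.METRIC_COLUMNS
        with open(path, "w") as fh:
            fh.write("fold\t" + "\t".join(cols) + "\n")
            for i, rep in enumerate(self.fold_reports, start=1):
                row = rep.row()
                fh.write(f"{i}\t" + "\t".join(f"{row[c]:.4f}" for c in cols) + "\n")
            row = self.pooled.row()
            fh.write("pooled\t" + "\t".join(f"{row[c]:.4f}" for c in cols) + "\n")


def _fit_fold(
    spec: ClassifierSpec,
    train_windows: list[WindowSample],
    scheme: str,
    k_select: int | None,
    pseudocount: float,
    tune: bool,
):
    """Fit the full leakage-safe pipeline on one training split.

    Returns (transform, estimator) where transform maps raw windows to the
    selected, normalized feature space learned from this split only.
    """
    profile = (
        fit_biprofile(train_windows, pseudocount)
        if scheme == "biprofile_bayes"
        else None
    )
    train_X = encode_windows(train_windows, scheme, profile=profile)
    norm = feat.fit_normalizer(train_X)
    train_X = feat.apply_normalizer(norm, train_X)
    if k_select is None:
        k_select = min(REFERENCE_K.get(scheme, train_X.values.shape[1]),
                       train_X.values.shape[1])
    selected = feat.select_top_k(feat.rank_features(train_X), k_select)
    train_X = feat.subset_features(train_X, selected)

    fit_spec = _tune_spec(spec, train_X) if tune else spec
    est = train(fit_spec, train_X)

    def transform(windows: list[WindowSample]) -> FeatureMatrix:
        X = encode_windows(windows, scheme, profile=profile)
        X = feat.apply_normalizer(norm, X)
        return feat.subset_features(X, selected)

    return transform, est, selected


def fit_pipeline(
    spec: ClassifierSpec,
    train_windows: list[WindowSample],
    scheme: str,
    k_select: int | None = None,
    pseudocount: float = 0.0,
    tune: bool = False,
):
    """Fit the full encode/normalize/select/train pipeline on a training set.

    Returns ``(transform, estimator, selected_features)`` where ``transform``
    maps new windows into the learned feature space, for scoring held-out or
    unlabeled cysteines.
    """
    return _fit_fold(spec, train_windows, scheme, k_select, pseudocount, tune)


def _tune_spec(spec: ClassifierSpec, train_X: FeatureMatrix) -> ClassifierSpec:
    """Pick SVM hyperparameters by inner 5-fold CV over the LIBSVM-style grid.

    Non-SVM families are returned unchanged (their single hyperparameter is
    part of the spec).
    """
    if spec.family != "svm":
        return spec
    if spec.kernel == "linear":
        grid = [replace(spec, cost=c) for c in SVM_COST_GRID]
    elif spec.kernel == "polynomial":
        grid = [
            replace(spec, cost=c, gamma=g, degree=d)
            for c in SVM_COST_GRID
            for g in SVM_GAMMA_GRID
            for d in POLY_DEGREE_GRID
        ]
    else:
        grid = [
            replace(spec, cost=c, gamma=g)
            for c in SVM_COST_GRID
            for g in SVM_GAMMA_GRID
        ]
    y = train_X.y
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed)
    best, best_auc = spec, -np.inf
    for cand in grid:
        scores = np.zeros(len(y))
        ok = True
        for tr, te in inner.split(train_X.values, y):
            if len(set(y[tr])) < 2:
                ok = False
                break
            est = make_estimator(cand)
            est.fit(train_X.values[tr], y[tr])
            scores[te] = decision_scores(est, train_X.values[te])
        if not ok:
            continue
        auc, _ = roc_auc(scores, y)
        if auc > best_auc:
            best, best_auc = cand, auc
    return best


def crossvalidate(
    spec: ClassifierSpec,
    windows: list[WindowSample],
    scheme: str,
    k_select: int | None = None,
    folds: int = 5,
    seed: int = 0,
    pseudocount: float = 0.0,
    tune: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold, the Bi-profile matrix (when applicable), the normalizer, the
    t-test ranking and the classifier are fit on the training part only; the
    held-out part is scored.  Pooled metrics come from the concatenated
    out-of-fold predictions; per-fold reports are also returned.
    """
    if folds < 2:
        raise SglutError("folds must be >= 2")
    y = np.array([1 if w.label == POSITIVE else 0 for w in windows])
    if len(set(y.tolist())) < 2:
        raise DegenerateComputationError("dataset must contain both classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.full(len(windows), -1)
    oof_scores = np.zeros(len(windows))
    oof_pred = np.zeros(len(windows), dtype=int)
    fold_reports: list[MetricsReport] = []
    selected_per_fold: list[list[str]] = []
    for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(set(y[tr].tolist())) < 2 or len(set(y[te].tolist())) < 2:
            raise DegenerateComputationError(
                f"fold {fold_i} is single-class; use a different seed or fold count"
            )
        assignment[te] = fold_i
        train_windows = [windows[i] for i in tr]
        test_windows = [windows[i] for i in te]
        transform, est, selected = _fit_fold(
            spec, train_windows, scheme, k_select, pseudocount, tune
        )
        selected_per_fold.append(selected)
        test_X = transform(test_windows)
        oof_pred[te] = est.predict(test_X.values)
        oof_scores[te] = decision_scores(est, test_X.values)
        fold_reports.append(evaluate_predictions(y[te], oof_pred[te], oof_scores[te]))
    pooled = evaluate_predictions(y, oof_pred, oof_scores)
    return CVResult(fold_reports, pooled, assignment, selected_per_fold)


def sweep_window_sizes(
    proteins: list[ProteinRecord],
    annotations: list[SiteAnnotation],
    spec: ClassifierSpec,
    scheme: str,
    sizes: tuple[int, ...] = (9, 11, 13, 15, 17, 19, 21),
    k_select: int | None = None,
    folds: int = 5,
    seed: int = 0,
    pseudocount: float = 0.0,
    tune: bool = False,
) -> dict[int, CVResult]:
    """Re-extract windows at each size and cross-validate with a shared seed.

    The same seed across sizes keeps fold structure comparable; sites whose
    window falls off a terminus at a larger size are discarded there only.
    """
    results: dict[int, CVResult] = {}
    for w in sizes:
        if w % 2 == 0:
            raise SglutError(f"window sizes must be odd, got {w}")
        windows, n_discarded = extract_labeled_windows(proteins, annotations, w)
        windows = [win for win in windows if win.is_standard()]
        if n_discarded:
            logger.info("window size %d: %d terminal sites discarded", w, n_discarded)
        results[w] = crossvalidate(
            spec,
            windows,
            scheme,
            k_select=k_select,
            folds=folds,
            seed=seed,
            pseudocount=pseudocount,
            tune=tune,
        )
    return results


def write_roc_tsv(path, roc_points: list[tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in roc_points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
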