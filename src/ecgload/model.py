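"""Supervised estimation of session internal load.

Regression on continuous TRIMP and classification of TRIMP tertiles with
gradient-boosted trees (XGBoost, early-stopped on an inner 10% split),
random forest, and an RBF support-vector machine; 10-fold stratified
cross-validation with z-scoring fit on training folds only; the metric
suite (MAE, RMSE, R^2 = 1 - SSres/SStot; macro precision/recall/F1 and
one-vs-rest AUC); paired t-tests between models with Holm correction; and
Shapley attribution by exact interventional coalition enumeration.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .preprocess import NormalizationStats, zscore

MODEL_NAMES = ("gbt", "rf", "svm")

GBT_PARAMS = dict(n_estimators=500, max_depth=4, learning_rate=0.05)
GBT_EARLY_STOPPING_ROUNDS = 50
RF_PARAMS = dict(n_estimators=500)
SVM_PARAMS = dict(C=1.0, gamma="auto", kernel="rbf")  # gamma = 1/p after z-scoring


@dataclasses.dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    rmse: float
    r2: float


@dataclasses.dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float


@dataclasses.dataclass
class CvReport:
    task: str
    per_fold: Dict[str, List[dict]]  # model -> list of per-fold metric dicts
    aggregate: Dict[str, Dict[str, Tuple[float, float]]]  # model -> metric -> (mean, sd)
    pairwise_tests: Dict[Tuple[str, str], Dict[str, float]]
    attributions: Dict[str, Dict[str, float]]  # model -> feature -> mean |phi|
    fold_assignment: np.ndarray


# ---------------------------------------------------------------------------
# folds


def make_folds(
    manifest: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    strata_cols: Sequence[str] = ("session_type", "stratum"),
) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Stratifies on the composite of the given columns (session type, and
    TRIMP stratum when present); falls back to type-only stratification
    with a warning when a composite stratum has fewer members than folds.
    """
    n = len(manifest)
    if n < k:
        raise ValueError(f"need at least k={k} sessions, got {n}")
    cols = [c for c in strata_cols if c in manifest.columns]
    labels = (
        manifest[cols].astype(str).agg("|".join, axis=1)
        if cols
        else pd.Series(["all"] * n, index=manifest.index)
    )
    if labels.value_counts().min() < k and len(cols) > 1:
        warnings.warn(
            "a composite stratum is smaller than k; falling back to "
            f"{cols[0]}-only stratification",
            stacklevel=2,
        )
        labels = manifest[cols[0]].astype(str)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# estimators


def _make_estimator(name: str, task: str, seed: int):
    if name == "gbt":
        cls = XGBRegressor if task == "regression" else XGBClassifier
        return cls(
            **GBT_PARAMS,
            random_state=seed,
            early_stopping_rounds=GBT_EARLY_STOPPING_ROUNDS,
            n_jobs=1,
        )
    if name == "rf":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(**RF_PARAMS, random_state=seed, n_jobs=1)
    if name == "svm":
        if task == "regression":
            return SVR(**SVM_PARAMS)
        return SVC(**SVM_PARAMS, probability=True, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def fit_predict(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    task: str = "regression",
    seed: int = 0,
):
    """Fit one model and predict the test split.

    Regression returns (predictions, fitted); classification returns
    (class probabilities, fitted) with classes in ``fitted.classes_``.
    The boosted model holds out an inner 10% validation split for early
    stopping.  A zero-variance training target is rejected.
    """
    y_train = np.asarray(y_train)
    if task == "regression" and float(np.std(y_train)) == 0.0:
        raise ValueError("degenerate training target: zero variance")
    if task == "classification" and len(np.unique(y_train)) < 2:
        raise ValueError("degenerate training target: single class")
    est = _make_estimator(name, task, seed)
    if name == "gbt":
        stratify = y_train if task == "classification" else None
        X_in, X_val, y_in, y_val = train_test_split(
            X_train, y_train, test_size=0.1, random_state=seed, stratify=stratify
        )
        est.fit(X_in, y_in, eval_set=[(X_val, y_val)], verbose=False)
    else:
        est.fit(X_train, y_train)
    if task == "regression":
        return est.predict(X_test), est
    return est.predict_proba(X_test), est


# ---------------------------------------------------------------------------
# metrics


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> RegressionMetrics:
    """MAE, RMSE and R^2 = 1 - SSres/SStot (may be negative; NaN for constant y)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("need equal nonzero lengths")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sstot == 0 else 1.0 - float(np.sum(err**2)) / sstot
    return RegressionMetrics(mae=mae, rmse=rmse, r2=r2)


def classification_metrics(
    labels: Sequence,
    predicted: Sequence,
    probabilities: Optional[np.ndarray] = None,
    classes: Optional[Sequence] = None,
) -> ClassificationMetrics:
    """Macro-averaged precision/recall/F1 and macro one-vs-rest AUC.

    Classes absent from ``labels`` are macro-averaged over the present
    classes, with a warning.
    """
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < len(classes):
        warnings.warn("class absent from labels: macro average over present classes",
                      stacklevel=2)
    accuracy = float(np.mean(labels == predicted))
    precisions, recalls, f1s = [], [], []
    for c in present:
        tp = float(np.sum((predicted == c) & (labels == c)))
        fp = float(np.sum((predicted == c) & (labels != c)))
        fn = float(np.sum((predicted != c) & (labels == c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    auc = float("nan")
    if probabilities is not None:
        cols = [int(np.flatnonzero(classes == c)[0]) for c in present]
        proba = np.asarray(probabilities)[:, cols]
        if len(present) == 2:
            auc = float(roc_auc_score((labels == present[1]).astype(int), proba[:, 1]))
        elif len(present) > 2:
            proba = proba / proba.sum(axis=1, keepdims=True)
            auc = float(
                roc_auc_score(labels, proba, multi_class="ovr",
                              average="macro", labels=present)
            )
    return ClassificationMetrics(
        accuracy=accuracy,
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        auc=auc,
    )


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t on fold-wise differences, df = k - 1.

    Zero-variance differences are degenerate: p = 1 when the mean
    difference is zero, else p = 0 with an infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal fold counts >= 2")
    d = a - b
    if float(np.std(d, ddof=1)) == 0.0:
        if float(np.mean(d)) == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, float(np.mean(d))), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def holm_correction(pvalues: Dict, alpha: float = 0.05) -> Dict:
    """Holm step-down adjusted p-values for a family of pairwise tests."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for i, (key, p) in enumerate(items):
        running = max(running, min((m - i) * p, 1.0))
        adjusted[key] = running
    return {k: adjusted[k] for k in pvalues}


# ---------------------------------------------------------------------------
# Shapley attribution


@dataclasses.dataclass
class ShapleyResult:
    values: np.ndarray  # (n_rows, n_features)
    base_value: float
    feature_names: List[str]
    mc_error: Optional[float] = None  # None for the exact path

    def mean_abs(self) -> Dict[str, float]:
        return {
            name: float(np.mean(np.abs(self.values[:, j])))
            for j, name in enumerate(self.feature_names)
        }


def shapley_attribution(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: Optional[np.ndarray] = None,
    feature_names: Optional[Sequence[str]] = None,
    max_exact: int = 12,
    n_permutations: int = 64,
    seed: int = 0,
) -> ShapleyResult:
    """Interventional Shapley values for a black-box prediction function.

    For p <= ``max_exact`` features the coalition value
    v(S, x) = E_b[ f(x_S, b_not-S) ] is enumerated exhaustively over all
    2^p subsets against the background sample, giving exact attributions
    that satisfy local accuracy: sum_j phi_j(x) = f(x) - E_b[f(b)].  Beyond
    that, a seeded permutation-sampling approximation is used and the
    Monte-Carlo standard error is reported.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if background is None:
        background = X
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    base = float(np.mean(predict(background)))
    if p <= max_exact:
        values = _exact_shapley(predict, X, background)
        return ShapleyResult(values, base, list(feature_names))
    values, err = _sampled_shapley(predict, X, background, n_permutations, seed)
    return ShapleyResult(values, base, list(feature_names), mc_error=err)


def _coalition_value(predict, X, background, mask: np.ndarray) -> np.ndarray:
    """E over background of f(x with features in `mask`, background elsewhere)."""
    n, p = X.shape
    m = background.shape[0]
    z = np.repeat(background[None, :, :], n, axis=0)  # (n, m, p)
    z[:, :, mask] = X[:, None, mask]
    preds = predict(z.reshape(n * m, p))
    return np.asarray(preds, dtype=float).reshape(n, m).mean(axis=1)


def _exact_shapley(predict, X, background) -> np.ndarray:
    n, p = X.shape
    fact = [math.factorial(i) for i in range(p + 1)]
    v = {}  # frozenset bitmask -> (n,) value vector
    for size in range(p + 1):
        for subset in combinations(range(p), size):
            mask = np.zeros(p, dtype=bool)
            mask[list(subset)] = True
            v[subset] = _coalition_value(predict, X, background, mask)
    phi = np.zeros((n, p))
    for subset, val in v.items():
        s = len(subset)
        sset = set(subset)
        for j in range(p):
            if j in sset:
                continue
            w = fact[s] * fact[p - s - 1] / fact[p]
            with_j = tuple(sorted(sset | {j}))
            phi[:, j] += w * (v[with_j] - val)
    return phi


def _sampled_shapley(predict, X, background, n_permutations: int, seed: int):
    rng = np.random.default_rng(seed)
    n, p = X.shape
    m = background.shape[0]
    contribs = np.zeros((n_permutations, n, p))
    for t in range(n_permutations):
        order = rng.permutation(p)
        b = background[rng.integers(0, m, size=n)]
        z = b.copy()
        prev = np.asarray(predict(z), dtype=float)
        for j in order:
            z[:, j] = X[:, j]
            cur = np.asarray(predict(z), dtype=float)
            contribs[t, :, j] = cur - prev
            prev = cur
    values = contribs.mean(axis=0)
    err = float(np.mean(contribs.std(axis=0, ddof=1) / math.sqrt(n_permutations)))
    return values, err


# ---------------------------------------------------------------------------
# cross-validation driver


def _zscore_fold(X_train: pd.DataFrame, X_test: pd.DataFrame):
    """Z-score both splits with statistics fit on the training fold only."""
    train = np.empty_like(X_train.to_numpy(dtype=float))
    test = np.empty_like(X_test.to_numpy(dtype=float))
    for j, col in enumerate(X_train.columns):
        z, stats_ = zscore(X_train[col].to_numpy(dtype=float))
        train[:, j] = z
        test[:, j] = stats_.apply(X_test[col].to_numpy(dtype=float))
    return train, test


def cross_validate(
    X: pd.DataFrame,
    y: Sequence,
    manifest: pd.DataFrame,
    task: str = "regression",
    models: Sequence[str] = MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
    attribution_rows_per_fold: int = 8,
    attribution_background: int = 50,
    compute_attributions: bool = True,
) -> CvReport:
    """Stratified k-fold cross-validation of the model roster.

    Features are z-scored with training-fold statistics; per-fold metrics,
    aggregate mean +/- SD, Holm-corrected paired t-tests on the primary
    metric (R^2 or macro F1), and mean |Shapley| attributions (on a
    subsample of test rows per fold) are reported.
    """
    y = np.asarray(y)
    classes = None
    if task == "classification":
        # integer-encode labels once; reported classes keep the original values
        classes, y = np.unique(y, return_inverse=True)
    assignment = make_folds(manifest, k=k, seed=seed)
    per_fold: Dict[str, List[dict]] = {m: [] for m in models}
    attr_acc: Dict[str, List[np.ndarray]] = {m: [] for m in models}
    rng = np.random.default_rng(seed)

    for fold in range(k):
        test_mask = assignment == fold
        X_tr_raw, X_te_raw = X.loc[~test_mask], X.loc[test_mask]
        y_tr, y_te = y[~test_mask], y[test_mask]
        X_tr, X_te = _zscore_fold(X_tr_raw, X_te_raw)
        for name in models:
            pred, est = fit_predict(name, X_tr, y_tr, X_te, task=task, seed=seed)
            if task == "regression":
                m = regression_metrics(y_te, pred)
                per_fold[name].append(dataclasses.asdict(m))
                predict_fn = est.predict
            else:
                hard = np.argmax(pred, axis=1)
                m = classification_metrics(
                    y_te, hard, pred, classes=np.arange(len(classes))
                )
                per_fold[name].append(dataclasses.asdict(m))
                predict_fn = lambda Z, e=est: e.predict_proba(Z).max(axis=1)  # noqa: E731
            if compute_attributions:
                take = min(attribution_rows_per_fold, X_te.shape[0])
                rows = rng.choice(X_te.shape[0], size=take, replace=False)
                bg_n = min(attribution_background, X_tr.shape[0])
                bg = X_tr[rng.choice(X_tr.shape[0], size=bg_n, replace=False)]
                res = shapley_attribution(
                    predict_fn, X_te[rows], background=bg,
                    feature_names=list(X.columns), seed=seed,
                )
                attr_acc[name].append(np.abs(res.values))

    aggregate = {
        name: {
            metric: (
                float(np.mean([f[metric] for f in folds])),
                float(np.std([f[metric] for f in folds], ddof=1)),
            )
            for metric in folds[0]
        }
        for name, folds in per_fold.items()
    }

    primary = "r2" if task == "regression" else "f1"
    raw_p: Dict[Tuple[str, str], float] = {}
    tests: Dict[Tuple[str, str], Dict[str, float]] = {}
    for a, b in combinations(models, 2):
        t, p = paired_ttest(
            [f[primary] for f in per_fold[a]], [f[primary] for f in per_fold[b]]
        )
        tests[(a, b)] = {"t": t, "p": p, "metric": primary}
        raw_p[(a, b)] = p
    adjusted = holm_correction(raw_p) if raw_p else {}
    for key, padj in adjusted.items():
        tests[key]["p_holm"] = padj

    attributions = {
        name: {
            col: float(np.mean(np.vstack(blocks)[:, j])) if blocks else float("nan")
            for j, col in enumerate(X.columns)
        }
        for name, blocks in attr_acc.items()
    }
    return CvReport(
        task=task,
        per_fold=per_fold,
        aggregate=aggregate,
        pairwise_tests=tests,
        attributions=attributions,
        fold_assignment=assignment,
    )
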