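"""Relapse/progression classification protocol.

Nested cross-validation harness around a fixed per-fold pipeline:
correlation filtering, SMOTE class balancing, train-fitted z-scoring,
sequential forward feature selection with an inner CV, then a KNN / LDA /
random-forest / ICARE classifier, reporting accuracy, F1, recall, precision
and ROC AUC as mean ± SD over outer folds × repeats.

SMOTE is applied inside each outer-training fold by default (leak-free);
``smote_mode="before_split"`` reproduces the literal balance-then-split
ordering for comparison — it leaks test information and inflates metrics,
which is exactly why it is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from .icare import BaggedIcare, IcareHyperParams, rank_auc
from .longitudinal import zscore

logger = logging.getLogger("deltarad")

METRICS = ("accuracy", "f1", "recall", "precision", "roc_auc")


@dataclass
class CVConfig:
    """Nested-CV protocol settings (defaults follow the study design)."""

    outer_folds: int = 10
    outer_repeats: int = 5
    inner_folds: int = 5
    inner_repeats: int = 20
    holdout_fraction: float = 0.15
    stratified: bool = True
    max_features: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 <= self.holdout_fraction < 0.5:
            raise ValueError("holdout_fraction must be in [0, 0.5)")


@dataclass
class CVReport:
    model: str
    combo: str
    fold_metrics: pd.DataFrame  # one row per outer fold x repeat
    chosen_features: list[list[str]]
    holdout_metrics: dict | None = None

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.fold_metrics.mean(), "sd": self.fold_metrics.std(ddof=0)})


def correlation_filter(X: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Drop constant columns, then greedily (in column order) drop features
    with |Pearson r| above ``threshold`` to an already retained one."""
    variable = [c for c in X.columns if X[c].nunique() > 1]
    if not variable:
        return []
    corr = X[variable].corr().abs().to_numpy()
    kept_idx: list[int] = []
    for j in range(len(variable)):
        if all(corr[j, k] <= threshold for k in kept_idx):
            kept_idx.append(j)
    return [variable[j] for j in kept_idx]


def smote(
    X: pd.DataFrame,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balance classes by interpolated synthetic minority samples.

    Each synthetic point is ``x_i + lambda * (x_nn - x_i)`` with
    ``lambda ~ U(0, 1)`` and ``x_nn`` one of the ``k`` nearest minority
    neighbours of ``x_i`` (k capped at minority size - 1).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects a binary label")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("smote needs at least 2 minority samples")
    Xm = X[y == minority].to_numpy(dtype=float)
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, nbrs = nn.kneighbors(Xm)  # column 0 is the point itself

    need = n_maj - n_min
    base = rng.integers(0, n_min, size=need)
    pick = rng.integers(1, k + 1, size=need)
    lam = rng.random(need)
    synth = Xm[base] + lam[:, None] * (Xm[nbrs[base, pick]] - Xm[base])
    X_new = pd.DataFrame(
        np.vstack([X.to_numpy(dtype=float), synth]),
        columns=X.columns,
        index=list(X.index) + [f"synth_{i}" for i in range(need)],
    )
    y_new = np.concatenate([y, np.full(need, minority)])
    return X_new, y_new


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def _inner_cv_score(
    X: pd.DataFrame, y: np.ndarray, estimator, cols: list[str],
    inner_folds: int, inner_repeats: int, seed: int,
) -> float:
    """Mean F1 of ``estimator`` on ``cols`` over repeated stratified folds."""
    n_splits = min(inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        return 0.0
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=inner_repeats, random_state=seed)
    scores = []
    V = X[cols]
    for tr, te in cv.split(V, y):
        m = clone(estimator)
        try:
            m.fit(V.iloc[tr], y[tr])
            pred = m.predict(V.iloc[te])
        except (ValueError, IndexError, np.linalg.LinAlgError):
            # degenerate split (e.g. a candidate feature constant on the
            # training part); such a candidate scores 0 for this fold
            scores.append(0.0)
            continue
        scores.append(_f1(y[te], pred))
    return float(np.mean(scores))


def sequential_forward_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    estimator,
    inner_folds: int = 5,
    inner_repeats: int = 1,
    max_features: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection scored by inner-CV F1.

    Starts empty, repeatedly adds the feature with the best inner-CV score,
    stops when no addition improves the score or ``max_features`` is
    reached.  Ties break on the lowest column index, making the selection
    deterministic for a fixed seed.  (Greedy search can miss jointly
    predictive but marginally useless pairs, e.g. XOR structure.)
    """
    y = np.asarray(y)
    max_features = max_features or X.shape[1]
    selected: list[str] = []
    best_score = -np.inf
    remaining = list(X.columns)
    while remaining and len(selected) < max_features:
        scores = [
            _inner_cv_score(X, y, estimator, selected + [c], inner_folds, inner_repeats, seed)
            for c in remaining
        ]
        j = int(np.argmax(scores))  # argmax takes the first (lowest-index) maximum
        if scores[j] <= best_score:
            break
        best_score = scores[j]
        selected.append(remaining.pop(j))
    if not selected:
        selected = [X.columns[0]]
    return selected


def classification_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, F1, recall, precision and (tie-aware) ROC AUC.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean.
    ROC AUC is NaN when only one class is present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    auc = rank_auc(scores, y_true) if len(np.unique(y_true)) == 2 else float("nan")
    return {
        "accuracy": (tp + tn) / len(y_true),
        "f1": f1,
        "recall": rec,
        "precision": prec,
        "roc_auc": auc,
    }


def _make_estimator(model: str, params: dict, seed: int):
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 5))
    if model == "lda":
        return LinearDiscriminantAnalysis()
    if model == "rf":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500), random_state=seed
        )
    raise ValueError(f"unknown model {model!r}")


KNN_K_GRID = (3, 5, 7)


def _fit_predict_fold(
    model: str,
    params: dict,
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    X_te: pd.DataFrame,
    cfg: CVConfig,
    smote_mode: str,
    fold_seed: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[str]]:
    """One outer-fold pipeline; returns (test scores, threshold, chosen features)."""
    retained = correlation_filter(X_tr, params.get("correlation_threshold", 0.8))
    X_tr, X_te = X_tr[retained], X_te[retained]
    if smote_mode == "within_fold":
        X_tr, y_tr = smote(X_tr, y_tr, rng=np.random.default_rng(fold_seed))
    X_trz, stats = zscore(X_tr)
    X_tez, _ = zscore(X_te, fit_stats=stats)

    if model == "icare":
        feats = list(X_trz.columns)
        ens = BaggedIcare(IcareHyperParams(
            n_models=params.get("n_models", 100), F=params.get("F", 10),
            Cmin=params.get("Cmin", 0.05), rho=params.get("rho", 0.8),
        ))
        ens.fit(X_trz, y_tr, np.random.default_rng(fold_seed))
        return ens.predict_score(X_tez), 0.0, feats

    sfs_estimator = _make_estimator(model, params, fold_seed)
    feats = sequential_forward_selection(
        X_trz, y_tr, sfs_estimator,
        inner_folds=cfg.inner_folds, inner_repeats=cfg.inner_repeats,
        max_features=cfg.max_features, seed=fold_seed,
    )
    if model == "knn":
        # tune k on the selected features in the same inner CV
        best_k, best = KNN_K_GRID[0], -np.inf
        for k in KNN_K_GRID:
            s = _inner_cv_score(
                X_trz, y_tr, KNeighborsClassifier(n_neighbors=k), feats,
                cfg.inner_folds, cfg.inner_repeats, fold_seed,
            )
            if s > best:
                best_k, best = k, s
        params = {**params, "k": best_k}
    est = _make_estimator(model, params, fold_seed)
    est.fit(X_trz[feats], y_tr)
    scores = est.predict_proba(X_tez[feats])[:, 1]
    return scores, 0.5, feats


def nested_cv_classify(
    X: pd.DataFrame,
    y: np.ndarray,
    model: str = "rf",
    cfg: CVConfig | None = None,
    smote_mode: str = "within_fold",
    model_params: dict | None = None,
    combo_name: str = "",
) -> CVReport:
    """Nested cross-validated classification with the full per-fold pipeline.

    ``model`` is one of knn / lda / rf / icare.  The optional 15% holdout is
    carved off first (stratified) and evaluated once with a pipeline trained
    on the rest.
    """
    cfg = cfg or CVConfig()
    params = model_params or {}
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if smote_mode not in ("within_fold", "before_split"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")

    rng = np.random.default_rng(cfg.seed)
    if smote_mode == "before_split":
        X, y = smote(X, y, rng=np.random.default_rng(cfg.seed))

    holdout = None
    if cfg.holdout_fraction > 0:
        X, X_hold, y, y_hold = train_test_split(
            X, y, test_size=cfg.holdout_fraction, stratify=y if cfg.stratified else None,
            random_state=cfg.seed,
        )
        holdout = (X_hold, y_hold)

    n_splits = min(cfg.outer_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few samples in the minority class for outer folds")
    if cfg.stratified:
        outer = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=cfg.outer_repeats, random_state=cfg.seed
        )
    else:
        from sklearn.model_selection import RepeatedKFold

        outer = RepeatedKFold(n_splits=n_splits, n_repeats=cfg.outer_repeats, random_state=cfg.seed)

    rows, chosen = [], []
    for fold_i, (tr, te) in enumerate(outer.split(X, y)):
        y_tr, y_te = y[tr], y[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            logger.warning("fold %d lacks a class; skipped", fold_i)
            continue
        fold_seed = int(rng.integers(0, 2**31))
        scores, thr, feats = _fit_predict_fold(
            model, params, X.iloc[tr], y_tr, X.iloc[te], cfg, smote_mode, fold_seed, rng
        )
        rows.append(classification_metrics(y_te, scores, thr))
        chosen.append(feats)

    report = CVReport(model, combo_name, pd.DataFrame(rows, columns=list(METRICS)), chosen)

    if holdout is not None:
        X_hold, y_hold = holdout
        fold_seed = int(rng.integers(0, 2**31))
        scores, thr, _ = _fit_predict_fold(
            model, params, X, y, X_hold, cfg, smote_mode, fold_seed, rng
        )
        if len(np.unique(y_hold)) == 2:
            report.holdout_metrics = classification_metrics(y_hold, scores, thr)
    return report
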