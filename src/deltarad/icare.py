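"""ICARE: individual coefficient approximation for risk estimation.

A deliberately minimal risk model for small radiomics cohorts: each retained
feature contributes only its sign.  Fitting z-scores the features, measures
each feature's univariate discrimination (ROC AUC against a binary label, or
Harrell's concordance against a right-censored time), keeps features whose
margin ``|u - 0.5|`` exceeds ``Cmin``, greedily decorrelates the survivors
(visiting by descending margin, dropping any feature correlated above
``rho`` with a kept one), draws a random subset of at most ``F`` of them,
and scores new samples as the mean of ``w_j * z_j`` with ``w_j = ±1``
oriented by the univariate direction.  Risk scores are anti-concordant with
survival time: higher risk means earlier progression.

The bagged ensemble fits many such models on bootstrap resamples and
aggregates predictions with the median; hyperparameters (F, Cmin, rho) can
be tuned by ranking randomly sampled sets with Monte Carlo cross-validation
and letting each ensemble member draw one of the top-B sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival_ttp import harrell_cindex


@dataclass
class IcareHyperParams:
    F: int = 10
    Cmin: float = 0.05
    rho: float = 0.8
    n_models: int = 1000
    B: int = 5

    def __post_init__(self) -> None:
        if self.F < 1 or self.n_models < 1:
            raise ValueError("F and n_models must be >= 1")
        if not 0 <= self.Cmin < 0.5:
            raise ValueError("Cmin must be in [0, 0.5)")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")


def rank_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of x as a score for y=1; tied scores count 0.5."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    pos, neg = x[y == 1], x[y == 0]
    if pos.size == 0 or neg.size == 0:
        return 0.5
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


@dataclass
class IcareModel:
    """One fitted binary-weighted model."""

    features: list[str]
    weights: np.ndarray  # ±1 per retained feature
    means: np.ndarray
    sds: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not self.features:
            return np.zeros(len(X))
        Z = (X[self.features].to_numpy(dtype=float) - self.means) / self.sds
        return (Z * self.weights).mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IcareModel":
        return cls(
            features=list(d["features"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
        )


def _univariate_performance(x: np.ndarray, target) -> float:
    """AUC for a binary target, Harrell c (anti-concordant) for (time, event)."""
    if isinstance(target, tuple):
        time, event = target
        c = harrell_cindex(x, time, event)
        return 0.5 if np.isnan(c) else c
    return rank_auc(x, np.asarray(target))


def fit_single(
    X: pd.DataFrame, target, params: IcareHyperParams, rng: np.random.Generator
) -> IcareModel:
    """Fit one binary-weighted model; ``target`` is a label vector or a
    (time, event) tuple for survival."""
    cols = list(X.columns)
    V = X.to_numpy(dtype=float)
    means = V.mean(axis=0)
    sds = V.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (V - means) / sds

    u = np.array([_univariate_performance(Z[:, j], target) for j in range(len(cols))])
    w = np.where(u > 0.5, 1.0, -1.0)
    margin = np.abs(u - 0.5)
    survivors = np.flatnonzero(margin >= params.Cmin)
    if survivors.size == 0:
        import logging

        logging.getLogger("deltarad").warning("ICARE: no feature reaches Cmin; constant-0 model")
        return IcareModel([], np.array([]), np.array([]), np.array([]))

    # greedy decorrelation by descending margin (stable tie-break on index)
    order = survivors[np.lexsort((survivors, -margin[survivors]))]
    Zs = Z[:, order]
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(Zs.T)) if order.size > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    kept_pos: list[int] = []
    for pos in range(order.size):
        if all(corr[pos, k] <= params.rho for k in kept_pos):
            kept_pos.append(pos)
    kept = [int(order[p]) for p in kept_pos]

    if len(kept) > params.F:
        kept = sorted(rng.choice(kept, size=params.F, replace=False).tolist())
    kept = sorted(kept)
    return IcareModel(
        features=[cols[j] for j in kept],
        weights=w[kept],
        means=means[kept],
        sds=sds[kept],
    )


def predict_ensemble(models: list[IcareModel], X: pd.DataFrame) -> np.ndarray:
    """Median over member risks, each member applying its own normalization."""
    if not models:
        raise ValueError("need at least one model")
    preds = np.stack([m.predict(X) for m in models])
    return np.median(preds, axis=0)


def _bootstrap_indices(n: int, target, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap resample; for classification, redrawn until both classes appear."""
    is_classif = not isinstance(target, tuple)
    y = np.asarray(target) if is_classif else None
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if not is_classif or len(np.unique(y[idx])) == 2:
            return idx
    return np.arange(n)  # degenerate target; fall back to the full sample


def _subset_target(target, idx: np.ndarray):
    if isinstance(target, tuple):
        return (np.asarray(target[0])[idx], np.asarray(target[1])[idx])
    return np.asarray(target)[idx]


@dataclass
class BaggedIcare:
    """Bootstrap ensemble of binary-weighted models aggregated by the median."""

    params: IcareHyperParams = field(default_factory=IcareHyperParams)
    param_sets: list[IcareHyperParams] | None = None  # one drawn per member when set
    models: list[IcareModel] = field(default_factory=list)

    def fit(self, X: pd.DataFrame, target, rng: np.random.Generator | int | None = None) -> "BaggedIcare":
        rng = np.random.default_rng(rng)
        n = len(X)
        self.models = []
        for _ in range(self.params.n_models):
            member_rng = np.random.default_rng(rng.integers(0, 2**31))
            p = self.params
            if self.param_sets:
                p = self.param_sets[member_rng.integers(0, len(self.param_sets))]
            idx = _bootstrap_indices(n, target, member_rng)
            self.models.append(fit_single(X.iloc[idx], _subset_target(target, idx), p, member_rng))
        return self

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        return predict_ensemble(self.models, X)

    def to_json(self) -> str:
        return json.dumps({"models": [m.to_dict() for m in self.models]})

    @classmethod
    def from_json(cls, s: str) -> "BaggedIcare":
        d = json.loads(s)
        obj = cls()
        obj.models = [IcareModel.from_dict(m) for m in d["models"]]
        return obj


def fit_bagged(
    X: pd.DataFrame, target, params: IcareHyperParams, rng: np.random.Generator | int | None = None
) -> BaggedIcare:
    return BaggedIcare(params=params).fit(X, target, rng)


def _sample_param_set(p_features: int, rng: np.random.Generator, n_models: int) -> IcareHyperParams:
    """Hyperparameter set drawn from the documented ranges."""
    return IcareHyperParams(
        F=int(rng.integers(1, min(30, p_features) + 1)),
        Cmin=float(rng.uniform(0.0, 0.2)),
        rho=float(rng.uniform(0.3, 1.0)),
        n_models=n_models,
    )


def _mc_cv_score(
    X: pd.DataFrame, target, params: IcareHyperParams, rng: np.random.Generator,
    n_splits: int = 10, test_fraction: float = 0.25,
) -> float:
    """Monte Carlo CV score of a single (non-bagged) model under one parameter set."""
    n = len(X)
    n_test = max(2, int(round(test_fraction * n)))
    scores = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        t_train = _subset_target(target, train)
        if not isinstance(target, tuple) and len(np.unique(t_train)) < 2:
            continue
        model = fit_single(X.iloc[train], t_train, params, rng)
        pred = model.predict(X.iloc[test])
        scores.append(_univariate_performance(pred, _subset_target(target, test)))
    return float(np.mean(scores)) if scores else 0.5


def tune_bagged(
    X: pd.DataFrame,
    target,
    n_candidate_sets: int = 1000,
    rng: np.random.Generator | int | None = None,
    n_models: int = 1000,
    b_grid: tuple[int, ...] = (1, 3, 5, 10),
    mc_splits: int = 10,
) -> BaggedIcare:
    """Random-search tuning: rank candidate (F, Cmin, rho) sets by Monte Carlo
    CV, let each ensemble member draw one of the top-B sets, and choose B by
    an additional CV step."""
    if len(X) < 20:
        raise ValueError("tune_bagged needs n >= 20")
    rng = np.random.default_rng(rng)
    candidates = [_sample_param_set(X.shape[1], rng, n_models) for _ in range(n_candidate_sets)]
    scores = [_mc_cv_score(X, target, c, rng, n_splits=mc_splits) for c in candidates]
    ranked = [candidates[i] for i in np.argsort(scores)[::-1]]

    best_b, best_score = b_grid[0], -np.inf
    for b in b_grid:
        top = ranked[: min(b, len(ranked))]
        cv_scores = []
        n = len(X)
        n_test = max(2, int(round(0.25 * n)))
        for _ in range(mc_splits):
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            t_train = _subset_target(target, train)
            if not isinstance(target, tuple) and len(np.unique(t_train)) < 2:
                continue
            ens = BaggedIcare(params=top[0], param_sets=top)
            ens.params = IcareHyperParams(**{**top[0].__dict__, "n_models": max(25, n_models // 20)})
            ens.fit(X.iloc[train], t_train, np.random.default_rng(rng.integers(0, 2**31)))
            pred = ens.predict_score(X.iloc[test])
            cv_scores.append(_univariate_performance(pred, _subset_target(target, test)))
        score = float(np.mean(cv_scores)) if cv_scores else 0.5
        if score > best_score:
            best_b, best_score = b, score

    top = ranked[: min(best_b, len(ranked))]
    final = BaggedIcare(params=IcareHyperParams(**{**top[0].__dict__, "n_models": n_models}), param_sets=top)
    final.fit(X, target, np.random.default_rng(rng.integers(0, 2**31)))
    return final


def icare_survival_direction(predictions: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell c of a risk score under the anti-concordant orientation
    (higher risk = shorter time)."""
    return harrell_cindex(predictions, time, event)
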