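"""Longitudinal feature processing: delta features, imputation, z-scoring,
scanner-effect testing and longitudinal ComBat harmonization.

Delta radiomics comes in two flavours: the absolute change
``EoT - baseline`` and the relative change ``(EoT - baseline) / baseline``.
Relative deltas with a near-zero baseline are recorded as missing (and
mean-imputed later) rather than clipped, to avoid fabricating huge ratios.

Scanner effects are probed per feature with a Welch two-sample t-test
(additive mean shift) and Bartlett's test (multiplicative / variance
effect); harmonization uses a longitudinal ComBat variant with subject and
time-point terms and empirical-Bayes shrinkage of the batch parameters
across features, followed by a two-sample Kolmogorov-Smirnov before/after
check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("deltarad")

FEATURE_SET_COMBOS = (
    "baseline",
    "eot",
    "baseline+eot",
    "rel_delta",
    "abs_delta",
    "baseline+rel_delta",
    "baseline+abs_delta",
)

#: relative tolerance defining a "zero" baseline for relative deltas
REL_DELTA_EPS = 1e-8


def _align(baseline: pd.DataFrame, eot: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    common = baseline.index.intersection(eot.index)
    dropped = set(baseline.index).symmetric_difference(eot.index)
    if dropped:
        logger.warning("delta: %d subject(s) present at only one time point dropped: %s",
                       len(dropped), sorted(dropped))
    if set(baseline.columns) != set(eot.columns):
        raise ValueError("baseline and EoT tables must share feature columns")
    return baseline.loc[common], eot.loc[common, baseline.columns]


def compute_delta(
    baseline: pd.DataFrame, eot: pd.DataFrame, mode: str = "absolute", eps: float = REL_DELTA_EPS
) -> pd.DataFrame:
    """Per-feature change from baseline to EoT.

    ``absolute``: EoT - baseline.  ``relative``: (EoT - baseline) / baseline,
    with cells whose |baseline| falls below ``eps`` times the column scale
    set to NaN.
    """
    base, end = _align(baseline, eot)
    diff = end - base
    if mode == "absolute":
        return diff
    if mode != "relative":
        raise ValueError(f"unknown delta mode {mode!r}")
    scale = base.abs().max().replace(0.0, 1.0)
    ok = base.abs().ge(eps * scale)
    return diff.where(ok, np.nan) / base.where(ok)


def build_feature_set(
    baseline: pd.DataFrame | None = None,
    eot: pd.DataFrame | None = None,
    combo: str = "baseline+abs_delta",
) -> pd.DataFrame:
    """Column-concatenated feature matrix for one of the seven study combos.

    Prefixes (``base_``, ``eot_``, ``dRel_``, ``dAbs_``) carry provenance;
    combos involving two time points keep only subjects present in both.
    """
    if combo not in FEATURE_SET_COMBOS:
        raise ValueError(f"unknown combo {combo!r}; choose from {FEATURE_SET_COMBOS}")
    need_base = "baseline" in combo
    need_eot = combo != "baseline"
    if need_base and baseline is None:
        raise ValueError(f"combo {combo!r} requires a baseline table")
    if need_eot and eot is None:
        raise ValueError(f"combo {combo!r} requires an EoT table")

    parts = []
    if combo in ("baseline",):
        parts.append(baseline.add_prefix("base_"))
    elif combo == "eot":
        parts.append(eot.add_prefix("eot_"))
    else:
        base, end = _align(baseline, eot)
        if "baseline" in combo:
            parts.append(base.add_prefix("base_"))
        if "eot" in combo:
            parts.append(end.add_prefix("eot_"))
        if "rel_delta" in combo:
            parts.append(compute_delta(base, end, "relative").add_prefix("dRel_"))
        if "abs_delta" in combo:
            parts.append(compute_delta(base, end, "absolute").add_prefix("dAbs_"))
    return pd.concat(parts, axis=1)


def mean_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the column mean; all-missing columns are dropped."""
    out = table.copy()
    all_missing = out.columns[out.isna().all()]
    if len(all_missing):
        logger.warning("mean_impute: dropping all-missing column(s): %s", list(all_missing))
        out = out.drop(columns=all_missing)
    return out.fillna(out.mean())


def zscore(
    table: pd.DataFrame, fit_stats: tuple[pd.Series, pd.Series] | None = None
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """(x - mu) / sigma per column (population sigma).

    ``fit_stats`` = (mu, sigma) from a training partition applies train-only
    normalization to held-out data; constant columns map to 0.
    """
    if fit_stats is None:
        mu = table.mean()
        sigma = table.std(ddof=0)
    else:
        mu, sigma = fit_stats
    safe = sigma.replace(0.0, 1.0)
    z = (table - mu) / safe
    z.loc[:, sigma == 0.0] = 0.0
    return z, (mu, sigma)


@dataclass
class ScannerEffectReport:
    """Per-feature additive (Welch t) and multiplicative (Bartlett) test results."""

    table: pd.DataFrame  # t_stat, t_p, bartlett_stat, bartlett_p, flags
    alpha: float

    @property
    def additive_flagged(self) -> pd.Index:
        return self.table.index[self.table["additive_flag"]]

    @property
    def multiplicative_flagged(self) -> pd.Index:
        return self.table.index[self.table["multiplicative_flag"]]


def _bh_flags(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection flags."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        kmax = np.flatnonzero(passed).max()
        flags[order[: kmax + 1]] = True
    return flags


def scanner_effect_tests(
    table: pd.DataFrame, scanner_ids: np.ndarray, alpha: float = 0.05
) -> ScannerEffectReport:
    """Welch t-test (mean shift) and Bartlett test (heteroscedasticity) per
    feature between exactly two scanner groups."""
    ids = np.asarray(scanner_ids)
    groups = pd.unique(ids)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two scanner groups, got {list(groups)}")
    a = table.loc[ids == groups[0]]
    b = table.loc[ids == groups[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each scanner group needs n >= 3")
    rows = {}
    for col in table.columns:
        t_stat, t_p = stats.ttest_ind(a[col], b[col], equal_var=False)
        try:
            b_stat, b_p = stats.bartlett(a[col], b[col])
        except ValueError:  # zero-variance group
            b_stat, b_p = np.nan, 1.0
        rows[col] = {"t_stat": t_stat, "t_p": t_p, "bartlett_stat": b_stat, "bartlett_p": b_p}
    rep = pd.DataFrame(rows).T
    rep["additive_flag"] = rep["t_p"] < alpha
    rep["multiplicative_flag"] = rep["bartlett_p"] < alpha
    rep["additive_flag_bh"] = _bh_flags(rep["t_p"].to_numpy(), alpha)
    rep["multiplicative_flag_bh"] = _bh_flags(rep["bartlett_p"].to_numpy(), alpha)
    return ScannerEffectReport(rep, alpha)


def _combat_design(
    n: int, subject_ids: np.ndarray, timepoints: np.ndarray, scanner_ids: np.ndarray
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix [intercept | time | subject dummies | scanner dummies]."""
    subjects = pd.unique(subject_ids)
    scanners = pd.unique(scanner_ids)
    tps = pd.unique(timepoints)
    cols = [np.ones(n)]
    for tp in tps[1:]:
        cols.append((timepoints == tp).astype(float))
    for s in subjects[1:]:
        cols.append((subject_ids == s).astype(float))
    scanner_cols = []
    for s in scanners[1:]:
        scanner_cols.append((scanner_ids == s).astype(float))
    X = np.column_stack(cols + scanner_cols)
    scanner_idx = np.arange(X.shape[1] - len(scanner_cols), X.shape[1])
    return X, list(scanners[1:]), scanner_idx


def longitudinal_combat(
    table: pd.DataFrame,
    scanner_ids: np.ndarray,
    subject_ids: np.ndarray,
    timepoints: np.ndarray,
    alpha_gate: float = 0.05,
) -> pd.DataFrame:
    """Remove per-scanner additive and multiplicative effects from repeated scans.

    Per feature, a joint least-squares fit of intercept + time-point +
    subject + scanner terms estimates the scanner location effect without the
    attenuation a two-stage (residual-based) fit would suffer when subjects
    mix scanners.  Location estimates are shrunk across features by an
    empirical-Bayes step (clipped moment estimator, pooled weights); residual
    scale ratios are shrunk likewise on the log scale.  A significance gate
    (chi-square over the standardized location estimates; Fisher-combined
    Bartlett p-values for scale) leaves the table untouched when no batch
    effect is detectable, which also makes the adjustment idempotent.
    """
    scanner_ids = np.asarray(scanner_ids)
    subject_ids = np.asarray(subject_ids)
    timepoints = np.asarray(timepoints)
    scanners = pd.unique(scanner_ids)
    if len(scanners) < 2:
        raise ValueError("longitudinal_combat needs >= 2 scanners")

    Y = table.to_numpy(dtype=float)
    n, n_feat = Y.shape
    X, scanner_names, scanner_idx = _combat_design(n, subject_ids, timepoints, scanner_ids)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "longitudinal_combat: scanner assignment confounded with subjects "
            "(rank-deficient design); adjustment still computed via min-norm fit"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    sigma = resid.std(axis=0, ddof=X.shape[1] - len(scanner_idx))
    sigma = np.where(sigma <= 0, 1.0, sigma)

    # standardized location effects g[s, f] and their common sampling variance
    XtX_inv = np.linalg.pinv(X.T @ X)
    out = Y.copy()
    adjusted = False

    # ---- location (additive) effects
    for j, sname in zip(scanner_idx, scanner_names):
        g = B[j] / sigma  # standardized shift of this scanner vs reference
        v = XtX_inv[j, j]  # sampling variance of g (unit residual variance)
        chi2 = float((g**2).sum() / v)
        p_gate = stats.chi2.sf(chi2, df=n_feat)
        if p_gate >= alpha_gate:
            continue
        adjusted = True
        gbar = g.mean()
        tau2 = max(0.0, g.var(ddof=1) - v)  # clipped moment estimator
        w = tau2 / (tau2 + v) if tau2 > 0 else 0.0  # pooled shrinkage weight
        g_star = w * g + (1 - w) * gbar
        rows = scanner_ids == sname
        out[rows] -= g_star * sigma

    # ---- scale (multiplicative) effects on marginal, time-detrended values.
    # Subject fixed intercepts split each subject's noise evenly across its two
    # scans, so model residuals under-estimate per-scanner noise ratios; the
    # multiplicative effect (and the KS/Bartlett post-checks) live on the
    # marginal group variances, so those are equalized directly.
    n_time_cols = 1 + len(pd.unique(timepoints)) - 1
    T = X[:, :n_time_cols]
    bt, *_ = np.linalg.lstsq(T, out, rcond=None)
    detr = out - T @ bt
    ref_rows = scanner_ids == scanners[0]
    bart_p = []
    for f in range(n_feat):
        groups = [detr[scanner_ids == s, f] for s in scanners]
        try:
            bart_p.append(stats.bartlett(*groups).pvalue)
        except ValueError:
            bart_p.append(1.0)
    bart_p = np.clip(np.asarray(bart_p), 1e-300, 1.0)
    fisher = -2.0 * float(np.log(bart_p).sum())
    p_scale_gate = stats.chi2.sf(fisher, df=2 * n_feat)
    if p_scale_gate < alpha_gate:
        adjusted = True
        ref_sd = detr[ref_rows].std(axis=0, ddof=1)
        ref_sd = np.where(ref_sd <= 0, 1.0, ref_sd)
        for sname in scanners[1:]:
            rows = scanner_ids == sname
            sd_s = detr[rows].std(axis=0, ddof=1)
            log_d2 = 2.0 * np.log(np.where(sd_s <= 0, ref_sd, sd_s) / ref_sd)
            # EB shrink log variance ratios toward their across-feature mean
            samp_var = 2.0 / max(rows.sum() - 1, 1) + 2.0 / max(ref_rows.sum() - 1, 1)
            tau2 = max(0.0, log_d2.var(ddof=1) - samp_var)
            w = tau2 / (tau2 + samp_var) if tau2 > 0 else 0.0
            log_star = w * log_d2 + (1 - w) * log_d2.mean()
            delta_star = np.exp(0.5 * log_star)
            # rescale this scanner's values around its own (time-detrended) mean
            center = (T @ bt)[rows] + detr[rows].mean(axis=0)
            out[rows] = center + (out[rows] - center) / delta_star

    if not adjusted:
        logger.info("longitudinal_combat: no detectable scanner effect; table returned unchanged")
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def ks_compare(before: pd.DataFrame, after: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Two-sample Kolmogorov-Smirnov p-value per feature (before vs after)."""
    if before.shape != after.shape:
        raise ValueError("tables must have the same shape")
    pvals = {}
    for col in before.columns:
        pvals[col] = stats.ks_2samp(before[col].to_numpy(), after[col].to_numpy()).pvalue
    return pd.Series(pvals, name="ks_p")
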