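"""Discrimination and calibration of the nomogram against observed outcomes.

Discrimination is the area under the ROC curve — the probability that a
randomly chosen NSN-positive patient scores higher than a randomly chosen
NSN-negative one (ties counting one half).  Calibration is assessed by
logistic recalibration: refit the outcome on the logit of the predicted
probability, so that perfect calibration corresponds to intercept alpha = 0
and slope beta = 1, and test that joint null with a 2-degree-of-freedom
likelihood-ratio chi-square.  A binned reliability curve (equal-count bins)
and its OLS line are also produced for plotting on the probability scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm

__all__ = ["CIMethod", "ROCResult", "CalibrationResult", "roc", "calibration"]

_EPS = 1e-6  # clamp for logit of scores at 0 or 1


class CIMethod(str, enum.Enum):
    HANLEY = "hanley"
    DELONG = "delong"
    BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float
    ci_low: float
    ci_high: float
    ci_method: CIMethod


@dataclass(frozen=True)
class CalibrationResult:
    intercept_alpha: float
    slope_beta: float
    lr_chi2: float
    lr_df: int
    lr_pvalue: float
    binned_curve: tuple[tuple[float, float, int], ...]  # (mean pred, obs freq, n)
    binned_ols_intercept: float
    binned_ols_slope: float


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels are degenerate: need at least one positive and one negative")


def _hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    # Hanley & McNeil (1982) standard error of the AUC
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    # DeLong, DeLong & Clarke-Pearson (1988) via midrank placements
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    v01 = (all_r[:m] - pos_r) / n                # placement of each positive
    v10 = 1.0 - (all_r[m:] - neg_r) / m          # placement of each negative
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s01 / m + s10 / n))


def roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_method: CIMethod = CIMethod.HANLEY,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with a confidence interval.

    AUC equals the Mann-Whitney probability that a positive outranks a
    negative with ties counting one half.  CI methods: Hanley-McNeil (normal
    approximation, default), DeLong, or a percentile bootstrap over patients.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    _check_labels(y.astype(int))
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = tuple(zip(fpr.tolist(), tpr.tolist()))

    ci_method = CIMethod(ci_method)
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method is CIMethod.HANLEY:
        se = _hanley_se(auc, int(y.sum()), int((~y).sum()))
        lo, hi = auc - z * se, auc + z * se
    elif ci_method is CIMethod.DELONG:
        se = _delong_se(s, y)
        lo, hi = auc - z * se, auc + z * se
    else:
        rng = np.random.default_rng(seed)
        n = len(s)
        reps = []
        while len(reps) < n_boot:
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            reps.append(roc_auc_score(yb, s[idx]))
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo = float(min(max(lo, 0.0), auc))
    hi = float(max(min(hi, 1.0), auc))
    return ROCResult(points=points, auc=auc, ci_low=lo, ci_high=hi, ci_method=ci_method)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def calibration(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_bins: int = 10,
) -> CalibrationResult:
    """Logistic recalibration and reliability curve.

    Fits logit P(y=1) = alpha + beta * logit(score) by maximum likelihood and
    tests the perfect-calibration null (alpha, beta) = (0, 1) with
    LR = 2 (loglik_fitted - loglik_null) on 2 degrees of freedom.  Scores at
    exactly 0 or 1 are clamped by 1e-6 before the logit.  The binned curve
    uses equal-count bins of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    _check_labels(y)

    x = _logit(s)
    model = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
    fit = model.fit()
    alpha_hat, beta_hat = float(fit.params[0]), float(fit.params[1])
    ll_fit = float(fit.llf)
    ll_null = _bernoulli_loglik(y, s)  # alpha=0, beta=1 leaves p = score
    lr = max(2.0 * (ll_fit - ll_null), 0.0)
    pval = float(stats.chi2.sf(lr, df=2))

    # equal-count reliability bins; duplicate edges merged for tied scores
    order = pd.qcut(pd.Series(s).rank(method="first"), q=n_bins, labels=False)
    curve = []
    for b in range(int(order.max()) + 1):
        mask = (order == b).to_numpy()
        if mask.sum() == 0:
            continue
        curve.append((float(s[mask].mean()), float(y[mask].mean()), int(mask.sum())))
    xs = np.array([c[0] for c in curve])
    ys = np.array([c[1] for c in curve])
    if len(curve) >= 2 and np.ptp(xs) > 0:
        slope, intercept = np.polyfit(xs, ys, 1)
    else:  # all bins collapse: undefined line, report identity-offset
        slope, intercept = np.nan, np.nan
    return CalibrationResult(
        intercept_alpha=alpha_hat,
        slope_beta=beta_hat,
        lr_chi2=lr,
        lr_df=2,
        lr_pvalue=pval,
        binned_curve=tuple(curve),
        binned_ols_intercept=float(intercept),
        binned_ols_slope=float(slope),
    )
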