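"""Case-control discrimination and calibration statistics.

- OPERA: odds ratio per age-adjusted standard deviation of a log risk
  score, ``exp(beta * s)`` where ``beta`` is the score's logistic
  coefficient (age-adjusted) and ``s`` the control SD of the age-adjusted
  log score.
- AUC with DeLong variance, and the DeLong paired test for the change in
  AUC between two correlated scores (1 df chi-square).
- Hosmer–Lemeshow decile-of-risk goodness-of-fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass(frozen=True)
class OperaEstimate:
    score_name: str
    opera_or: float
    ci_low: float
    ci_high: float
    p_value: float
    s: float  # control SD of the age-adjusted log score


@dataclass(frozen=True)
class AucEstimate:
    score_name: str
    auc: float
    ci_low: float
    ci_high: float


def _as_binary_status(status) -> np.ndarray:
    status = np.asarray(status)
    if status.dtype.kind in "US" or status.dtype == object:
        y = np.where(status == "case", 1, np.where(status == "control", 0, -1))
        if (y < 0).any():
            raise ValueError("status must be 'case'/'control' or 0/1")
        return y.astype(float)
    y = status.astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("numeric status must be 0/1")
    return y


def opera(
    log_scores,
    status,
    age,
    *,
    score_name: str = "score",
    variant: str = "covariate",
) -> OperaEstimate:
    """Odds ratio per age-adjusted SD of a log risk score.

    ``variant="covariate"`` (default) fits ``status ~ log_score + age``;
    ``variant="residualize"`` first residualizes the log score on age
    (line fitted among controls) and fits ``status ~ residual``.  In both
    cases ``s`` is the SD of the control residuals about the control-fitted
    age line, and OPERA = exp(beta * s) with Wald CI exp((beta +/- 1.96 SE) s).
    """
    x = np.asarray(log_scores, dtype=float)
    y = _as_binary_status(status)
    age = np.asarray(age, dtype=float)
    if len(x) != len(y) or len(x) != len(age):
        raise ValueError("log_scores, status and age must have equal length")
    if len(x) < 20:
        raise ValueError("need at least 20 subjects")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both cases and controls are required")
    if np.std(x) == 0:
        raise ValueError(f"{score_name}: zero-variance score")

    controls = y == 0
    slope, intercept = np.polyfit(age[controls], x[controls], 1)
    resid_controls = x[controls] - (intercept + slope * age[controls])
    n_ctrl = controls.sum()
    s = float(np.sqrt((resid_controls**2).sum() / max(n_ctrl - 2, 1)))

    if variant == "covariate":
        design = sm.add_constant(np.column_stack([x, age]))
    elif variant == "residualize":
        resid_all = x - (intercept + slope * age)
        design = sm.add_constant(resid_all)
    else:
        raise ValueError(f"unknown OPERA variant {variant!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not (np.isfinite(beta) and np.isfinite(se)) or not fit.mle_retvals.get("converged", True):
        raise ValueError(f"{score_name}: logistic fit failed (possible perfect separation)")
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return OperaEstimate(
        score_name=score_name,
        opera_or=float(np.exp(beta * s)),
        ci_low=float(np.exp((beta - Z95 * se) * s)),
        ci_high=float(np.exp((beta + Z95 * se) * s)),
        p_value=p,
        s=s,
    )


# ---------------------------------------------------------------------------
# AUC / DeLong


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (per-case V10, per-control V01)."""
    cases = scores[y == 1]
    controls = scores[y == 0]
    m, n = len(cases), len(controls)
    tx = _midranks(cases)
    ty = _midranks(controls)
    tz = _midranks(np.concatenate([cases, controls]))
    auc_value = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n  # P(case > random control), per case
    v01 = 1.0 - (tz[m:] - ty) / m  # per control
    return float(auc_value), v10, v01


def auc(scores, status, *, score_name: str = "score") -> AucEstimate:
    """Mann–Whitney AUC (ties count half) with a DeLong-variance Wald CI."""
    x = np.asarray(scores, dtype=float)
    y = _as_binary_status(status)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both cases and controls are required")
    auc_value, v10, v01 = _delong_components(x, y)
    var_cases = np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0
    var_ctrls = np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0
    var = var_cases + var_ctrls
    half = Z95 * np.sqrt(var)
    return AucEstimate(
        score_name=score_name,
        auc=auc_value,
        ci_low=float(max(0.0, auc_value - half)),
        ci_high=float(min(1.0, auc_value + half)),
    )


def auc_compare(score_a, score_b, status) -> tuple[float, float]:
    """DeLong paired test for two correlated scores on the same subjects.

    Returns ``(chi_square, p_value)`` with 1 degree of freedom, where
    ``chi_square = (AUC_a - AUC_b)^2 / var(AUC_a - AUC_b)``.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    y = _as_binary_status(status)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired scores must cover the same subjects")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) / m
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) / n
    cov = s10 + s01
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0:
        if abs(delta) > 1e-12:
            raise ValueError("zero variance for a nonzero AUC difference")
        return 0.0, 1.0
    chi2 = float(delta**2 / var_delta)
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# calibration


def hosmer_lemeshow(fitted_probs, status, n_groups: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow decile-of-risk test.

    Groups are equal-count quantile bins of the fitted probabilities with
    ties kept together; groups with zero expected count merge into their
    neighbor.  Returns ``(chi_square, df, p_value)`` with
    ``df = n_groups_used - 2`` (at least 1).
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = _as_binary_status(status)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("fitted probabilities must lie strictly in (0,1)")
    if len(p) < n_groups:
        raise ValueError("fewer observations than groups")

    # quantile edges; ties collapse duplicate edges so tied probs share a bin
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_groups + 1)))
    if len(edges) < 2:
        groups = np.zeros(len(p), dtype=int)
        n_bins = 1
    else:
        groups = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        n_bins = len(edges) - 1

    obs = np.bincount(groups, weights=y, minlength=n_bins)
    exp = np.bincount(groups, weights=p, minlength=n_bins)
    cnt = np.bincount(groups, minlength=n_bins).astype(float)
    keep = cnt > 0
    obs, exp, cnt = obs[keep], exp[keep], cnt[keep]

    # merge zero-expected groups into the previous (or next) bin
    while len(exp) > 1 and (exp == 0).any():
        i = int(np.flatnonzero(exp == 0)[0])
        j = i - 1 if i > 0 else i + 1
        logger.warning("Hosmer-Lemeshow: merging zero-expected group %d into %d", i, j)
        exp[j] += exp[i]
        obs[j] += obs[i]
        cnt[j] += cnt[i]
        exp = np.delete(exp, i)
        obs = np.delete(obs, i)
        cnt = np.delete(cnt, i)

    pbar = exp / cnt
    denom = cnt * pbar * (1 - pbar)
    valid = denom > 0
    chi2 = float(((obs[valid] - exp[valid]) ** 2 / denom[valid]).sum())
    df = max(len(exp) - 2, 1)
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


__all__ = [
    "OperaEstimate",
    "AucEstimate",
    "opera",
    "auc",
    "auc_compare",
    "hosmer_lemeshow",
]
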