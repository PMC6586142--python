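"""Statistical machinery: rank-sum tests, ROC/AUC, DeLong comparisons, OLS.

The AUC is computed as the tie-corrected Mann-Whitney U-statistic — the
probability that a random case scores more extreme than a random control in
the positive direction, with ties earning 0.5.  DeLong's method expresses
the same U-statistic through per-observation "placements": the fraction of
controls each case beats and the fraction of cases each control loses to.
The sample covariances of those placement vectors give the variance of one
AUC and of a difference of two AUCs measured on the same samples, hence a
z-test for correlated ROC curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SigscoreError

logger = logging.getLogger("sigscore")

__all__ = [
    "GroupTestResult",
    "RocCurve",
    "RocComparison",
    "LinearFit",
    "wilcoxon_rank_sum",
    "roc_curve",
    "delong_components",
    "delong_auc_variance",
    "auc_z_test",
    "delong_paired_test",
    "fit_ols",
]

# product of group sizes below which the exact rank-sum null is enumerated
EXACT_WILCOXON_LIMIT = 400


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a two-group location test."""

    statistic: float
    pvalue: float
    n_x: int
    n_y: int
    test_name: str


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over all distinct thresholds, plus its AUC and orientation."""

    thresholds: np.ndarray  # descending cutoffs on the oriented score
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_direction: str  # "larger" or "smaller": which way cases score

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass(frozen=True)
class RocComparison:
    """Paired DeLong comparison of two AUCs measured on the same samples."""

    auc_a: float
    auc_b: float
    variance: float
    z: float
    pvalue: float
    name_a: str = "a"
    name_b: str = "b"
    direction_a: str = "larger"
    direction_b: str = "larger"


@dataclass(frozen=True)
class LinearFit:
    """OLS fit summary with per-coefficient t-tests (the Pr(>|t|) contract)."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residual_variance: float
    rsquared: float
    df_resid: int
    n_obs: int


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise SigscoreError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise SigscoreError(f"{name} contains non-finite values")
    return arr


def wilcoxon_rank_sum(x, y) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The exact null distribution is enumerated when ``n_x * n_y <= 400`` and
    the pooled data are tie-free; otherwise the normal approximation with
    tie and continuity corrections is used.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (xa.size * ya.size <= EXACT_WILCOXON_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_x=xa.size,
        n_y=ya.size,
        test_name=f"wilcoxon_rank_sum[{method}]",
    )


def _oriented(scores: np.ndarray, labels: np.ndarray, positive_direction: str):
    """Resolve orientation; returns (oriented scores, direction string).

    ``auto`` picks the direction in which cases out-rank controls on
    average, so an informative biomarker always yields AUC >= 0.5 — e.g. a
    repression-type score that is *lower* in cases is oriented "smaller".
    The chosen direction is recorded in the returned objects.
    """
    if positive_direction == "auto":
        ranks = stats.rankdata(scores)
        direction = "larger" if ranks[labels == 1].mean() >= ranks[labels == 0].mean() else "smaller"
    elif positive_direction in ("larger", "smaller"):
        direction = positive_direction
    else:
        raise SigscoreError(
            f"positive_direction must be 'larger', 'smaller' or 'auto', got {positive_direction!r}"
        )
    return (scores if direction == "larger" else -scores), direction


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape:
        raise SigscoreError("scores and labels differ in length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        if set(classes.tolist()) <= {0, 1}:
            raise SigscoreError("both classes (cases and controls) must be present")
        raise SigscoreError("labels must be binary 0/1")


def _placements(s: np.ndarray, labels: np.ndarray):
    """Midrank placements: case vs control standings underlying the AUC.

    Returns ``(v_cases, v_controls, auc)`` where ``v_cases[i]`` is the
    fraction of controls case i beats (ties 0.5), ``v_controls[j]`` the
    fraction of cases control j loses to; both vectors average to the AUC.
    """
    cases = s[labels == 1]
    controls = s[labels == 0]
    m, n = cases.size, controls.size
    r_all = stats.rankdata(np.concatenate([cases, controls]))
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    v_cases = (r_all[:m] - r_cases) / n
    v_controls = 1.0 - (r_all[m:] - r_controls) / m
    auc = (r_all[:m].sum() / m - (m + 1) / 2.0) / n
    return v_cases, v_controls, float(auc)


def roc_curve(scores, labels, positive_direction: str = "auto") -> RocCurve:
    """ROC curve and tie-corrected U-statistic AUC.

    Thresholds run over all distinct oriented score values (descending) with
    the degenerate endpoints included, so the curve steps from (0,0) to
    (1,1).  Constant scores give AUC 0.5 with a warning.
    """
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(int).ravel()
    _check_labels(s, y)
    oriented, direction = _oriented(s, y, positive_direction)
    if np.ptp(oriented) == 0:
        logger.warning("constant scores: ROC curve is the diagonal, AUC = 0.5")

    cutoffs = np.unique(oriented)[::-1]
    thresholds = np.concatenate(([np.inf], cutoffs))
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        predicted = oriented >= thr
        tpr[i] = (predicted & (y == 1)).sum() / n_pos
        fpr[i] = (predicted & (y == 0)).sum() / n_neg
    _, _, auc = _placements(oriented, y)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                    positive_direction=direction)


def delong_components(scores, labels, positive_direction: str = "auto"):
    """Structural placements for DeLong's method (see `_placements`)."""
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(int).ravel()
    _check_labels(s, y)
    oriented, direction = _oriented(s, y, positive_direction)
    v_cases, v_controls, auc = _placements(oriented, y)
    return v_cases, v_controls, auc, direction


def delong_auc_variance(scores, labels, positive_direction: str = "auto") -> float:
    """DeLong variance of a single AUC: S_cases/m + S_controls/n."""
    v_cases, v_controls, _, _ = delong_components(scores, labels, positive_direction)
    m, n = v_cases.size, v_controls.size
    s_cases = v_cases.var(ddof=1) if m > 1 else 0.0
    s_controls = v_controls.var(ddof=1) if n > 1 else 0.0
    return float(s_cases / m + s_controls / n)


def auc_z_test(scores, labels, positive_direction: str = "auto",
               null_auc: float = 0.5) -> tuple[float, float, float]:
    """z-test of one AUC against a null value using its DeLong variance.

    Returns ``(auc, z, two-sided p)``; zero variance collapses to z=0, p=1.
    """
    _, _, auc, direction = delong_components(scores, labels, positive_direction)
    var = delong_auc_variance(scores, labels, direction)
    if var <= 0:
        logger.warning("degenerate DeLong variance; reporting z=0, p=1")
        return auc, 0.0, 1.0
    z = (auc - null_auc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc, float(z), float(p)


def delong_paired_test(
    scores_a,
    scores_b,
    labels,
    direction_a: str = "auto",
    direction_b: str = "auto",
    name_a: str = "a",
    name_b: str = "b",
) -> RocComparison:
    """DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be measured on the identical samples; the
    variance of ``auc_a - auc_b`` combines the 2x2 covariance matrices of
    the paired placement vectors within cases and within controls.  A zero
    variance (e.g. a biomarker compared with itself) yields z=0, p=1.
    """
    sa = _as_1d(scores_a, "scores_a")
    sb = _as_1d(scores_b, "scores_b")
    if sa.shape != sb.shape:
        raise SigscoreError("paired DeLong test requires scores over identical samples")
    y = np.asarray(labels).astype(int).ravel()
    va_c, va_n, auc_a, dir_a = delong_components(sa, y, direction_a)
    vb_c, vb_n, auc_b, dir_b = delong_components(sb, y, direction_b)
    m, n = va_c.size, va_n.size

    d_cases = va_c - vb_c
    d_controls = va_n - vb_n
    s_cases = d_cases.var(ddof=1) if m > 1 else 0.0
    s_controls = d_controls.var(ddof=1) if n > 1 else 0.0
    var = s_cases / m + s_controls / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) > 1e-12:
            logger.warning("zero DeLong variance with unequal AUCs; reporting z=0, p=1")
        z, p = 0.0, 1.0
    else:
        z = float(diff / np.sqrt(var))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RocComparison(auc_a=auc_a, auc_b=auc_b, variance=float(max(var, 0.0)),
                         z=z, pvalue=p, name_a=name_a, name_b=name_b,
                         direction_a=dir_a, direction_b=dir_b)


def fit_ols(response, covariates, names=None, add_intercept: bool = True) -> LinearFit:
    """Ordinary least squares with per-coefficient two-sided t-tests.

    ``covariates`` may be a DataFrame (column names used) or a 2-D array
    with ``names``.  The design must be full rank after adding the
    intercept; rank deficiency raises an error naming the collinear
    columns, as does ``n <= p``.
    """
    import statsmodels.api as sm

    y = _as_1d(response, "response")
    if isinstance(covariates, pd.DataFrame):
        X = covariates.to_numpy(dtype=float)
        col_names = list(covariates.columns)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        col_names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != y.size:
        raise SigscoreError(
            f"covariate rows ({X.shape[0]}) do not match response length ({y.size})"
        )
    if not np.all(np.isfinite(X)):
        raise SigscoreError("covariates contain non-finite values")

    if add_intercept:
        design = np.column_stack([np.ones(y.size), X])
        design_names = ["intercept", *col_names]
    else:
        design = X
        design_names = col_names

    n, p = design.shape
    if n <= p:
        raise SigscoreError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        # name columns whose QR pivot magnitude collapses
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        bad = [design_names[i] for i in np.flatnonzero(diag <= tol)] or design_names
        raise SigscoreError(
            "rank-deficient design; collinear columns: " + ", ".join(bad)
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, design).fit()
    idx = pd.Index(design_names)
    return LinearFit(
        params=pd.Series(fit.params, index=idx),
        bse=pd.Series(fit.bse, index=idx),
        tvalues=pd.Series(fit.tvalues, index=idx),
        pvalues=pd.Series(fit.pvalues, index=idx),
        residual_variance=float(fit.mse_resid) if fit.df_resid > 0 else 0.0,
        rsquared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
    )
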