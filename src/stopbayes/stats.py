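"""Sequential-effect statistic and cohort-level regression helpers.

The sequential effect quantifies proactive inhibition as the Pearson
correlation, over a subject's correct go trials, between the trial-wise
stop-signal expectancy p(Stop) and the go reaction time: a subject who
slows down when a stop signal is anticipated shows a positive value.
Cohort analyses are plain Pearson regressions against age (with optional
covariates, in which case the partial correlation is reported), plus a
test for equality of two regression slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "SequentialEffect",
    "RegressionResult",
    "sequential_effect",
    "pearson_regression",
    "slope_difference_test",
    "bonferroni_threshold",
]


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    """Zero-variance input makes the correlation undefined."""


@dataclass(frozen=True)
class SequentialEffect:
    r: float
    n_trials: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation out of range")
        if self.n_trials < 3:
            raise ValueError("need at least 3 trials")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    residual_se: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1.0 + 1e-12:
            raise ValueError("correlation out of range")
        if self.n < 3:
            raise ValueError("need at least 3 observations")


def sequential_effect(
    pstop: np.ndarray,
    go_rt: np.ndarray,
    include_mask: Optional[np.ndarray] = None,
) -> SequentialEffect:
    """Corr(p(Stop), goRT) over the included (go-success) trials.

    ``pstop`` and ``go_rt`` are aligned by trial; ``include_mask`` selects
    the responded go trials (all finite pairs when omitted).  The p-value
    is the usual t transform of r.
    """
    pstop = np.asarray(pstop, dtype=float)
    go_rt = np.asarray(go_rt, dtype=float)
    if pstop.shape != go_rt.shape:
        raise ValueError("pstop and go_rt must be aligned by trial")
    mask = np.isfinite(pstop) & np.isfinite(go_rt)
    if include_mask is not None:
        mask &= np.asarray(include_mask, dtype=bool)
    x, y = pstop[mask], go_rt[mask]
    if x.size < 3:
        raise InsufficientDataError(f"only {x.size} usable trial pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    res = stats.pearsonr(x, y)
    return SequentialEffect(r=float(res.statistic), n_trials=int(x.size), p_value=float(res.pvalue))


def pearson_regression(
    x: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> RegressionResult:
    """OLS of ``y`` on ``x`` (plus optional covariates).

    Without covariates ``r`` is the simple Pearson correlation; with them
    it is the partial correlation of ``x`` and ``y`` given the covariates,
    recovered from the t statistic of the ``x`` coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")

    if covariates is None:
        X = sm.add_constant(x)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
        X = sm.add_constant(np.column_stack([x, cov]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear design: predictor/covariates are rank deficient")
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    tval = float(fit.tvalues[1])
    df = int(fit.df_resid)
    if covariates is None:
        r = float(stats.pearsonr(x, y).statistic) if np.ptp(x) > 0 and np.ptp(y) > 0 else 0.0
    else:
        r = tval / np.sqrt(tval**2 + df) if df > 0 else 0.0
    return RegressionResult(
        slope=slope,
        intercept=float(fit.params[0]),
        r=float(r),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
        residual_se=float(np.sqrt(fit.mse_resid)) if df > 0 else 0.0,
    )


def slope_difference_test(
    x1: np.ndarray,
    y1: np.ndarray,
    x2: np.ndarray,
    y2: np.ndarray,
    paired: bool = True,
) -> tuple[float, float]:
    """Test equality of two regression slopes sharing the predictor.

    ``paired=True`` (default) treats the two outcomes as measured on the
    same subjects against the same predictor and tests the slope of the
    outcome difference ``y1 - y2`` on ``x`` — exact under Gaussian errors.
    ``paired=False`` uses the independent-samples statistic
    ``t = (b1 - b2) / sqrt(SE1^2 + SE2^2)`` with ``n1 + n2 - 4`` df.
    Returns ``(t, two-sided p)``.
    """
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if paired:
        if x1.shape != x2.shape or not np.allclose(x1, x2):
            raise ValueError("paired slope test needs the same predictor values for both outcomes")
        if y1.shape != x1.shape or y2.shape != x1.shape:
            raise ValueError("mismatched sample sizes without pairing information")
        diff = y1 - y2
        if np.ptp(diff) == 0:
            return 0.0, 1.0  # identical outcomes: slopes equal by construction
        fit = sm.OLS(diff, sm.add_constant(x1)).fit()
        return float(fit.tvalues[1]), float(fit.pvalues[1])
    fit1 = sm.OLS(y1, sm.add_constant(x1)).fit()
    fit2 = sm.OLS(y2, sm.add_constant(x2)).fit()
    b1, b2 = fit1.params[1], fit2.params[1]
    se = np.sqrt(fit1.bse[1] ** 2 + fit2.bse[1] ** 2)
    if se == 0:
        return 0.0, 1.0
    t = float((b1 - b2) / se)
    df = x1.size + x2.size - 4
    return t, float(2.0 * stats.t.sf(abs(t), df))


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 4) -> float:
    """Corrected per-test significance threshold (0.05/4 = 0.0125 for the
    four behavior-structure regressions)."""
    if not 0 < alpha < 1 or n_tests < 1:
        raise ValueError("need 0 < alpha < 1 and n_tests >= 1")
    return alpha / n_tests
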