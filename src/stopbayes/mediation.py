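"""Path-equation mediation analysis with bootstrap inference.

Whether a mediator M carries the association between an independent
variable X and an outcome Y is assessed with three OLS equations:

    Y = i1 + c  X           + e1        (total effect)
    Y = i2 + c' X + b M     + e2        (direct effect, M controlled)
    M = i3 + a  X           + e3        (X -> M path)

The indirect effect is the product a*b, which for nested OLS fits on the
same data equals c - c' exactly.  Inference on a*b uses a case-resampling
bootstrap with a bias-corrected percentile interval.  M is declared a
mediator when a, b and a*b are all significant; mediation is *complete*
when additionally c' is not.  The test is only meaningful when X relates
to both Y and M in the first place, so the decision is gated on those two
simple correlations being significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["MediationResult", "mediation_paths", "bootstrap_mediation"]


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int
    p_ab: Optional[float] = None
    ci_ab: Optional[tuple[float, float]] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    preconditions_met: Optional[bool] = None
    mediation: Optional[bool] = None
    complete_mediation: Optional[bool] = None


def _ols(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-sided p-values of an OLS fit."""
    n, p = D.shape
    if np.linalg.matrix_rank(D) < p:
        raise np.linalg.LinAlgError("collinear design (is M a linear function of X?)")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = n - p
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, pvals


def _designs(X, M, C):
    one = np.ones_like(X)
    cols_c = () if C is None else (C,)
    D_total = np.column_stack((one, X) + cols_c)
    D_direct = np.column_stack((one, X, M) + cols_c)
    return D_total, D_direct


def mediation_paths(
    X: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> MediationResult:
    """Point estimates of the paths a, b, c, c' from three OLS fits."""
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    if not (X.shape == M.shape == Y.shape) or X.ndim != 1:
        raise ValueError("X, M, Y must be aligned 1-d vectors")
    n = X.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if not all(np.all(np.isfinite(v)) for v in (X, M, Y)):
        raise ValueError("inputs must be finite")
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
    D_total, D_direct = _designs(X, M, C)
    beta_c, p_c = _ols(D_total, Y)
    beta_d, p_d = _ols(D_direct, Y)
    beta_a, p_a = _ols(D_total, M)
    a, b = float(beta_a[1]), float(beta_d[2])
    return MediationResult(
        a=a,
        b=b,
        c=float(beta_c[1]),
        c_prime=float(beta_d[1]),
        ab=a * b,
        p_a=float(p_a[1]),
        p_b=float(p_d[2]),
        p_c=float(p_c[1]),
        p_c_prime=float(p_d[1]),
        n=n,
    )


def _batch_ab(X, M, Y, C, idx):
    """Indirect-effect estimates a*b (and a, b, c') for resampled rows.

    Solves the normal equations of the two relevant fits for every
    bootstrap resample at once; returns (a, b, ab) arrays and a validity
    mask (False where a resample is degenerate).
    """
    Xb, Mb, Yb = X[idx], M[idx], Y[idx]
    one = np.ones_like(Xb)
    cols = [one, Xb, Mb]
    if C is not None:
        for j in range(C.shape[1]):
            cols.append(C[idx, j])
    D = np.stack(cols, axis=-1)  # boot x n x p  (direct-effect design)
    Da = D[:, :, [0, 1]] if C is None else D[:, :, [0, 1] + list(range(3, D.shape[2]))]

    def solve(Db, yb):
        G = np.einsum("bni,bnj->bij", Db, Db)
        h = np.einsum("bni,bn->bi", Db, yb)
        ok = np.abs(np.linalg.det(G)) > 1e-12 * np.abs(G[:, 0, 0]) ** Db.shape[2]
        beta = np.full((Db.shape[0], Db.shape[2]), np.nan)
        if ok.any():
            beta[ok] = np.linalg.solve(G[ok], h[ok][..., None])[..., 0]
        return beta, ok

    beta_m, ok_m = solve(Da, Mb)  # M ~ 1 + X (+C)
    beta_y, ok_y = solve(D, Yb)  # Y ~ 1 + X + M (+C)
    a = beta_m[:, 1]
    b = beta_y[:, 2]
    ok = ok_m & ok_y & np.isfinite(a) & np.isfinite(b)
    return a, b, a * b, ok


def bootstrap_mediation(
    X: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_boot: int = 10000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    alpha: float = 0.05,
) -> MediationResult:
    """Case-resampling bootstrap of the indirect effect a*b.

    Returns the point estimates together with a bias-corrected percentile
    CI, a two-sided bootstrap p-value for a*b, and the mediation decision
    (gated on significant X-Y and X-M correlations).  Same seed and inputs
    reproduce the interval bit-identically.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    point = mediation_paths(X, M, Y, covariates=covariates)
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != X.size:
            C = C.T
    rng = np.random.default_rng(seed)
    n = X.size

    idx = rng.integers(0, n, size=(n_boot, n))
    _, _, ab_boot, ok = _batch_ab(X, M, Y, C, idx)
    n_redrawn = 0
    for _ in range(100):
        if ok.all():
            break
        bad = ~ok
        n_redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        _, _, ab_new, ok_new = _batch_ab(X, M, Y, C, idx[bad])
        ab_boot[bad] = ab_new
        ok[bad] = ok_new
    if not ok.all():
        raise RuntimeError("bootstrap kept producing degenerate resamples")
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} degenerate bootstrap resamples")

    # bias-corrected percentile interval
    prop_below = np.clip(np.mean(ab_boot < point.ab), 1.0 / n_boot, 1.0 - 1.0 / n_boot)
    z0 = stats.norm.ppf(prop_below)
    zlo = stats.norm.ppf((1.0 - ci_level) / 2.0)
    lo_q = stats.norm.cdf(2.0 * z0 + zlo)
    hi_q = stats.norm.cdf(2.0 * z0 - zlo)
    ci = (float(np.quantile(ab_boot, lo_q)), float(np.quantile(ab_boot, hi_q)))

    p_ab = 2.0 * min(np.mean(ab_boot <= 0.0), np.mean(ab_boot >= 0.0))
    p_ab = float(max(p_ab, 1.0 / n_boot))

    r_xy = stats.pearsonr(X, Y)
    r_xm = stats.pearsonr(X, M)
    preconditions = bool(r_xy.pvalue < alpha and r_xm.pvalue < alpha)
    significant = p_ab < alpha and point.p_a < alpha and point.p_b < alpha
    mediation = bool(preconditions and significant)
    complete = bool(mediation and point.p_c_prime >= alpha)
    return MediationResult(
        a=point.a,
        b=point.b,
        c=point.c,
        c_prime=point.c_prime,
        ab=point.ab,
        p_a=point.p_a,
        p_b=point.p_b,
        p_c=point.p_c,
        p_c_prime=point.p_c_prime,
        n=point.n,
        p_ab=p_ab,
        ci_ab=ci,
        n_boot=n_boot,
        seed=seed,
        preconditions_met=preconditions,
        mediation=mediation,
        complete_mediation=complete,
    )
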