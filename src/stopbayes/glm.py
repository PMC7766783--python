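"""First-level fMRI GLM design construction and AR(1) fitting.

Two design variants mirror the standard model-based analysis of the
stop-signal task:

* **GLM1** anchors event regressors at the go-signal onsets and carries the
  parametric modulators ``RT of GS trials``, ``SSD of SS trials`` and
  ``SSD of SE trials``, in that order.
* **GLM2** anchors at the fixation (trial) onsets and carries ``p(Stop) of
  GS``, ``SSD of SS``, ``p(Stop) of SS``, ``SSD of SE`` and ``p(Stop) of
  SE``, in that order.

Each trial-outcome condition (GS, GE, SS, SE) contributes a canonical
double-gamma HRF regressor plus its temporal derivative; modulators are
mean-centered within condition, multiplied into the condition's event
train, convolved and (optionally, the default) serially orthogonalized
against the condition's earlier columns.  A discrete-cosine drift basis up
to the 1/128 Hz cutoff, optional motion nuisance columns and a constant
complete the matrix.  Fitting estimates the lag-1 residual autocorrelation,
prewhitens, refits, and evaluates contrasts (e.g. SS > GS, or "1" on a
modulator) on the whitened model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sst import TrialRecord

__all__ = [
    "HrfSpec",
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "dct_drift_basis",
    "build_design",
    "fit_glm_ar1",
    "contrast_vector",
]

CONDITION_ORDER = ("GS", "GE", "SS", "SE")

#: Modulator schedule per model: (column name, condition, trial attribute).
MODULATORS = {
    "GLM1": (("GSxRT", "GS", "rt"), ("SSxSSD", "SS", "ssd"), ("SExSSD", "SE", "ssd")),
    "GLM2": (
        ("GSxpstop", "GS", "pstop"),
        ("SSxSSD", "SS", "ssd"),
        ("SSxpstop", "SS", "pstop"),
        ("SExSSD", "SE", "ssd"),
        ("SExpstop", "SE", "pstop"),
    ),
}


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF: a peak gamma density minus a scaled
    undershoot gamma density (peak 6 s, undershoot 16 s, ratio 6)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion_s",
            "undershoot_dispersion_s",
            "peak_undershoot_ratio",
            "kernel_length_s",
            "dt_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.kernel_length_s / self.dt_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt_s must divide kernel_length_s")


def canonical_hrf(spec: HrfSpec = HrfSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Sampled HRF kernel and its temporal-derivative kernel.

    The derivative is the finite difference between the kernel and the
    kernel shifted by one ``dt``; peak is normalized to 1 (contrasts are
    invariant to kernel scale).
    """
    from scipy import stats

    t = np.arange(0.0, spec.kernel_length_s, spec.dt_s)
    h = stats.gamma.pdf(
        t, spec.peak_delay_s / spec.peak_dispersion_s, scale=spec.peak_dispersion_s
    ) - stats.gamma.pdf(
        t, spec.undershoot_delay_s / spec.undershoot_dispersion_s,
        scale=spec.undershoot_dispersion_s,
    ) / spec.peak_undershoot_ratio
    h = h / np.max(np.abs(h))
    shifted = np.concatenate([[0.0], h[:-1]])
    dh = (h - shifted) / spec.dt_s
    return h, dh


def dct_drift_basis(n_scans: int, tr_s: float, hp_cutoff_s: float) -> np.ndarray:
    """Discrete cosine drift basis covering frequencies below the high-pass
    cutoff (the convention of standard fMRI packages), constant excluded."""
    order = int(np.floor(2.0 * n_scans * tr_s / hp_cutoff_s))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * j / (2.0 * n_scans))
        for j in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass(frozen=True)
class DesignMatrix:
    """Scans-by-regressors design with named columns."""

    frame: pd.DataFrame
    tr_s: float
    hp_cutoff_s: float

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_scans(self) -> int:
        return self.frame.shape[0]


def _ortho(col: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Residualize col against the span of basis columns."""
    if not basis:
        return col
    B = np.column_stack(basis)
    coef, *_ = np.linalg.lstsq(B, col, rcond=None)
    return col - B @ coef


def build_design(
    trials: Sequence[TrialRecord],
    model: str = "GLM1",
    pstop: Optional[Sequence[float]] = None,
    hrf: HrfSpec = HrfSpec(),
    n_scans: int = 300,
    tr_s: float = 2.0,
    nuisance: Optional[np.ndarray] = None,
    hp_cutoff_s: float = 128.0,
    discard_volumes: int = 5,
    go_delay_s: float = 2.0,
    orthogonalize: bool = True,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one session.

    ``trials`` carry fixation onsets; GLM1 anchors events at
    ``onset + go_delay_s`` (the go signal), GLM2 at the fixation onset.
    ``pstop`` (trial-aligned) is required for GLM2.  The first
    ``discard_volumes`` scans are dropped: onsets shift back by
    ``discard_volumes * tr_s`` and the matrix has ``n_scans -
    discard_volumes`` rows.  Events are zero-duration impulses.
    """
    if model not in MODULATORS:
        raise ValueError(f"unknown model {model!r}; expected GLM1 or GLM2")
    if model == "GLM2" and pstop is None:
        raise ValueError("GLM2 requires the trial-wise pstop series")
    if pstop is not None and len(pstop) != len(trials):
        raise ValueError("pstop must be aligned with trials")

    n_kept = n_scans - discard_volumes
    if n_kept <= 0:
        raise ValueError("no scans left after discarding initial volumes")
    shift = discard_volumes * tr_s
    t_end = n_kept * tr_s

    anchor_offset = go_delay_s if model == "GLM1" else 0.0
    per_trial: dict[str, list[tuple[float, dict]]] = {c: [] for c in CONDITION_ORDER}
    n_clipped = 0
    for i, tr in enumerate(trials):
        onset = tr.onset_s + anchor_offset - shift
        if onset < 0 or onset >= t_end:
            n_clipped += 1
            continue
        attrs = {
            "rt": tr.rt_ms,
            "ssd": tr.ssd_ms,
            "pstop": None if pstop is None else float(pstop[i]),
        }
        per_trial[tr.outcome].append((onset, attrs))
    if n_clipped:
        warnings.warn(f"{n_clipped} events outside the scan window were clipped")

    h, dh = canonical_hrf(hrf)
    dt = hrf.dt_s
    n_hi = int(np.ceil(t_end / dt)) + h.size
    scan_idx = (np.round(np.arange(n_kept) * tr_s / dt)).astype(int)

    def convolved(onsets_w: Sequence[tuple[float, float]], kernel: np.ndarray) -> np.ndarray:
        train = np.zeros(n_hi)
        for onset, w in onsets_w:
            train[int(np.round(onset / dt))] += w
        return np.convolve(train, kernel)[:n_hi][scan_idx]

    columns: dict[str, np.ndarray] = {}
    cond_cols: dict[str, str] = {}
    present = [c for c in CONDITION_ORDER if per_trial[c]]
    for cond in present:
        events = [(on, 1.0) for on, _ in per_trial[cond]]
        columns[cond] = convolved(events, h)
        columns[f"{cond}_deriv"] = convolved(events, dh)
        cond_cols[cond] = cond

    ortho_basis: dict[str, list[np.ndarray]] = {c: [columns[c]] for c in present}
    for name, cond, attr in MODULATORS[model]:
        if cond not in present:
            continue
        vals = np.array([a[attr] for _, a in per_trial[cond]], dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"modulator {name} has missing values")
        if np.ptp(vals) == 0:
            warnings.warn(f"modulator {name} has zero variance and was omitted")
            continue
        centered = vals - vals.mean()
        events = [(on, w) for (on, _), w in zip(per_trial[cond], centered)]
        col = convolved(events, h)
        if orthogonalize:
            col = _ortho(col, ortho_basis[cond])
        columns[name] = col
        ortho_basis[cond].append(col)

    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.shape[0] != n_kept:
            raise ValueError("nuisance rows must match the kept scans")
        for j in range(nuis.shape[1]):
            columns[f"motion{j + 1}"] = nuis[:, j]

    drift = dct_drift_basis(n_kept, tr_s, hp_cutoff_s)
    for j in range(drift.shape[1]):
        columns[f"drift{j + 1}"] = drift[:, j]
    columns["constant"] = np.ones(n_kept)

    return DesignMatrix(frame=pd.DataFrame(columns), tr_s=tr_s, hp_cutoff_s=hp_cutoff_s)


def _whiten(a: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening transform (first row scaled by sqrt(1-rho^2)),
    making whitened OLS identical to GLS under the AR(1) covariance."""
    out = a.astype(float).copy()
    out[1:] = a[1:] - rho * a[:-1]
    out[0] = np.sqrt(1.0 - rho**2) * a[0]
    return out


@dataclass
class GlmFit:
    """Whitened-GLM fit for one or more voxels."""

    design: DesignMatrix
    betas: pd.DataFrame  # regressors x voxels
    ar1_rho: np.ndarray  # per voxel
    sigma2: np.ndarray  # per voxel residual variance (whitened)
    _cov_unscaled: np.ndarray = field(repr=False)  # voxels x p x p
    df_resid: int = 0

    def contrast(self, weights: Mapping[str, float] | np.ndarray) -> pd.DataFrame:
        """Evaluate a linear contrast of the betas per voxel.

        Returns estimate, standard error, t and two-sided p.
        """
        from scipy import stats

        c = contrast_vector(self.design, weights) if isinstance(weights, Mapping) else np.asarray(weights, float)
        if c.size != self.betas.shape[0]:
            raise ValueError("contrast length must match the number of regressors")
        est = c @ self.betas.to_numpy()
        var = self.sigma2 * np.einsum("i,vij,j->v", c, self._cov_unscaled, c)
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame({"estimate": est, "se": se, "t": t, "p": p})


def contrast_vector(design: DesignMatrix, weights: Mapping[str, float]) -> np.ndarray:
    """Build a contrast vector from a name->weight mapping (e.g.
    ``{"SS": 1, "GS": -1}`` for stop success > go success)."""
    c = np.zeros(len(design.names))
    for name, w in weights.items():
        if name not in design.names:
            raise KeyError(f"regressor {name!r} not in design ({design.names})")
        c[design.names.index(name)] = w
    return c


def fit_glm_ar1(
    Y: np.ndarray,
    design: DesignMatrix,
    pooled_rho: bool = False,
) -> GlmFit:
    """Fit voxel time series with AR(1) prewhitening.

    ``Y`` is scans x voxels (a 1-d vector is treated as one voxel).  The
    lag-1 autocorrelation is estimated from OLS residuals (per voxel by
    default, pooled across voxels with ``pooled_rho=True``), both sides of
    the model are whitened, and the model is refit.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y rows must equal design rows")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta_ols
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid[:-1] ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    rho = np.clip(rho, -0.99, 0.99)
    if pooled_rho:
        rho = np.full(Y.shape[1], float(rho.mean()))

    n_vox = Y.shape[1]
    betas = np.empty((p, n_vox))
    sigma2 = np.empty(n_vox)
    cov_unscaled = np.empty((n_vox, p, p))
    df = X.shape[0] - p
    for v in range(n_vox):
        Xw = _whiten(X, rho[v])
        yw = _whiten(Y[:, v], rho[v])
        b, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rw = yw - Xw @ b
        betas[:, v] = b
        sigma2[v] = rw @ rw / df if df > 0 else np.nan
        cov_unscaled[v] = np.linalg.inv(Xw.T @ Xw)
    return GlmFit(
        design=design,
        betas=pd.DataFrame(betas, index=design.names),
        ar1_rho=rho,
        sigma2=sigma2,
        _cov_unscaled=cov_unscaled,
        df_resid=df,
    )
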