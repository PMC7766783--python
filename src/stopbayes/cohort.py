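"""Synthetic study generator with known ground truth.

Builds a cohort of subjects — age, sex, race-model parameters, regional
gray-matter volumes (GMV) and fMRI contrast betas — whose correlation
structure with age is controlled, then simulates each subject's
staircase-tracked stop-signal sessions so every stage of the pipeline
(p(Stop), SSRT, sequential effect, regressions, mediation) can be checked
against the generating values.

Subject-level traits follow a single-factor Gaussian model: each latent
trait equals ``rho * z_age + sqrt(1 - rho^2) * noise``, which hits the
target age correlation for every trait and is positive semi-definite by
construction.  A mediation chain (age -> anterior GMV -> SSRT) can be
switched on to give the mediation stage a known indirect effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .glm import DesignMatrix
from .observer import ObserverParams
from .sst import RaceParams, SessionDesign, simulate_session
from .ssrt import estimate_ssrt
from .stats import sequential_effect

__all__ = ["CohortSpec", "generate_cohort", "analyze_cohort", "generate_voxel_bold"]

#: traits whose age-correlation is targeted, with (mean, sd) on their
#: natural scale; means/SDs follow the behavioral scales of a typical
#: adult SST cohort and arbitrary-but-fixed units for GMV (ml) and betas.
_TRAIT_SCALES = {
    "ssrt_true_ms": (206.0, 37.0),
    "gort_shift_ms": (0.0, 119.0),
    "proactive_gain_ms": (400.0, 100.0),
    "gmv_anterior": (3.5, 0.35),
    "gmv_posterior": (2.5, 0.25),
    "beta_ssgs": (0.5, 0.3),
    "beta_pstop": (0.3, 0.3),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, age distribution and target age correlations.

    Defaults describe a 149-subject adult cohort (83 women), ages 18-72
    with mean 31.6 and SD 11.9, SSRT correlating ~0.27 with age, go RT
    ~0.17, a near-zero age trend of the sequential effect, age-declining
    anterior/posterior GMV, and age-correlated contrast betas.
    """

    n_subjects: int = 149
    age_min: float = 18.0
    age_max: float = 72.0
    age_mean: float = 31.6
    age_sd: float = 11.9
    sex_ratio: float = 83.0 / 149.0  # proportion of women
    r_age_ssrt: float = 0.2671
    r_age_gort: float = 0.1671
    r_age_seqeffect: float = -0.0510
    r_age_gmv_anterior: float = -0.2554
    r_age_gmv_posterior: float = -0.2486
    r_age_beta_ssgs: float = -0.26
    r_age_beta_pstop: float = 0.30
    mediation_mode: str = "none"  # none | full | partial
    mediation_a: float = -0.55  # age -> anterior GMV (latent scale)
    mediation_b: float = -0.55  # anterior GMV -> SSRT (latent scale)
    mediation_direct: float = 0.30  # residual direct age -> SSRT (partial mode)
    n_sessions: int = 4
    trials_per_session: int = 100
    n_three_session_subjects: int = 3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if self.mediation_mode not in ("none", "full", "partial"):
            raise ValueError("mediation_mode must be none, full or partial")
        for name, r in self.target_correlations().items():
            if not -1.0 < r < 1.0:
                raise ValueError(
                    f"infeasible correlation target age<->{name}: {r} not in (-1, 1)"
                )

    def target_correlations(self) -> dict[str, float]:
        return {
            "ssrt_true_ms": self.r_age_ssrt,
            "gort_shift_ms": self.r_age_gort,
            "proactive_gain_ms": self.r_age_seqeffect,
            "gmv_anterior": self.r_age_gmv_anterior,
            "gmv_posterior": self.r_age_gmv_posterior,
            "beta_ssgs": self.r_age_beta_ssgs,
            "beta_pstop": self.r_age_beta_pstop,
        }

    def implied_correlation_matrix(self) -> np.ndarray:
        """Full trait correlation matrix implied by the single-factor model
        (validated PSD; a violation names the offending pair)."""
        rhos = np.array([1.0] + list(self.target_correlations().values()))
        R = np.outer(rhos, rhos)
        np.fill_diagonal(R, 1.0)
        names = ["age"] + list(self.target_correlations())
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            worst = np.unravel_index(np.argmax(np.abs(R - np.eye(len(R)))), R.shape)
            raise ValueError(
                "infeasible correlation matrix (not PSD); "
                f"largest off-diagonal entry at {names[worst[0]]}<->{names[worst[1]]}"
            )
        return R


def _truncnorm_z(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ages from a truncated normal on [age_min, age_max]; returns
    (age, standardized age score)."""
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    b = (spec.age_max - spec.age_mean) / spec.age_sd
    u = rng.random(spec.n_subjects)
    age = stats.truncnorm.ppf(u, a, b, loc=spec.age_mean, scale=spec.age_sd)
    z = (age - age.mean()) / age.std()
    return age, z


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    observer_params: Optional[ObserverParams] = ObserverParams(),
    simulate_behavior: bool = True,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Draw a cohort table and (optionally) simulate each subject's sessions.

    Returns ``(table, events)`` where ``events`` maps subject id to the
    list of that subject's simulated sessions (each a list of trial
    records; the staircase and the observer restart at every session).
    The proactive slowing of each subject's go process is driven by the
    Bayesian observer when ``observer_params`` is given.  Same seed gives
    an identical cohort.
    """
    spec.implied_correlation_matrix()  # feasibility gate
    if seed is None:
        seed = spec.seed
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    age, z_age = _truncnorm_z(spec, rng)
    n_women = int(round(spec.sex_ratio * spec.n_subjects))
    sex = np.array(["F"] * n_women + ["M"] * (spec.n_subjects - n_women))
    rng.shuffle(sex)

    targets = spec.target_correlations()
    z: dict[str, np.ndarray] = {}
    for name, rho in targets.items():
        eps = rng.standard_normal(spec.n_subjects)
        z[name] = rho * z_age + np.sqrt(1.0 - rho**2) * eps

    if spec.mediation_mode != "none":
        # overwrite the GMV->SSRT pair with an explicit causal chain
        a_lat, b_lat = spec.mediation_a, spec.mediation_b
        z["gmv_anterior"] = a_lat * z_age + np.sqrt(1.0 - a_lat**2) * rng.standard_normal(
            spec.n_subjects
        )
        direct = spec.mediation_direct if spec.mediation_mode == "partial" else 0.0
        resid_var = 1.0 - b_lat**2 - direct**2 - 2.0 * a_lat * b_lat * direct
        if resid_var <= 0:
            raise ValueError("infeasible mediation effect sizes (residual variance <= 0)")
        z["ssrt_true_ms"] = (
            b_lat * z["gmv_anterior"]
            + direct * z_age
            + np.sqrt(resid_var) * rng.standard_normal(spec.n_subjects)
        )

    table = pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:03d}" for i in range(spec.n_subjects)],
            "age": age,
            "sex": sex,
        }
    )
    for name, (mean, sd) in _TRAIT_SCALES.items():
        table[name] = mean + sd * z[name]
    table["ssrt_true_ms"] = table["ssrt_true_ms"].clip(lower=80.0)
    table["proactive_gain_ms"] = table["proactive_gain_ms"].clip(lower=0.0)
    table["n_sessions"] = spec.n_sessions
    if spec.n_three_session_subjects > 0:
        # a small minority completes one session fewer (at least one)
        table.loc[: spec.n_three_session_subjects - 1, "n_sessions"] = max(spec.n_sessions - 1, 1)

    events: dict[str, list] = {}
    if simulate_behavior:
        subj_seeds = root.spawn(spec.n_subjects)
        base = RaceParams()
        for i, row in table.iterrows():
            params = RaceParams(
                go_mu_ms=max(base.go_mu_ms + row["gort_shift_ms"], 150.0),
                go_sigma_ms=base.go_sigma_ms,
                go_tau_ms=base.go_tau_ms,
                ssrt_true_ms=row["ssrt_true_ms"],
                ssrt_sd_ms=base.ssrt_sd_ms,
                go_omission_rate=base.go_omission_rate,
                proactive_gain_ms=row["proactive_gain_ms"],
            )
            design = SessionDesign(n_trials=spec.trials_per_session)
            sess_seeds = subj_seeds[i].generate_state(int(row["n_sessions"]), dtype=np.uint32)
            events[row["subject"]] = [
                simulate_session(design, params, observer_params=observer_params, seed=int(s))
                for s in sess_seeds
            ]
    return table, events


def analyze_cohort(
    table: pd.DataFrame,
    events: dict[str, list],
    observer_params: ObserverParams = ObserverParams(),
    ssrt_method: str = "critical_ssd",
) -> pd.DataFrame:
    """Run the behavioral pipeline per subject and append derived columns:
    estimated SSRT, median go RT, stop-respond rate and sequential effect.

    p(Stop) is computed per session (the observer restarts with its prior
    at each session start) and pooled across sessions for the sequential
    effect.
    """
    from .observer import pstop_sequence

    out = table.copy()
    cols = {"ssrt_est_ms": [], "median_gort_ms": [], "p_respond_stop": [], "seq_effect": []}
    for subject in out["subject"]:
        sessions = events[subject]
        est = estimate_ssrt(sessions, method=ssrt_method)
        pstop = np.concatenate(
            [
                pstop_sequence([1 if t.category == "stop" else 0 for t in sess], observer_params)
                for sess in sessions
            ]
        )
        flat = [t for sess in sessions for t in sess]
        rts = np.array([t.rt_ms if t.rt_ms is not None else np.nan for t in flat])
        mask = np.array([t.outcome == "GS" for t in flat])
        seq = sequential_effect(pstop, rts, include_mask=mask)
        cols["ssrt_est_ms"].append(est.ssrt_ms)
        cols["median_gort_ms"].append(est.median_gort_ms)
        cols["p_respond_stop"].append(est.p_respond_stop)
        cols["seq_effect"].append(seq.r)
    for k, v in cols.items():
        out[k] = v
    return out


def generate_voxel_bold(
    design: DesignMatrix,
    beta_true: np.ndarray,
    ar1_rho: float = 0.0,
    noise_sd: float = 1.0,
    seed: Optional[int] = None,
    n_voxels: int = 1,
) -> np.ndarray:
    """Synthetic BOLD: ``Y = X @ beta_true + AR(1) noise`` (scans x voxels).

    The noise is a stationary AR(1) process with lag-1 correlation
    ``ar1_rho`` and innovation SD scaled so the marginal SD is
    ``noise_sd``.
    """
    if not -1.0 < ar1_rho < 1.0:
        raise ValueError("|ar1_rho| must be < 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    X = design.matrix
    beta_true = np.asarray(beta_true, float)
    if beta_true.ndim == 1:
        beta_true = beta_true[:, None]
    if beta_true.shape[0] != X.shape[1]:
        raise ValueError("beta_true length must match the number of regressors")
    if beta_true.shape[1] == 1 and n_voxels > 1:
        beta_true = np.repeat(beta_true, n_voxels, axis=1)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    innov_sd = noise_sd * np.sqrt(1.0 - ar1_rho**2)
    noise = np.empty((n, beta_true.shape[1]))
    noise[0] = rng.normal(0.0, noise_sd, size=beta_true.shape[1])
    e = rng.normal(0.0, innov_sd, size=(n - 1, beta_true.shape[1]))
    for t in range(1, n):
        noise[t] = ar1_rho * noise[t - 1] + e[t - 1]
    return X @ beta_true + noise
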