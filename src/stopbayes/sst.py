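"""Stop-signal task simulation.

The stop-signal task (SST) interleaves frequent go trials with occasional
stop trials on which a stop signal, presented at a delay (SSD) after the go
signal, instructs the subject to withhold the prepared response.  Behavior
is generated from an independent horse-race between a go process and a stop
process: whichever finishes first determines the trial outcome.  The SSD is
adapted by a one-up-one-down staircase that converges on the delay at which
the subject stops on about half of the stop trials.

The go finish time is drawn from an ex-Gaussian distribution (the standard
right-skewed family for reaction times), optionally slowed in proportion to
the subject's current belief that a stop signal is imminent (``p(Stop)``
from :mod:`stopbayes.observer`) — a simple linear mechanism for proactive
slowing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OUTCOMES",
    "TrialRecord",
    "SessionDesign",
    "RaceParams",
    "update_ssd",
    "race_trial",
    "simulate_session",
]

#: Trial outcome codes: go success, go error (omission), stop success
#: (response withheld), stop error (response emitted despite the signal).
OUTCOMES = ("GS", "GE", "SS", "SE")


@dataclass(frozen=True)
class TrialRecord:
    """One stop-signal-task trial.

    ``category`` is ``"go"`` or ``"stop"``; ``ssd_ms`` is the stop-signal
    delay and is ``None`` on go trials; ``rt_ms`` is present iff the subject
    responded.  ``onset_s`` is the trial (fixation) onset from session start.
    """

    index: int
    onset_s: float
    category: str
    ssd_ms: Optional[float]
    responded: bool
    rt_ms: Optional[float]
    outcome: str

    def __post_init__(self) -> None:
        if self.category not in ("go", "stop"):
            raise ValueError(f"unknown trial category {self.category!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.category == "go" and self.ssd_ms is not None:
            raise ValueError("go trial must have null ssd_ms")
        if self.category == "stop" and self.ssd_ms is None:
            raise ValueError("stop trial must carry an SSD")
        if self.outcome == "SS" and (self.category != "stop" or self.responded):
            raise ValueError("SS requires a stop trial without a response")
        if self.outcome == "SE" and (self.category != "stop" or not self.responded):
            raise ValueError("SE requires a stop trial with a response")
        if self.outcome in ("GS", "GE") and self.category != "go":
            raise ValueError(f"{self.outcome} requires a go trial")
        if self.responded != (self.rt_ms is not None):
            raise ValueError("rt_ms must be present iff responded")
        if self.rt_ms is not None and not self.rt_ms > 0:
            raise ValueError("rt_ms must be positive")


@dataclass(frozen=True)
class SessionDesign:
    """Session layout and staircase schedule.

    Defaults give ~100-trial sessions with 25% stop trials; the staircase
    starts at 200 ms and moves in 67 ms steps, clamped to [0, 1500] ms
    (the task literature states no bounds; an SSD cannot be negative and
    1500 ms exceeds any plausible delay).
    """

    n_trials: int = 100
    stop_fraction: float = 0.25
    ssd_start_ms: float = 200.0
    ssd_step_ms: float = 67.0
    ssd_min_ms: float = 0.0
    ssd_max_ms: float = 1500.0
    inter_onset_s: float = 6.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError("stop_fraction must lie in (0, 1)")
        if self.ssd_step_ms <= 0:
            raise ValueError("ssd_step_ms must be positive")
        if self.ssd_min_ms < 0 or self.ssd_min_ms >= self.ssd_max_ms:
            raise ValueError("need 0 <= ssd_min_ms < ssd_max_ms")
        if self.inter_onset_s <= 0:
            raise ValueError("inter_onset_s must be positive")


@dataclass(frozen=True)
class RaceParams:
    """Generative race-model parameters for one subject.

    The go finish time is ex-Gaussian(go_mu, go_sigma, go_tau) plus
    ``proactive_gain_ms`` times the current stop-signal expectancy; the stop
    process finishes Normal(ssrt_true, ssrt_sd) ms after the stop signal.
    Defaults put the median go RT near 628 ms and the true SSRT at 200 ms.
    """

    go_mu_ms: float = 505.0
    go_sigma_ms: float = 60.0
    go_tau_ms: float = 165.0
    ssrt_true_ms: float = 200.0
    ssrt_sd_ms: float = 30.0
    go_omission_rate: float = 0.02
    proactive_gain_ms: float = 0.0

    def __post_init__(self) -> None:
        for name in ("go_mu_ms", "go_sigma_ms", "go_tau_ms", "ssrt_true_ms", "ssrt_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.go_omission_rate < 1.0:
            raise ValueError("go_omission_rate must lie in [0, 1)")


def update_ssd(ssd_ms: float, outcome: str, design: SessionDesign) -> float:
    """One staircase move: +step after a stop success, −step after a stop error.

    The result is clamped to ``[design.ssd_min_ms, design.ssd_max_ms]``.
    """
    if outcome == "SS":
        nxt = ssd_ms + design.ssd_step_ms
    elif outcome == "SE":
        nxt = ssd_ms - design.ssd_step_ms
    else:
        raise ValueError(f"staircase updates only on stop outcomes, got {outcome!r}")
    return float(min(max(nxt, design.ssd_min_ms), design.ssd_max_ms))


def _sample_go_finish(params: RaceParams, pstop_belief: float, rng: np.random.Generator) -> float:
    # exGaussian = Normal + Exponential; resample non-finite, clamp at 1 ms
    while True:
        t = (
            rng.normal(params.go_mu_ms, params.go_sigma_ms)
            + rng.exponential(params.go_tau_ms)
            + params.proactive_gain_ms * pstop_belief
        )
        if np.isfinite(t):
            return max(t, 1.0)


def race_trial(
    category: str,
    ssd_ms: Optional[float],
    params: RaceParams,
    pstop_belief: float,
    rng: np.random.Generator,
) -> tuple[bool, Optional[float], str]:
    """Run the go/stop race for one trial.

    Returns ``(responded, rt_ms, outcome)``.  On stop trials the subject
    responds iff the go process beats ``ssd + stop finish time``; on go
    trials the response is omitted with probability ``go_omission_rate``.
    """
    if category == "go":
        if rng.random() < params.go_omission_rate:
            return False, None, "GE"
        t_go = _sample_go_finish(params, pstop_belief, rng)
        return True, t_go, "GS"
    if category == "stop":
        if ssd_ms is None:
            raise ValueError("stop trial requires an SSD")
        t_go = _sample_go_finish(params, pstop_belief, rng)
        while True:
            t_stop = ssd_ms + rng.normal(params.ssrt_true_ms, params.ssrt_sd_ms)
            if np.isfinite(t_stop):
                break
        t_stop = max(t_stop, 1.0)
        if t_go < t_stop:
            return True, t_go, "SE"
        return False, None, "SS"
    raise ValueError(f"unknown trial category {category!r}")


def simulate_session(
    design: SessionDesign,
    params: RaceParams,
    observer_params=None,
    seed: Optional[int] = None,
) -> list[TrialRecord]:
    """Simulate one staircase-tracked SST session.

    Trial categories are drawn i.i.d. with ``design.stop_fraction``; the SSD
    follows the one-up-one-down staircase across successive stop trials,
    starting at ``design.ssd_start_ms``.  When ``observer_params`` (an
    :class:`stopbayes.observer.ObserverParams`) is given, the Bayesian
    observer is run alongside the session and its trial-wise p(Stop) drives
    the proactive slowing term; otherwise the static ``stop_fraction`` is
    used as the belief.  Identical ``(design, params, seed)`` reproduce the
    records bit-identically.
    """
    if design.n_trials < 10:
        raise ValueError("session too short for the staircase (need >= 10 trials)")
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)

    belief_state = None
    if observer_params is not None:
        from .observer import init_prior  # local import: avoid cycle at module load

        belief_state = init_prior(observer_params)

    records: list[TrialRecord] = []
    ssd = float(design.ssd_start_ms)
    categories = np.where(rng.random(design.n_trials) < design.stop_fraction, "stop", "go")
    for k, category in enumerate(categories):
        pstop = belief_state.pstop if belief_state is not None else design.stop_fraction
        trial_ssd = ssd if category == "stop" else None
        responded, rt, outcome = race_trial(category, trial_ssd, params, pstop, rng)
        records.append(
            TrialRecord(
                index=k + 1,
                onset_s=k * design.inter_onset_s,
                category=str(category),
                ssd_ms=trial_ssd,
                responded=responded,
                rt_ms=rt,
                outcome=outcome,
            )
        )
        if category == "stop":
            ssd = update_ssd(ssd, outcome, design)
        if belief_state is not None:
            from .observer import update_belief

            belief_state = update_belief(belief_state, 1 if category == "stop" else 0, observer_params)
    return records


def concat_sessions(sessions: Sequence[Sequence[TrialRecord]], gap_s: float = 12.0) -> list[TrialRecord]:
    """Concatenate sessions into one record list, re-indexing trials and
    offsetting onsets so sessions do not overlap."""
    out: list[TrialRecord] = []
    t0 = 0.0
    idx = 1
    for sess in sessions:
        for rec in sess:
            out.append(replace(rec, index=idx, onset_s=rec.onset_s + t0))
            idx += 1
        if sess:
            t0 = out[-1].onset_s + gap_s
    return out
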