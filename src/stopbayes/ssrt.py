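"""Stop-signal reaction time (SSRT) estimation.

Under the race model the staircase converges on the *critical SSD* — the
delay at which the stop process wins exactly half the time — so

    SSRT = median go RT  -  critical SSD

(the "critical_ssd" method, the default here).  The "integration" method
instead reads the go-RT distribution at the observed stop-respond
percentile and subtracts the mean SSD; when the staircase has tracked
P(respond | stop) to ~0.5 the two estimators agree asymptotically.

Sessions restart the staircase at its 200 ms starting delay, so a burn-in
of stop trials is discarded *per session* before SSDs enter the average.
Input may be a single flat sequence of trials (one session) or a sequence
of sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sst import TrialRecord

__all__ = ["InsufficientDataError", "SsrtEstimate", "critical_ssd", "estimate_ssrt"]

#: Stop trials discarded at the start of each session before averaging
#: staircase SSDs, so the transient climb from the 200 ms starting delay
#: does not bias the mean.
DEFAULT_BURN_IN = 10


class InsufficientDataError(ValueError):
    """Raised when a session has too few usable trials for an estimate."""


@dataclass(frozen=True)
class SsrtEstimate:
    ssrt_ms: float
    method: str
    critical_ssd_ms: float
    median_gort_ms: float
    p_respond_stop: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ssrt_ms):
            raise ValueError("ssrt_ms must be finite")
        if not 0.0 <= self.p_respond_stop <= 1.0:
            raise ValueError("p_respond_stop must lie in [0, 1]")


def _as_sessions(trials) -> list[list[TrialRecord]]:
    trials = list(trials)
    if trials and isinstance(trials[0], TrialRecord):
        return [trials]
    return [list(s) for s in trials]


def _post_burn_in(sessions: list[list[TrialRecord]], burn_in: int):
    """Post-burn-in stop trials, pooled across sessions."""
    kept = []
    for sess in sessions:
        stops = [t for t in sess if t.category == "stop"]
        kept.extend(stops[burn_in:])
    return kept


def critical_ssd(trials, burn_in: int = DEFAULT_BURN_IN) -> float:
    """Mean staircase SSD over stop trials, discarding ``burn_in`` stop
    trials at the start of each session."""
    kept = _post_burn_in(_as_sessions(trials), burn_in)
    if len(kept) < 20:
        raise InsufficientDataError(
            f"need >= 20 stop trials after burn-in, have {len(kept)}"
        )
    return float(np.mean([t.ssd_ms for t in kept]))


def estimate_ssrt(
    trials,
    method: str = "critical_ssd",
    burn_in: int = DEFAULT_BURN_IN,
) -> SsrtEstimate:
    """Estimate SSRT from one subject's trials (one session or a list of
    sessions).

    Go RTs come from go-success (GS) trials only; omissions are excluded.
    ``critical_ssd``: median go RT minus the mean post-burn-in SSD.
    ``integration``: the go-RT quantile at the post-burn-in stop-respond
    rate minus the mean post-burn-in SSD.  The reported
    ``p_respond_stop`` is the raw behavioral rate over *all* stop trials.
    """
    sessions = _as_sessions(trials)
    flat = [t for sess in sessions for t in sess]
    go_rts = np.array([t.rt_ms for t in flat if t.outcome == "GS"], dtype=float)
    if go_rts.size == 0:
        raise InsufficientDataError("no go-success trials with a reaction time")
    all_stops = [t for t in flat if t.category == "stop"]
    if not all_stops:
        raise InsufficientDataError("no stop trials")
    p_respond_all = float(np.mean([t.responded for t in all_stops]))
    kept = _post_burn_in(sessions, burn_in)
    if len(kept) < 20:
        raise InsufficientDataError(
            f"need >= 20 stop trials after burn-in, have {len(kept)}"
        )
    crit = float(np.mean([t.ssd_ms for t in kept]))
    median_gort = float(np.median(go_rts))

    if method == "critical_ssd":
        ssrt = median_gort - crit
    elif method == "integration":
        p_respond_stationary = float(np.mean([t.responded for t in kept]))
        ssrt = float(np.quantile(go_rts, p_respond_stationary)) - crit
    else:
        raise ValueError(f"unknown SSRT method {method!r}")
    return SsrtEstimate(
        ssrt_ms=ssrt,
        method=method,
        critical_ssd_ms=crit,
        median_gort_ms=median_gort,
        p_respond_stop=p_respond_all,
    )
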