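"""Dynamic Bayesian estimate of trial-wise stop-signal probability.

The observer assumes the stop-signal rate ``r_k`` is piecewise stable: on
each trial it stays at its previous value with probability ``alpha`` and is
redrawn from a generic beta prior with probability ``1 - alpha``.  Given
the trial history the predictive density over ``r_k`` is therefore a
mixture of the previous posterior and the prior,

    predictive_k = alpha * posterior_{k-1} + (1 - alpha) * prior,

the posterior after seeing the trial category multiplies in the Bernoulli
likelihood (``r`` for a stop trial, ``1 - r`` for a go trial), and the
quantity of interest — p(Stop), the subject's prior belief that the
upcoming trial carries a stop signal — is the mean of the predictive
density.  This mixture leaves the beta family whenever ``alpha < 1``, so
the density is tracked on a fixed uniform grid over (0, 1); the ``alpha=1``
limit reduces to conjugate beta-Bernoulli updating and the ``alpha=0``
limit pins p(Stop) at the prior mean, both of which serve as closed-form
checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["ObserverParams", "BeliefState", "init_prior", "update_belief", "pstop_sequence"]


@dataclass(frozen=True)
class ObserverParams:
    """Observer parameters.

    ``alpha`` is the persistence probability of the stop-signal rate, ``pm``
    the prior mean and ``scale`` the concentration of the beta prior, giving
    shape parameters ``(pm*scale, (1-pm)*scale)`` — Beta(2.5, 7.5) at the
    defaults (pm=0.25, scale=10, alpha=0.8).  ``beta_a``/``beta_b`` override
    the mean/scale parameterization with explicit shapes when set.
    """

    alpha: float = 0.8
    pm: float = 0.25
    scale: float = 10.0
    grid_size: int = 1000
    beta_a: Optional[float] = None
    beta_b: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.pm < 1.0:
            raise ValueError("pm must lie in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.grid_size < 100:
            raise ValueError("grid_size must be at least 100")
        if (self.beta_a is None) != (self.beta_b is None):
            raise ValueError("beta_a and beta_b must be set together")
        if self.beta_a is not None and (self.beta_a <= 0 or self.beta_b <= 0):
            raise ValueError("beta shapes must be positive")

    @property
    def shapes(self) -> tuple[float, float]:
        """Beta shape parameters (a, b) of the prior."""
        if self.beta_a is not None:
            return float(self.beta_a), float(self.beta_b)
        return self.pm * self.scale, (1.0 - self.pm) * self.scale


@dataclass(frozen=True)
class BeliefState:
    """Discretized belief over the stop-signal rate.

    ``density`` is probability mass on the bin midpoints ``grid``; ``pstop``
    is the grid-weighted mean, i.e. the predictive stop probability.
    ``prior_density`` is the discretized generic prior reused by every
    update.
    """

    grid: np.ndarray
    density: np.ndarray
    pstop: float
    prior_density: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.density.sum()) - 1.0) > 1e-9:
            raise ValueError("belief density must sum to 1")
        if not 0.0 < self.pstop < 1.0:
            raise ValueError("pstop must lie strictly inside (0, 1)")


def _mean(grid: np.ndarray, density: np.ndarray) -> float:
    return float(np.dot(grid, density))


def init_prior(params: ObserverParams) -> BeliefState:
    """Discretize the beta prior on a uniform midpoint grid over (0, 1)."""
    a, b = params.shapes
    edges = np.linspace(0.0, 1.0, params.grid_size + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    # exact bin masses via the beta CDF (robust for peaked priors)
    mass = np.diff(stats.beta.cdf(edges, a, b))
    mass = mass / mass.sum()
    return BeliefState(grid=grid, density=mass, pstop=_mean(grid, mass), prior_density=mass)


def update_belief(state: BeliefState, s_k: int, params: ObserverParams) -> BeliefState:
    """Absorb one trial category and return the next predictive belief.

    ``s_k`` is 1 for a stop trial, 0 for a go trial.  The posterior
    multiplies the Bernoulli likelihood into the current predictive
    density; the next predictive mixes it with the generic prior using the
    persistence probability ``alpha``.
    """
    if s_k not in (0, 1):
        raise ValueError(f"trial category must be 0 (go) or 1 (stop), got {s_k!r}")
    lik = state.grid if s_k == 1 else 1.0 - state.grid
    post = lik * state.density
    post = post / post.sum()
    nxt = params.alpha * post + (1.0 - params.alpha) * state.prior_density
    nxt = nxt / nxt.sum()
    return BeliefState(
        grid=state.grid,
        density=nxt,
        pstop=_mean(state.grid, nxt),
        prior_density=state.prior_density,
    )


def pstop_sequence(categories: Sequence[int], params: ObserverParams) -> np.ndarray:
    """p(Stop) for every trial of a session.

    Element ``k`` is the predictive mean *before* trial ``k`` is observed —
    the prior belief of an impending stop signal — so the first element
    equals the prior mean regardless of the sequence.
    """
    cats = np.asarray(categories)
    if cats.size == 0:
        raise ValueError("category sequence must be non-empty")
    state = init_prior(params)
    out = np.empty(cats.size)
    for k, s in enumerate(cats):
        out[k] = state.pstop
        state = update_belief(state, int(s), params)
    return out
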