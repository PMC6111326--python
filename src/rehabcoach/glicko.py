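"""Glicko2 rating engine.

The recommender treats each exercise as a *player* whose strength is the
user's ability to perform it well.  A rating is a triple

* ``rating`` -- skill estimate on the familiar Glicko scale (base 1500),
* ``deviation`` -- the rating's uncertainty (RD); shrinks with informative
  matches and grows while the player is idle,
* ``volatility`` -- the expected degree of rating fluctuation (sigma);
  rises when results contradict the current rating.

The update here is the full Glicko2 step: match variance, the improvement
estimate, the iterative volatility solver, and the deviation/rating update.
All public functions are pure -- they return new :class:`RatingState`
instances and never mutate their arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Conversion factor between the public (1500-based) and internal scales.
GLICKO2_SCALE = 173.7178

#: Base rating assigned to a player that has never competed.
BASE_RATING = 1500.0

#: Default system constant (tau), bounding how fast volatility may change.
DEFAULT_TAU = 0.5

# bracket width at convergence; tight enough that the defining equation's
# residual at the returned root is well below 1e-6
_CONVERGENCE_TOL = 1e-9
_MAX_ITER = 100

WIN, TIE, LOSS = 1.0, 0.5, 0.0


@dataclass(frozen=True)
class RatingState:
    """Rating, deviation and volatility for one (user, exercise) pair."""

    rating: float
    deviation: float
    volatility: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.rating):
            raise ValueError("rating must be finite")
        if self.deviation <= 0:
            raise ValueError("deviation must be positive")
        if self.volatility < 0:
            raise ValueError("volatility must be non-negative")


@dataclass(frozen=True)
class MatchOutcome:
    """One match against ``opponent`` with ``score`` 1 (win), 0.5 (tie) or 0 (loss).

    The score is from the perspective of the player being updated.
    """

    opponent: RatingState
    score: float

    def __post_init__(self) -> None:
        if self.score not in (WIN, TIE, LOSS):
            raise ValueError("score must be one of 0, 0.5, 1")


class VolatilityConvergenceError(RuntimeError):
    """The iterative volatility solver failed to converge."""


def scale_to_internal(state: RatingState) -> tuple[float, float]:
    """Map a public-scale state to the internal (mu, phi) pair."""
    mu = (state.rating - BASE_RATING) / GLICKO2_SCALE
    phi = state.deviation / GLICKO2_SCALE
    return mu, phi


def scale_from_internal(mu: float, phi: float, volatility: float) -> RatingState:
    """Inverse of :func:`scale_to_internal`."""
    return RatingState(
        rating=mu * GLICKO2_SCALE + BASE_RATING,
        deviation=phi * GLICKO2_SCALE,
        volatility=volatility,
    )


def _g(phi: float) -> float:
    return 1.0 / math.sqrt(1.0 + 3.0 * phi * phi / (math.pi * math.pi))


def expected_score(player: tuple[float, float], opponent: tuple[float, float]) -> float:
    """Expected score of ``player`` against ``opponent``, both internal (mu, phi).

    Symmetric in the sense that equally rated players expect 0.5 regardless
    of either deviation; only the opponent's deviation discounts the result.
    """
    mu, _ = player
    mu_j, phi_j = opponent
    return 1.0 / (1.0 + math.exp(-_g(phi_j) * (mu - mu_j)))


def _solve_volatility(
    delta: float, phi: float, v: float, sigma: float, tau: float
) -> float:
    """Solve for the new volatility with the bracketing regula-falsi scheme."""
    a = math.log(sigma * sigma)
    delta2, phi2 = delta * delta, phi * phi

    def f(x: float) -> float:
        ex = math.exp(x)
        num = ex * (delta2 - phi2 - v - ex)
        den = 2.0 * (phi2 + v + ex) ** 2
        return num / den - (x - a) / (tau * tau)

    lo = a
    if delta2 > phi2 + v:
        hi = math.log(delta2 - phi2 - v)
    else:
        k = 1
        while f(a - k * tau) < 0:
            k += 1
            if k > _MAX_ITER:
                raise VolatilityConvergenceError("no sign change found")
        hi = a - k * tau
    # regula falsi with the Illinois modification
    f_lo, f_hi = f(lo), f(hi)
    for _ in range(_MAX_ITER):
        if abs(hi - lo) <= _CONVERGENCE_TOL:
            return math.exp(lo / 2.0)
        mid = lo + (lo - hi) * f_lo / (f_hi - f_lo)
        f_mid = f(mid)
        if f_mid * f_hi <= 0:
            lo, f_lo = hi, f_hi
        else:
            f_lo /= 2.0
        hi, f_hi = mid, f_mid
    raise VolatilityConvergenceError(
        f"volatility solver did not converge in {_MAX_ITER} iterations"
    )


def update_rating(
    player: RatingState,
    outcomes: Sequence[MatchOutcome] | Iterable[MatchOutcome],
    tau: float = DEFAULT_TAU,
    rating_floor: float = 0.0,
) -> RatingState:
    """One full Glicko2 update of ``player`` given its match ``outcomes``.

    With no outcomes the player is idle: only the deviation grows (see
    :func:`inactivity_step`).  The rating is floored at ``rating_floor``
    to avoid pathological negatives in long declining runs.
    """
    if tau <= 0:
        raise ValueError("system constant tau must be positive")
    outcomes = list(outcomes)
    if not outcomes:
        return inactivity_step(player)

    mu, phi = scale_to_internal(player)
    gs, es, scores = [], [], []
    for m in outcomes:
        mu_j, phi_j = scale_to_internal(m.opponent)
        g = _g(phi_j)
        e = 1.0 / (1.0 + math.exp(-g * (mu - mu_j)))
        gs.append(g)
        es.append(e)
        scores.append(m.score)

    v = 1.0 / sum(g * g * e * (1.0 - e) for g, e in zip(gs, es))
    improvement_sum = sum(g * (s - e) for g, s, e in zip(gs, scores, es))
    delta = v * improvement_sum

    sigma_new = _solve_volatility(delta, phi, v, player.volatility, tau)
    phi_star = math.sqrt(phi * phi + sigma_new * sigma_new)
    phi_new = 1.0 / math.sqrt(1.0 / (phi_star * phi_star) + 1.0 / v)
    mu_new = mu + phi_new * phi_new * improvement_sum

    updated = scale_from_internal(mu_new, phi_new, sigma_new)
    if updated.rating < rating_floor:
        updated = RatingState(rating_floor, updated.deviation, updated.volatility)
    return updated


def inactivity_step(state: RatingState) -> RatingState:
    """Age an idle player one period: deviation grows, rating is untouched.

    The growth is the Glicko2 pre-period inflation
    ``RD' = sqrt(RD^2 + (scale * sigma)^2)``; with zero volatility the state
    is a fixed point.
    """
    new_dev = math.sqrt(
        state.deviation**2 + (GLICKO2_SCALE * state.volatility) ** 2
    )
    return RatingState(state.rating, new_dev, state.volatility)
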