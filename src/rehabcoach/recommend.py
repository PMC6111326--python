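"""The adaptive exercise recommender.

Each allowed exercise carries a per-user Glicko2 rating; a suggestion is a
*match* between the performed exercise and every idle peer.  When a
completeness percentage ``p`` arrives, each idle exercise is partitioned by
its own most recent completeness value ``ref``:

* ``ref > p + 2``  -- the idle exercise *over*-performs: a loss for the
  performed one,
* ``|ref - p| <= 2`` -- *same*: a tie,
* ``ref < p - 2``  -- *under*: a win.

The performed exercise's rating is updated against the idle peers' current
states; the peers themselves only age (deviation growth).  The next
suggestion is the highest-rated exercise outside the two most recently
suggested ones (window-2 no-repeat, which forces variety), with rating
ties broken uniformly at random.

A never-performed exercise contributes a *neutral* reference completeness
of 50: an unobserved ability is presumed average, so a first strong
performance beats every fresh peer while a genuinely poor one loses to
them and drops below the 1500 baseline.

The profiler watches each exercise's completeness history and flags
*declining* series (three strictly decreasing values ending below half the
historical maximum) and *chronically low* ones (every value below 25%) for
caregiver attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .glicko import (
    LOSS,
    TIE,
    WIN,
    MatchOutcome,
    RatingState,
    inactivity_step,
    update_rating,
)

#: Completeness band (percentage points) within which two values count as "same".
SAME_BAND = 2.0

#: Reference completeness attributed to a never-performed exercise.
NEUTRAL_REFERENCE = 50.0

#: Fresh exercises start at the base rating with small uncertainty, so a
#: new entry does not leap-frog established high ratings.
INITIAL_RATING = 1500.0
INITIAL_DEVIATION = 50.0
INITIAL_VOLATILITY = 0.06

VALID_INTERVALS = (4, 8, 12, 24)


@dataclass(frozen=True)
class PerformanceRecord:
    """One performed exercise with its completeness percentage."""

    iteration: int
    exercise: str
    completeness: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError("completeness must lie in [0, 100]")


@dataclass(frozen=True)
class ProfilerReport:
    """Caregiver warning for one exercise: none, declining, or chronically_low."""

    exercise: str
    flag: str
    evidence: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.flag not in ("none", "declining", "chronically_low"):
            raise ValueError(f"unknown profiler flag {self.flag!r}")
        if self.flag != "none" and not self.evidence:
            raise ValueError("a raised flag requires evidence")


@dataclass
class UserProfile:
    """Per-user recommender state."""

    user_id: str
    allowed: set[str]
    ratings: dict[str, RatingState]
    history: list[PerformanceRecord] = field(default_factory=list)
    last_two: list[str] = field(default_factory=list)
    schedule_interval: int = 24
    registered_at: datetime = field(default_factory=datetime.now)
    last_trigger: datetime | None = None


class _Registry:
    """Process-local guard against duplicate registrations."""

    def __init__(self) -> None:
        self.ids: set[str] = set()


_registry = _Registry()


def register_user(
    user_id: str,
    allowed: Sequence[str],
    interval: int = 24,
    registered_at: datetime | None = None,
    _registry: _Registry = _registry,
) -> UserProfile:
    """Create a profile with every allowed exercise at the base rating."""
    if not allowed:
        raise ValueError("allowed exercise set must be non-empty")
    if interval not in VALID_INTERVALS:
        raise ValueError(f"interval must be one of {VALID_INTERVALS}")
    if user_id in _registry.ids:
        raise ValueError(f"user {user_id!r} is already registered")
    _registry.ids.add(user_id)
    return UserProfile(
        user_id=user_id,
        allowed=set(allowed),
        ratings={
            name: RatingState(INITIAL_RATING, INITIAL_DEVIATION, INITIAL_VOLATILITY)
            for name in allowed
        },
        schedule_interval=interval,
        registered_at=registered_at or datetime.now(),
    )


def suggest(user: UserProfile, rng: np.random.Generator) -> str:
    """Pick the highest-rated exercise outside the last two suggestions.

    Ties at the top rating break uniformly at random via ``rng``.  Updates
    the user's suggestion window (FIFO of length 2).
    """
    eligible = sorted(user.allowed.difference(user.last_two))
    if not eligible:
        raise ValueError(
            "no eligible exercise: the allowed set must exceed the 2-suggestion window"
        )
    ratings = np.array([user.ratings[name].rating for name in eligible])
    top = np.flatnonzero(ratings == ratings.max())
    choice = eligible[int(rng.choice(top))]
    user.last_two.append(choice)
    del user.last_two[:-2]
    return choice


def force_suggest(user: UserProfile, exercise: str) -> str:
    """Record ``exercise`` as the suggestion without consulting ratings.

    For replaying known suggestion traces; applies the same window update
    as :func:`suggest`.
    """
    if exercise not in user.allowed:
        raise ValueError(f"{exercise!r} is not in the user's allowed set")
    user.last_two.append(exercise)
    del user.last_two[:-2]
    return exercise


def latest_completeness(user: UserProfile, exercise: str) -> float | None:
    """Most recent completeness value for ``exercise``, or None if never performed."""
    for record in reversed(user.history):
        if record.exercise == exercise:
            return record.completeness
    return None


def report_performance(
    user: UserProfile, exercise: str, completeness: float
) -> UserProfile:
    """Rate ``exercise`` from its completeness ``p`` and age the idle peers."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError("completeness must lie in [0, 100]")
    if not user.last_two or user.last_two[-1] != exercise:
        raise ValueError(
            f"{exercise!r} was not the last suggestion ({user.last_two[-1:] or 'none'})"
        )
    opponents = sorted(user.allowed.difference({exercise}))
    outcomes = []
    for name in opponents:
        ref = latest_completeness(user, name)
        if ref is None:
            ref = NEUTRAL_REFERENCE
        if ref > completeness + SAME_BAND:
            score = LOSS  # the idle exercise over-performs the reported one
        elif abs(ref - completeness) <= SAME_BAND:
            score = TIE
        else:
            score = WIN
        outcomes.append(MatchOutcome(opponent=user.ratings[name], score=score))

    user.ratings[exercise] = update_rating(user.ratings[exercise], outcomes)
    for name in opponents:
        user.ratings[name] = inactivity_step(user.ratings[name])
    user.history.append(
        PerformanceRecord(
            iteration=len(user.history) + 1,
            exercise=exercise,
            completeness=float(completeness),
        )
    )
    return user


def profiler_check(user: UserProfile, exercise: str) -> ProfilerReport:
    """Flag worrying completeness histories for one exercise.

    *declining*: the 3 most recent values are strictly decreasing and the
    latest is below half the historical maximum.  *chronically_low*: at
    least 2 records, all below 25%.
    """
    values = [r.completeness for r in user.history if r.exercise == exercise]
    if len(values) >= 3:
        a, b, c = values[-3:]
        if a > b > c and c < 0.5 * max(values):
            return ProfilerReport(exercise, "declining", tuple(values))
    if len(values) >= 2 and all(v < 25.0 for v in values):
        return ProfilerReport(exercise, "chronically_low", tuple(values))
    return ProfilerReport(exercise, "none")


def profiler_sweep(user: UserProfile) -> list[ProfilerReport]:
    """Profiler reports for every exercise with a raised flag."""
    reports = (profiler_check(user, name) for name in sorted(user.allowed))
    return [r for r in reports if r.flag != "none"]


def next_due(user: UserProfile, now: datetime | None = None) -> datetime:
    """When the next suggestion is due: last trigger + interval, else registration."""
    if user.last_trigger is None:
        return user.registered_at
    return user.last_trigger + timedelta(hours=user.schedule_interval)


def mark_triggered(user: UserProfile, when: datetime) -> None:
    user.last_trigger = when
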