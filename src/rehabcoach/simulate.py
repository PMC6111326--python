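"""Synthetic personas and longitudinal studies of the recommendation loop.

A persona stands in for the human performer: for each exercise it holds a
mean completeness, a spread, and an optional per-iteration drift (a slow
gain or decline in ability).  A study loops suggest -> perform -> rate for
a number of iterations, which is how the recommender's long-run behaviour
(exercise diversity, concentration on well-performed exercises, profiler
warnings) is examined without users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exercises import ExerciseDefinition
from .recommend import (
    PerformanceRecord,
    UserProfile,
    _Registry,
    register_user,
    report_performance,
    suggest,
)


@dataclass(frozen=True)
class PersonaSpec:
    """Per-exercise ability distribution and trend for one simulated user."""

    name: str
    abilities: dict[str, tuple[float, float]]  # exercise -> (mean %, sd %)
    trends: dict[str, float] = field(default_factory=dict)  # % per iteration
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for exercise, (mean, sd) in self.abilities.items():
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"{exercise!r}: mean {mean} outside [0, 100]")
            if sd < 0:
                raise ValueError(f"{exercise!r}: sd must be >= 0")


@dataclass
class StudyHistory:
    """Outcome of a simulated study: one record per iteration, final ratings."""

    records: list[PerformanceRecord]
    final_ratings: dict[str, float]
    persona: str = ""
    seed: int | None = None


def sample_completeness(
    persona: PersonaSpec,
    exercise: str,
    iteration: int,
    rng: np.random.Generator,
) -> float:
    """One completeness draw: Normal(mean + trend * iteration, sd), clipped to [0, 100]."""
    if exercise in persona.excluded:
        raise ValueError(f"{exercise!r} is excluded for persona {persona.name!r}")
    if exercise not in persona.abilities:
        raise ValueError(f"persona {persona.name!r} has no ability for {exercise!r}")
    mean, sd = persona.abilities[exercise]
    drift = persona.trends.get(exercise, 0.0)
    value = rng.normal(mean + drift * iteration, sd)
    return float(np.clip(value, 0.0, 100.0))


def run_study(
    persona: PersonaSpec,
    catalogue: Sequence[ExerciseDefinition],
    n_iterations: int,
    rng: np.random.Generator,
    interval: int = 24,
) -> StudyHistory:
    """Run the full recommend -> perform -> rate loop for ``n_iterations``.

    The user's allowed set is the catalogue minus the persona's exclusions;
    all randomness (tie-breaks and performance noise) comes from ``rng``,
    so a fixed generator state reproduces the history bit-for-bit.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    allowed = [d.name for d in catalogue if d.name not in persona.excluded]
    missing = [n for n in allowed if n not in persona.abilities]
    if missing:
        raise ValueError(f"persona {persona.name!r} lacks abilities for: {missing}")
    user: UserProfile = register_user(
        persona.name, allowed, interval=interval, _registry=_Registry()
    )
    for iteration in range(1, n_iterations + 1):
        exercise = suggest(user, rng)
        pct = sample_completeness(persona, exercise, iteration, rng)
        report_performance(user, exercise, pct)
    return StudyHistory(
        records=list(user.history),
        final_ratings={name: user.ratings[name].rating for name in sorted(allowed)},
        persona=persona.name,
    )
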