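"""Exercise catalogue, pose-class alphabet and the completeness score.

An exercise is one correct repetition of an ordered *canonical* sequence of
pose classes (discrete whole-body configurations, e.g. "sit upright with
arms over head").  A recorded attempt arrives as a frame-level sequence of
pose-class labels; collapsing consecutive repeats recovers the attempted
pose order, and the *completeness* score measures how much of the canonical
sequence was performed, in order:

    completeness = 100 * |LCS(observed, canonical)| / |canonical|

where LCS is the longest common subsequence.  An attempt covering 3 of the
5 arm-raises poses in order (down, extended, down) therefore scores 60%.

Pose-class id 0 is reserved for padding and never appears in a canonical
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PAD = 0

#: The four programme groups of the senior exercise plan.
EXERCISE_GROUPS = ("sitting", "flexibility", "strength", "balance")


@dataclass(frozen=True)
class PoseClass:
    """A discrete whole-body configuration symbol."""

    id: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("pose-class id must be >= 1 (0 is padding)")


@dataclass(frozen=True)
class ExerciseDefinition:
    """Named exercise with its canonical ordered pose-class sequence."""

    name: str
    group: str
    canonical: tuple[int, ...]
    restrictions: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group not in EXERCISE_GROUPS:
            raise ValueError(f"unknown exercise group {self.group!r}")
        canonical = tuple(int(p) for p in self.canonical)
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "restrictions", tuple(self.restrictions))
        if not canonical:
            raise ValueError(f"{self.name!r}: canonical sequence is empty")
        if any(p < 1 for p in canonical):
            raise ValueError(f"{self.name!r}: canonical contains a padding/invalid id")
        if any(a == b for a, b in zip(canonical, canonical[1:])):
            raise ValueError(
                f"{self.name!r}: consecutive canonical poses must be distinct"
            )


def collapse_runs(seq: Sequence[int] | np.ndarray) -> list[int]:
    """Strip padding and collapse maximal runs of equal labels to one element.

    The inverse of the dwell-time augmentation: a frame sequence where each
    pose is held for several frames collapses back to the attempted pose
    order.  Idempotent.

    >>> collapse_runs([7, 7, 8, 8, 8, 7, 0, 0])
    [7, 8, 7]
    """
    arr = np.asarray(seq, dtype=np.int64).ravel()
    arr = arr[arr != PAD]
    if arr.size == 0:
        return []
    keep = np.empty(arr.size, dtype=bool)
    keep[0] = True
    np.not_equal(arr[1:], arr[:-1], out=keep[1:])
    return arr[keep].tolist()


def _lcs_length(a: Sequence[int], b: Sequence[int]) -> int:
    """Length of the longest common subsequence (classic O(len(a)*len(b)) DP)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, 1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[j - 1]))
        prev = curr
    return prev[-1]


def completeness(
    observed_collapsed: Sequence[int], definition: ExerciseDefinition
) -> float:
    """Percentage of the canonical pose sequence performed, in order.

    ``observed_collapsed`` must be run-collapsed and padding-free (apply
    :func:`collapse_runs` first).  Returns a value in [0, 100] rounded to
    2 decimals; 100.0 exactly when the canonical sequence is an in-order
    subsequence of the observation.
    """
    if not definition.canonical:
        raise ValueError("definition has an empty canonical sequence")
    if PAD in observed_collapsed:
        raise ValueError("observed sequence still contains padding symbols")
    lcs = _lcs_length(observed_collapsed, definition.canonical)
    return round(100.0 * lcs / len(definition.canonical), 2)


def oracle_identify(
    observed_collapsed: Sequence[int],
    catalogue: Sequence[ExerciseDefinition],
) -> tuple[str, float]:
    """Deterministic reference classifier: the completeness-maximising exercise.

    Scores every catalogue entry and returns ``(name, completeness)`` of the
    best one; ties break towards the earliest catalogue entry.  Serves as
    the independent oracle the learned sequence classifier is checked
    against.
    """
    if not catalogue:
        raise ValueError("catalogue is empty")
    best_name, best_score = catalogue[0].name, -1.0
    for definition in catalogue:
        score = completeness(observed_collapsed, definition)
        if score > best_score:
            best_name, best_score = definition.name, score
    return best_name, best_score


def pose_alphabet_size(catalogue: Iterable[ExerciseDefinition]) -> int:
    """Highest pose-class id used by ``catalogue`` (vocabulary bound)."""
    return max(max(d.canonical) for d in catalogue)


# ---------------------------------------------------------------------------
# Default catalogue (shipped as package data)


def default_pose_alphabet() -> list[PoseClass]:
    """The shipped pose-class alphabet."""
    from . import io

    return io.load_pose_alphabet(io.packaged_data_path("poses.yaml"))


def default_catalogue() -> list[ExerciseDefinition]:
    """The full shipped catalogue: the senior exercise programme (all groups)."""
    from . import io

    return io.load_catalogue(io.packaged_data_path("catalogue.yaml"))


#: Names of the 15 exercises the sequence recognizer is trained on, in the
#: order their confusion-matrix rows are conventionally reported.
RECOGNIZER_EXERCISES: tuple[str, ...] = (
    "upper body twist left",
    "upper body twist right",
    "hip marching left",
    "hip marching right",
    "arm raises",
    "neck stretch left",
    "neck stretch right",
    "sit to stand",
    "mini squats",
    "sideways leg lift",
    "leg extension",
    "bicep curls",
    "sideways bend",
    "simple grapevine",
    "heel to toe walk",
)

#: Left/right sibling pairs that share their endpoint (neutral) poses; the
#: recognizer's residual confusions are expected to concentrate here.
LEFT_RIGHT_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"upper body twist left", "upper body twist right"}),
    frozenset({"hip marching left", "hip marching right"}),
    frozenset({"neck stretch left", "neck stretch right"}),
)


def recognizer_catalogue(
    catalogue: Sequence[ExerciseDefinition] | None = None,
) -> list[ExerciseDefinition]:
    """The 15-exercise subset used to train and evaluate the recognizer."""
    if catalogue is None:
        catalogue = default_catalogue()
    by_name = {d.name: d for d in catalogue}
    missing = [n for n in RECOGNIZER_EXERCISES if n not in by_name]
    if missing:
        raise ValueError(f"catalogue lacks recognizer exercises: {missing}")
    return [by_name[n] for n in RECOGNIZER_EXERCISES]
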