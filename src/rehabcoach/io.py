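"""Readers and writers: catalogue, pose alphabet, personas, histories, profiles.

All on-disk formats are plain text: YAML for catalogue/pose/persona files,
CSV (dot-decimal, UTF-8, header row) for performance histories, JSON for
user profiles.  Validation failures raise :class:`ValidationError` with a
message naming the offending entry or line.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .exercises import ExerciseDefinition, PoseClass

HISTORY_HEADER = ["iteration", "exercise", "pct_completed"]


class ValidationError(ValueError):
    """An input file violated its schema or an invariant."""


def packaged_data_path(name: str):
    """Path to a data file shipped inside the package."""
    return resources.files("rehabcoach").joinpath("data", name)


# -- pose alphabet ----------------------------------------------------------


def load_pose_alphabet(path) -> list[PoseClass]:
    raw = yaml.safe_load(_read_text(path))
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: pose alphabet must be a non-empty list")
    poses = []
    seen: set[int] = set()
    for entry in raw:
        if not isinstance(entry, dict) or "id" not in entry:
            raise ValidationError(f"{path}: each pose needs an 'id' field")
        pid = int(entry["id"])
        if pid in seen:
            raise ValidationError(f"{path}: duplicate pose id {pid}")
        seen.add(pid)
        poses.append(PoseClass(id=pid, description=str(entry.get("description", ""))))
    return poses


# -- catalogue --------------------------------------------------------------


def load_catalogue(path, pose_alphabet: Sequence[PoseClass] | None = None) -> list[ExerciseDefinition]:
    """Load and validate an exercise catalogue.

    Rejects, with distinct messages: schema violations, duplicate exercise
    names, canonical pose ids absent from the pose alphabet, and invalid
    canonical sequences (empty or with consecutive repeats).
    """
    raw = yaml.safe_load(_read_text(path))
    if not isinstance(raw, list) or not raw:
        raise ValidationError(f"{path}: schema error - expected a non-empty list of exercises")
    if pose_alphabet is None:
        pose_alphabet = load_pose_alphabet(packaged_data_path("poses.yaml"))
    known_ids = {p.id for p in pose_alphabet}

    catalogue: list[ExerciseDefinition] = []
    seen: set[str] = set()
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or not {"name", "group", "canonical"} <= set(entry):
            raise ValidationError(
                f"{path}: schema error in entry {i}: need name, group, canonical"
            )
        name = str(entry["name"])
        if name in seen:
            raise ValidationError(f"{path}: duplicate exercise name {name!r}")
        seen.add(name)
        canonical = entry["canonical"]
        if not isinstance(canonical, list):
            raise ValidationError(f"{path}: {name!r}: canonical must be a list of pose ids")
        unknown = [p for p in canonical if p not in known_ids]
        if unknown:
            raise ValidationError(f"{path}: {name!r}: unknown pose id(s) {unknown}")
        try:
            definition = ExerciseDefinition(
                name=name,
                group=str(entry["group"]),
                canonical=tuple(canonical),
                restrictions=tuple(entry.get("restrictions", ()) or ()),
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: validation error: {exc}") from exc
        catalogue.append(definition)
    return catalogue


# -- history CSV ------------------------------------------------------------


def write_history(path, records) -> None:
    """Write performance records as CSV with a ``iteration,exercise,pct_completed`` header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(HISTORY_HEADER)
        for rec in records:
            writer.writerow([rec.iteration, rec.exercise, f"{rec.completeness:.2f}"])


def read_history(path):
    """Read a history CSV back into a list of performance records.

    Malformed rows are reported with their 1-based line number; completeness
    values outside [0, 100] are range errors.
    """
    from .recommend import PerformanceRecord

    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != HISTORY_HEADER:
            raise ValidationError(f"{path}: line 1: expected header {','.join(HISTORY_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            try:
                iteration = int(row[0])
                pct = float(row[2])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: malformed row: {exc}") from exc
            if not 0.0 <= pct <= 100.0:
                raise ValidationError(
                    f"{path}: line {lineno}: completeness {pct} outside [0, 100]"
                )
            records.append(
                PerformanceRecord(iteration=iteration, exercise=row[1], completeness=pct)
            )
    return records


# -- user profile JSON ------------------------------------------------------


def save_profile(path, user) -> None:
    from .glicko import RatingState  # noqa: F401  (documents the serialised triple)

    payload = {
        "user_id": user.user_id,
        "interval_h": user.schedule_interval,
        "registered_at": user.registered_at.isoformat(),
        "last_trigger": user.last_trigger.isoformat() if user.last_trigger else None,
        "last_two": list(user.last_two),
        "ratings": {
            name: [round(s.rating, 6), round(s.deviation, 6), round(s.volatility, 6)]
            for name, s in user.ratings.items()
        },
        "history": [
            [r.iteration, r.exercise, round(r.completeness, 2)] for r in user.history
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_profile(path):
    from .glicko import RatingState
    from .recommend import PerformanceRecord, UserProfile

    data = json.loads(_read_text(path))
    try:
        return UserProfile(
            user_id=data["user_id"],
            allowed=set(data["ratings"]),
            ratings={
                name: RatingState(*vals) for name, vals in data["ratings"].items()
            },
            history=[
                PerformanceRecord(iteration=i, exercise=e, completeness=p)
                for i, e, p in data["history"]
            ],
            last_two=list(data["last_two"]),
            schedule_interval=int(data["interval_h"]),
            registered_at=datetime.fromisoformat(data["registered_at"]),
            last_trigger=(
                datetime.fromisoformat(data["last_trigger"])
                if data.get("last_trigger")
                else None
            ),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed user profile: {exc}") from exc


# -- persona YAML -----------------------------------------------------------


def load_persona(path):
    from .simulate import PersonaSpec

    data = yaml.safe_load(_read_text(path))
    if not isinstance(data, dict) or "abilities" not in data:
        raise ValidationError(f"{path}: persona file needs an 'abilities' mapping")
    abilities = {}
    for name, pair in data["abilities"].items():
        try:
            mean, sd = float(pair[0]), float(pair[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValidationError(
                f"{path}: ability for {name!r} must be [mean, sd]: {exc}"
            ) from exc
        abilities[str(name)] = (mean, sd)
    return PersonaSpec(
        name=str(data.get("name", "persona")),
        abilities=abilities,
        trends={str(k): float(v) for k, v in (data.get("trends") or {}).items()},
        excluded=frozenset(data.get("excluded") or ()),
    )


def default_persona():
    """The shipped default persona (leg-limited, declining step-up)."""
    return load_persona(packaged_data_path("john.yaml"))


def _read_text(path) -> str:
    if hasattr(path, "read_text"):
        return path.read_text(encoding="utf-8")
    return Path(path).read_text(encoding="utf-8")
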