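"""Users: preference scoring, step-count storage, performance strata, goals.

Each user answers a 10-item baseline survey rating the preference-tailored
BCTs on a 3-point scale (-1 = negative, 0 = neutral, +1 = positive). The
ratings are converted once into sampling weights (1 / 5 / 10) and stored on
the profile. Step counts arrive as cumulative daily records (one per sync,
nominally hourly); the day's latest count places the user into one of three
performance strata (<=2000, 2001-6000, >=6001 steps) that gate which
step-feedback messages are eligible. The daily goal defaults to the
guideline minimum of 7000 steps.
"""

from __future__ import annotations

import csv
import datetime as dt
from enum import Enum
from typing import Iterable, Mapping

from pydantic import BaseModel, Field, field_validator, model_validator

from .bct import PREFERENCE_BCTS, PREFERENCE_COLUMNS

#: Survey response -> sampling weight.
SCORE_MAP: dict[int, int] = {-1: 1, 0: 5, 1: 10}

#: Inclusive upper bounds of the LOW and MID step strata.
STRATUM_LOW_MAX = 2000
STRATUM_MID_MAX = 6000

DEFAULT_STEP_GOAL_MIN = 7000
DEFAULT_STEP_GOAL_MAX = 8000


class PreferenceError(ValueError):
    """A survey response is malformed (wrong tags or out-of-range value)."""


class MonotonicityError(ValueError):
    """A step record would decrease the cumulative count within one day."""


class UnknownUserError(KeyError):
    """Lookup for a user never registered in the step store."""


class Stratum(str, Enum):
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"


class Sensor(str, Enum):
    PEDOMETER = "pedometer"
    ACCELEROMETER = "accelerometer"


def score_preferences(
    responses: Mapping[str, int], score_map: Mapping[int, int] | None = None
) -> dict[str, int]:
    """Map a 10-item survey response vector to sampling weights.

    ``responses`` must contain exactly the 10 preference BCT tags, each with
    a value in {-1, 0, +1}; -1 maps to 1, 0 to 5, +1 to 10.
    """
    smap = dict(SCORE_MAP if score_map is None else score_map)
    missing = set(PREFERENCE_BCTS) - set(responses)
    extra = set(responses) - set(PREFERENCE_BCTS)
    if missing:
        raise PreferenceError(f"missing BCT responses: {sorted(missing)}")
    if extra:
        raise PreferenceError(f"unknown BCT tags: {sorted(extra)}")
    scores: dict[str, int] = {}
    for tag in PREFERENCE_BCTS:
        value = responses[tag]
        if value not in smap:
            raise PreferenceError(
                f"response for BCT {tag!r} must be one of {sorted(smap)}, got {value!r}"
            )
        scores[tag] = smap[value]
    return scores


class UserProfile(BaseModel):
    """One enrolled user: identity, BCT weights, and daily step goal."""

    user_id: str = Field(min_length=1)
    first_name: str = Field(min_length=1)
    scores: dict[str, int]
    step_goal_min: int = DEFAULT_STEP_GOAL_MIN
    step_goal_max: int = DEFAULT_STEP_GOAL_MAX

    @field_validator("scores")
    @classmethod
    def _check_scores(cls, v: dict[str, int]) -> dict[str, int]:
        if set(v) != set(PREFERENCE_BCTS):
            raise ValueError(
                f"scores must cover exactly the {len(PREFERENCE_BCTS)} preference BCTs"
            )
        valid = set(SCORE_MAP.values())
        for tag, s in v.items():
            if s not in valid:
                raise ValueError(f"score for {tag!r} must be in {sorted(valid)}, got {s}")
        return v

    @model_validator(mode="after")
    def _check_goal(self) -> "UserProfile":
        if self.step_goal_min > self.step_goal_max:
            raise ValueError("step_goal_min must not exceed step_goal_max")
        return self


class StepRecord(BaseModel):
    """One cumulative step-count sync: date, time of update, count, sensor."""

    model_config = {"frozen": True}

    date: dt.date
    update_time: dt.time
    steps: int = Field(ge=0)
    sensor: Sensor = Sensor.PEDOMETER


def classify_step_stratum(
    steps: int, low_max: int = STRATUM_LOW_MAX, mid_max: int = STRATUM_MID_MAX
) -> Stratum:
    """Place a daily step count into the LOW / MID / HIGH feedback stratum."""
    if steps < 0:
        raise ValueError(f"step count must be nonnegative, got {steps}")
    if steps <= low_max:
        return Stratum.LOW
    if steps <= mid_max:
        return Stratum.MID
    return Stratum.HIGH


def goal_met(steps: int, profile: UserProfile) -> bool:
    """True iff the day's count reaches the profile's minimum goal.

    Only the lower bound of the goal range has behavioral meaning; the upper
    bound is descriptive metadata.
    """
    if steps < 0:
        raise ValueError(f"step count must be nonnegative, got {steps}")
    return steps >= profile.step_goal_min


class StepStore:
    """Per-user, per-day cumulative step series with monotonicity enforcement.

    Within one (user, date) the cumulative count must be nondecreasing and
    update times strictly increasing; a new date starts a fresh series.
    Re-ingesting a record identical to one already stored is a no-op, so
    replaying a valid feed is idempotent.
    """

    def __init__(self) -> None:
        self._records: dict[str, dict[dt.date, list[StepRecord]]] = {}

    def register(self, user_id: str) -> None:
        self._records.setdefault(user_id, {})

    def known_users(self) -> list[str]:
        return sorted(self._records)

    def record(self, user_id: str, rec: StepRecord) -> None:
        """Append one record, enforcing per-day cumulative monotonicity."""
        days = self._records.setdefault(user_id, {})
        series = days.setdefault(rec.date, [])
        if rec in series:  # idempotent replay
            return
        if series:
            last = series[-1]
            if rec.update_time <= last.update_time or rec.steps < last.steps:
                raise MonotonicityError(
                    f"record at {rec.date} {rec.update_time} with {rec.steps} steps "
                    f"conflicts with stored ({last.update_time}, {last.steps})"
                )
        series.append(rec)

    def steps_for_day(
        self, user_id: str, date: dt.date, now: dt.time | None = None
    ) -> tuple[int, bool]:
        """Latest count for (user, date) up to ``now``; (0, stale=True) if none.

        The stale flag makes a missing feed observable instead of silently
        skipping a scheduled contact: the caller sends LOW-stratum feedback
        and marks the delivery.
        """
        if user_id not in self._records:
            raise UnknownUserError(user_id)
        series = self._records[user_id].get(date, [])
        if now is not None:
            series = [r for r in series if r.update_time <= now]
        if not series:
            return 0, True
        return series[-1].steps, False

    def records_for_day(self, user_id: str, date: dt.date) -> list[StepRecord]:
        if user_id not in self._records:
            raise UnknownUserError(user_id)
        return list(self._records[user_id].get(date, []))


# Module-level aliases matching the operation-style API.
def record_step_update(store: StepStore, user_id: str, rec: StepRecord) -> StepStore:
    store.record(user_id, rec)
    return store


def steps_for_day(
    store: StepStore, user_id: str, date: dt.date, now: dt.time | None = None
) -> tuple[int, bool]:
    return store.steps_for_day(user_id, date, now)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_PREF_HEADER = ("user_id", "first_name") + PREFERENCE_COLUMNS


def load_preference_responses(path) -> list[dict]:
    """Read raw survey responses (values in {-1, 0, 1}) from preferences.csv.

    Returns one dict per row: ``{"user_id", "first_name", "responses"}``.
    """
    rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _PREF_HEADER if c not in fields]
        if missing:
            raise PreferenceError(f"preferences file missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                responses = {
                    tag: int(row[f"bct_{tag}"]) for tag in PREFERENCE_BCTS
                }
            except (TypeError, ValueError) as exc:
                raise PreferenceError(f"row {i}: non-integer response ({exc})") from exc
            for tag, v in responses.items():
                if v not in (-1, 0, 1):
                    raise PreferenceError(
                        f"row {i}: response for {tag!r} must be -1, 0, or 1, got {v}"
                    )
            rows.append(
                {
                    "user_id": row["user_id"],
                    "first_name": row["first_name"],
                    "responses": responses,
                }
            )
    return rows


def write_preference_responses(rows: Iterable[dict], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PREF_HEADER)
        for row in rows:
            writer.writerow(
                [row["user_id"], row["first_name"]]
                + [row["responses"][t] for t in PREFERENCE_BCTS]
            )


def roster_from_responses(rows: Iterable[dict], **profile_kwargs) -> list[UserProfile]:
    """Score raw survey rows and build validated profiles."""
    return [
        UserProfile(
            user_id=row["user_id"],
            first_name=row["first_name"],
            scores=score_preferences(row["responses"]),
            **profile_kwargs,
        )
        for row in rows
    ]


def load_roster(path, **profile_kwargs) -> list[UserProfile]:
    """Load preferences.csv and return scored profiles."""
    return roster_from_responses(load_preference_responses(path), **profile_kwargs)


def write_preference_scores(profiles: Iterable[UserProfile], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PREF_HEADER)
        for p in profiles:
            writer.writerow(
                [p.user_id, p.first_name] + [p.scores[t] for t in PREFERENCE_BCTS]
            )


_STEPS_HEADER = ("user_id", "date", "time", "steps", "sensor")


def write_step_records(rows: Iterable[tuple[str, StepRecord]], path) -> None:
    """Write (user_id, record) pairs to steps.csv."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STEPS_HEADER)
        for user_id, rec in rows:
            writer.writerow(
                [
                    user_id,
                    rec.date.isoformat(),
                    rec.update_time.strftime("%H:%M"),
                    rec.steps,
                    rec.sensor.value,
                ]
            )


def load_step_records(path) -> list[tuple[str, StepRecord]]:
    out: list[tuple[str, StepRecord]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _STEPS_HEADER if c not in fields]
        if missing:
            raise ValueError(f"steps file missing columns: {missing}")
        for row in reader:
            out.append(
                (
                    row["user_id"],
                    StepRecord(
                        date=dt.date.fromisoformat(row["date"]),
                        update_time=dt.time.fromisoformat(row["time"]),
                        steps=int(row["steps"]),
                        sensor=Sensor(row["sensor"]),
                    ),
                )
            )
    return out
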