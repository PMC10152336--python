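"""Engine configuration: every numeric rule of the coaching protocol.

Defaults encode the published protocol: a 300-m geofence polled every 2
minutes, hourly step sync, at most 3 geolocation prompts per day and never
less than 4 hours apart within 08:00-20:00, scheduled contacts drawn
uniformly inside the morning (08:00-09:00), midday (11:30-12:30), and
evening (16:00-18:00) windows, a preference-weighted subset of 4 on the
BCT channel, performance strata split at 2000/6000 steps, survey scores
mapped -1/0/+1 -> 1/5/10, and a 7000-8000 step daily goal.

All times are minutes since local midnight; windows are half-open
``[start, end)`` at 1-minute resolution.
"""

from __future__ import annotations

from typing import Annotated, Tuple

import yaml
from pydantic import BaseModel, BeforeValidator, Field, model_validator


def _parse_minute(v) -> int:
    """Accept minutes-as-int or an 'HH:MM' string."""
    if isinstance(v, str):
        h, m = v.split(":")
        return int(h) * 60 + int(m)
    return int(v)


def _parse_window(v) -> tuple[int, int]:
    if isinstance(v, (list, tuple)) and len(v) == 2:
        return (_parse_minute(v[0]), _parse_minute(v[1]))
    raise ValueError(f"window must be a [start, end] pair, got {v!r}")


Window = Annotated[Tuple[int, int], BeforeValidator(_parse_window)]


def minute_str(minute: int) -> str:
    return f"{minute // 60:02d}:{minute % 60:02d}"


class EngineConfig(BaseModel):
    radius_m: float = Field(default=300.0, gt=0)
    geo_poll_interval_min: int = Field(default=2, ge=1)
    step_sync_interval_min: int = Field(default=60, ge=1)
    geo_window: Window = (8 * 60, 20 * 60)
    geo_daily_cap: int = Field(default=3, ge=1)
    geo_min_gap_min: int = Field(default=240, gt=0)
    morning_window: Window = (8 * 60, 9 * 60)
    midday_window: Window = (11 * 60 + 30, 12 * 60 + 30)
    evening_window: Window = (16 * 60, 18 * 60)
    bct_subset_k: int = Field(default=4, ge=1)
    stratum_low_max: int = Field(default=2000, ge=0)
    stratum_mid_max: int = Field(default=6000, ge=0)
    score_map: dict[int, int] = Field(default_factory=lambda: {-1: 1, 0: 5, 1: 10})
    step_goal_min: int = Field(default=7000, ge=0)
    step_goal_max: int = Field(default=8000, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "EngineConfig":
        for name in ("geo_window", "morning_window", "midday_window", "evening_window"):
            start, end = getattr(self, name)
            if not (0 <= start < end <= 1440):
                raise ValueError(f"{name} must satisfy 0 <= start < end <= 1440")
        if self.stratum_low_max >= self.stratum_mid_max:
            raise ValueError("stratum_low_max must be below stratum_mid_max")
        if self.step_goal_min > self.step_goal_max:
            raise ValueError("step_goal_min must not exceed step_goal_max")
        return self

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.model_dump()
        for name in ("geo_window", "morning_window", "midday_window", "evening_window"):
            start, end = data[name]
            data[name] = [minute_str(start), minute_str(end)]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
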