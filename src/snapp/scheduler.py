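"""Simulated-clock event loop: planning, gating, and the delivery log.

One minute is the clock tick. Each simulated user-day draws three scheduled
send times (morning/midday/evening, uniform over whole minutes in their
windows), syncs the step store on the hourly cadence, and polls the
geofence every 2 minutes against the user's GPS track. Geolocation prompts
pass through a gate enforcing the delivery window, the daily cap, and the
minimum gap (measured delivery-to-delivery; the cap counter resets at local
midnight). Every delivery *and* every skipped attempt (empty pool, gate
denial, rejected step record) is logged, so the engine's whole behavior is
observable from the log alone. When a scheduled tick and a geofence tick
share a minute, the scheduled message is processed first.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import EngineConfig
from .geofence import GeoObservation, GreenSpaceDB, Position, check_proximity
from .library import WEEKDAYS, MessageLibrary, Slot
from .tailoring import (
    SelectionOutcome,
    select_bct_message,
    select_geo_message,
    select_step_message,
)
from .users import MonotonicityError, StepRecord, StepStore, UserProfile

__all__ = [
    "EngineConfig",
    "SchedulePlan",
    "GeoGateState",
    "GateDecision",
    "DeliveryEvent",
    "UserScenario",
    "SimulationResult",
    "plan_day",
    "geo_gate",
    "run_simulation",
]

ALLOW = "ALLOW"
DENY_WINDOW = "WINDOW"
DENY_MAX_DAILY = "MAX_DAILY"
DENY_MIN_GAP = "MIN_GAP"


@dataclass(frozen=True)
class SchedulePlan:
    """The day's three scheduled send minutes (since local midnight)."""

    date: dt.date
    morning_time: int
    midday_time: int
    evening_time: int


def plan_day(date: dt.date, config: EngineConfig, rng: np.random.Generator) -> SchedulePlan:
    """Draw the three send times uniformly over whole minutes in-window.

    Draw order is fixed (morning, midday, evening) so a given RNG state
    always yields the same plan.
    """
    times = []
    for start, end in (config.morning_window, config.midday_window, config.evening_window):
        times.append(int(rng.integers(start, end)))
    return SchedulePlan(date, *times)


@dataclass
class GeoGateState:
    """Per-user rate-limit state for the geolocation channel."""

    geo_sent_today: int = 0
    last_geo_time: Optional[dt.datetime] = None

    def reset_day(self) -> None:
        self.geo_sent_today = 0


@dataclass(frozen=True)
class GateDecision:
    allowed: bool
    reason: Optional[str] = None  # WINDOW | MAX_DAILY | MIN_GAP when denied


def geo_gate(state: GeoGateState, now: dt.datetime, config: EngineConfig) -> GateDecision:
    """Decide whether a geolocation prompt may be sent at ``now``.

    Checks, in order: inside the delivery window, below the daily cap, at
    least the minimum gap since the previous geolocation delivery. The
    caller updates ``state`` after an actual delivery.
    """
    minute = now.hour * 60 + now.minute
    start, end = config.geo_window
    if not (start <= minute < end):
        return GateDecision(False, DENY_WINDOW)
    if state.geo_sent_today >= config.geo_daily_cap:
        return GateDecision(False, DENY_MAX_DAILY)
    if state.last_geo_time is not None:
        gap_min = (now - state.last_geo_time).total_seconds() / 60.0
        if gap_min < config.geo_min_gap_min:
            return GateDecision(False, DENY_MIN_GAP)
    return GateDecision(True)


@dataclass(frozen=True)
class DeliveryEvent:
    """One logged event: a delivery or an observable skip."""

    ts: str
    user_id: str
    kind: str  # DELIVERY | SKIP
    channel: str  # STEP | GEO | BCT-morning | BCT-evening | SYNC
    message_id: Optional[str]
    text: Optional[str]
    reason: str
    context: dict

    def as_dict(self) -> dict:
        return {
            "ts": self.ts,
            "user_id": self.user_id,
            "kind": self.kind,
            "channel": self.channel,
            "message_id": self.message_id,
            "text": self.text,
            "reason": self.reason,
            "context": self.context,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, ensure_ascii=False)


@dataclass
class UserScenario:
    """Synthetic inputs for one user: GPS tracks and the step-record feed.

    ``tracks`` maps each simulated date to a (1440, 2) array of minute
    positions (lat, lon); ``step_feed`` maps each simulated date to the
    records that *arrive* that day, in update-time order (a record's own
    ``date`` field may differ, e.g. under the stale-date fault).
    """

    user_id: str
    tracks: dict[dt.date, np.ndarray] = field(default_factory=dict)
    step_feed: dict[dt.date, list[StepRecord]] = field(default_factory=dict)


@dataclass
class SimulationResult:
    """Delivery log plus instrumentation from one simulation run."""

    events: list[DeliveryEvent]
    geo_eval_minutes: list[tuple[str, str, int]]  # (user_id, date iso, minute)
    seed: int
    config: EngineConfig

    def deliveries(self) -> list[DeliveryEvent]:
        return [e for e in self.events if e.kind == "DELIVERY"]

    def summary(self) -> pd.DataFrame:
        """Per-user-day delivery counts by channel (plus skips)."""
        rows: dict[tuple[str, str], dict] = {}
        for e in self.events:
            day = e.ts[:10]
            key = (e.user_id, day)
            row = rows.setdefault(
                key,
                {"user_id": e.user_id, "date": day, "STEP": 0, "GEO": 0,
                 "BCT": 0, "SKIP": 0},
            )
            if e.kind == "DELIVERY":
                channel = "BCT" if e.channel.startswith("BCT") else e.channel
                row[channel] += 1
            else:
                row["SKIP"] += 1
        df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["user_id"], r["date"])))
        if not df.empty:
            df["total"] = df["STEP"] + df["GEO"] + df["BCT"]
        return df

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(e.to_json() + "\n")

    def jsonl(self) -> str:
        return "".join(e.to_json() + "\n" for e in self.events)


def _ts(date: dt.date, minute: int) -> str:
    return f"{date.isoformat()}T{minute // 60:02d}:{minute % 60:02d}"


def run_simulation(
    roster: list[UserProfile],
    library: MessageLibrary,
    green_space_db: GreenSpaceDB,
    scenarios: Mapping[str, UserScenario],
    config: EngineConfig | None = None,
    seed: int = 0,
    sink: Optional[Callable[[DeliveryEvent], None]] = None,
    keep_events: bool = True,
    record_geo_evals: bool = True,
) -> SimulationResult:
    """Run the minute-resolution event loop over every scenario day.

    One shared RNG (seeded with ``seed``) governs all randomness, and users
    are processed in sorted id order within each day, so identical inputs
    replay to a byte-identical delivery log. ``sink`` receives every event
    as it is emitted; set ``keep_events=False`` to stream to the sink only
    (useful for long runs).
    """
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    store = StepStore()
    for p in roster:
        store.register(p.user_id)
    profiles = {p.user_id: p for p in roster}
    gate_states = {p.user_id: GeoGateState() for p in roster}

    events: list[DeliveryEvent] = []
    geo_evals: list[tuple[str, str, int]] = []

    def emit(event: DeliveryEvent) -> None:
        if keep_events:
            events.append(event)
        if sink is not None:
            sink(event)

    def emit_outcome(
        date: dt.date, minute: int, user_id: str, channel: str, outcome: SelectionOutcome
    ) -> None:
        kind = "DELIVERY" if outcome.selected else "SKIP"
        emit(
            DeliveryEvent(
                ts=_ts(date, minute),
                user_id=user_id,
                kind=kind,
                channel=channel,
                message_id=outcome.message_id,
                text=outcome.rendered_text,
                reason=outcome.reason.value,
                context=outcome.trace,
            )
        )

    all_dates = sorted({d for sc in scenarios.values() for d in sc.tracks})
    user_ids = sorted(uid for uid in scenarios if uid in profiles)
    unknown = sorted(set(scenarios) - set(profiles))
    if unknown:
        raise KeyError(f"scenarios reference users not in the roster: {unknown}")

    for date in all_dates:
        weekday = WEEKDAYS[date.weekday()]
        for user_id in user_ids:
            scenario = scenarios[user_id]
            if date not in scenario.tracks:
                continue
            profile = profiles[user_id]
            track = np.asarray(scenario.tracks[date], dtype=float)
            if track.shape != (1440, 2):
                raise ValueError(
                    f"track for {user_id} on {date} must have shape (1440, 2), "
                    f"got {track.shape}"
                )
            feed = list(scenario.step_feed.get(date, []))
            feed_pos = 0
            plan = plan_day(date, config, rng)
            gate = gate_states[user_id]
            gate.reset_day()

            for minute in range(1440):
                # --- hourly step sync -------------------------------------
                if minute % config.step_sync_interval_min == 0:
                    while feed_pos < len(feed):
                        rec = feed[feed_pos]
                        rec_minute = rec.update_time.hour * 60 + rec.update_time.minute
                        if rec_minute > minute:
                            break
                        feed_pos += 1
                        try:
                            store.record(user_id, rec)
                        except MonotonicityError as exc:
                            emit(
                                DeliveryEvent(
                                    ts=_ts(date, minute),
                                    user_id=user_id,
                                    kind="SKIP",
                                    channel="SYNC",
                                    message_id=None,
                                    text=None,
                                    reason="MONOTONICITY",
                                    context={"detail": str(exc)},
                                )
                            )

                # --- scheduled contacts (before geo on shared minutes) ----
                if minute == plan.morning_time or minute == plan.evening_time:
                    slot = Slot.MORNING if minute == plan.morning_time else Slot.EVENING
                    outcome = select_bct_message(
                        library, profile, slot, weekday, rng, k=config.bct_subset_k
                    )
                    emit_outcome(date, minute, user_id, f"BCT-{slot.value}", outcome)
                if minute == plan.midday_time:
                    now_t = dt.time(minute // 60, minute % 60)
                    steps, stale = store.steps_for_day(user_id, date, now=now_t)
                    outcome = select_step_message(
                        library,
                        profile,
                        steps,
                        stale,
                        rng,
                        low_max=config.stratum_low_max,
                        mid_max=config.stratum_mid_max,
                    )
                    emit_outcome(date, minute, user_id, "STEP", outcome)

                # --- geofence poll ----------------------------------------
                if minute % config.geo_poll_interval_min == 0:
                    if record_geo_evals:
                        geo_evals.append((user_id, date.isoformat(), minute))
                    pos = Position(track[minute, 0], track[minute, 1])
                    hit = check_proximity(pos, green_space_db, config.radius_m)
                    if hit is not None:
                        now = dt.datetime.combine(date, dt.time(minute // 60, minute % 60))
                        decision = geo_gate(gate, now, config)
                        if decision.allowed:
                            obs = GeoObservation(
                                timestamp=now,
                                green_space_type=hit.space.type,
                                space_id=hit.space.space_id,
                            )
                            outcome = select_geo_message(
                                library, profile, obs.green_space_type, rng
                            )
                            if outcome.selected:
                                gate.geo_sent_today += 1
                                gate.last_geo_time = now
                            trace = dict(outcome.trace)
                            trace["space_id"] = obs.space_id
                            outcome = SelectionOutcome(
                                outcome.message_id, outcome.rendered_text,
                                outcome.reason, trace,
                            )
                            emit_outcome(date, minute, user_id, "GEO", outcome)
                        else:
                            emit(
                                DeliveryEvent(
                                    ts=_ts(date, minute),
                                    user_id=user_id,
                                    kind="SKIP",
                                    channel="GEO",
                                    message_id=None,
                                    text=None,
                                    reason=f"DENY_{decision.reason}",
                                    context={
                                        "space_id": hit.space.space_id,
                                        "green_space_type": hit.space.type.value,
                                    },
                                )
                            )

    return SimulationResult(
        events=events, geo_eval_minutes=geo_evals, seed=seed, config=config
    )
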