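"""Synthetic-data generators: users, step trajectories, GPS tracks, fixtures.

These generators stand in for the mobile apps and real participants so the
whole engine is exercisable at desk scale. Daily step accrual is modeled as
a compound process — a Poisson number of walking bouts at uniform times,
lognormal bout sizes, plus a constant background drift — which produces
realistically skewed daily totals with analytic moments (mean total =
bouts_per_day_mean * exp(mu + sigma^2/2) + 24 * background). GPS tracks are
piecewise-linear walks between random waypoints around a home location, at
the engine's 1-minute clock resolution; a track can be made to dwell near a
green space to exercise the geofence. Neither model attempts realistic
human mobility — they exist to drive every engine rule, not to emulate a
population.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .bct import GEO_PROMPT_BCT, PREFERENCE_BCTS, STEP_FEEDBACK_BCT
from .geofence import (
    GreenSpace,
    GreenSpaceDB,
    GreenSpaceType,
    Position,
    destination_point,
)
from .library import Category, MessageLibrary, MessageTemplate
from .scheduler import UserScenario
from .users import Sensor, StepRecord, Stratum, UserProfile, roster_from_responses

_FIRST_NAMES = (
    "Anna", "Bram", "Carla", "Daan", "Els", "Femke", "Gijs", "Hannah",
    "Iris", "Jan", "Kim", "Lars", "Mara", "Nico", "Olaf", "Petra",
    "Quinn", "Rosa", "Sem", "Tess",
)


class ScenarioParams(BaseModel):
    """Knobs of the synthetic study population and its day structure."""

    n_users: int = Field(default=1, ge=1)
    #: Mean number of walking bouts per day (Poisson).
    bouts_per_day_mean: float = Field(default=6.0, ge=0)
    #: Lognormal bout size, log-space parameters.
    bout_mu: float = 6.4
    bout_sigma: float = Field(default=0.5, ge=0)
    #: Constant incidental drift (shuffling around the house).
    background_steps_per_hour: float = Field(default=100.0, ge=0)
    home: tuple[float, float] = (52.36, 4.90)
    waypoint_count: int = Field(default=8, ge=1)
    #: Std of waypoint scatter around home, meters.
    waypoint_spread_m: float = Field(default=800.0, ge=0)
    #: Probability that one waypoint dwells within 100 m of a green space.
    dwell_near_green: float = Field(default=0.3, ge=0, le=1)
    #: Reproduce the pilot clock fault: records keep the previous date.
    stale_fault: bool = False


def gen_preference_responses(
    n_users: int,
    seed: int,
    probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> list[dict]:
    """Random survey roster: 10 i.i.d. responses per user over {-1, 0, +1}.

    Returns rows in the shape consumed by
    :func:`snapp.users.roster_from_responses`.
    """
    if n_users < 1:
        raise ValueError("n_users must be >= 1")
    p = np.asarray(probs, dtype=float)
    if p.size != 3 or np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, rel_tol=1e-9):
        raise ValueError("probs must be 3 nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_users):
        draws = rng.choice([-1, 0, 1], size=len(PREFERENCE_BCTS), p=p)
        rows.append(
            {
                "user_id": f"u{i + 1:03d}",
                "first_name": _FIRST_NAMES[i % len(_FIRST_NAMES)],
                "responses": {tag: int(v) for tag, v in zip(PREFERENCE_BCTS, draws)},
            }
        )
    return rows


def gen_roster(n_users: int, seed: int, **kwargs) -> list[UserProfile]:
    return roster_from_responses(gen_preference_responses(n_users, seed, **kwargs))


def gen_step_trajectory(
    params: ScenarioParams,
    date: dt.date,
    seed: int,
    sensor: Sensor = Sensor.PEDOMETER,
) -> list[StepRecord]:
    """Hourly cumulative step records for one day.

    Records are stamped at minute :59 of each hour (24 per day), each
    carrying the steps accrued since midnight; the final record holds the
    day total. Under ``stale_fault`` the records carry the *previous* date,
    reproducing the pilot fault where the app stopped rolling its clock
    forward.
    """
    rng = np.random.default_rng(seed)
    n_bouts = int(rng.poisson(params.bouts_per_day_mean))
    bout_times_h = np.sort(rng.uniform(0.0, 24.0, size=n_bouts))
    bout_sizes = rng.lognormal(params.bout_mu, params.bout_sigma, size=n_bouts)
    record_date = date - dt.timedelta(days=1) if params.stale_fault else date
    records = []
    for h in range(24):
        t_end = h + 1.0
        walked = float(bout_sizes[bout_times_h < t_end].sum())
        total = int(round(params.background_steps_per_hour * t_end + walked))
        records.append(
            StepRecord(
                date=record_date,
                update_time=dt.time(h, 59),
                steps=total,
                sensor=sensor,
            )
        )
    return records


def gen_gps_track(
    params: ScenarioParams,
    date: dt.date,
    green_space_db: GreenSpaceDB,
    seed: int,
) -> np.ndarray:
    """Minute-resolution positions for one day, shape (1440, 2).

    A piecewise-linear walk between ``waypoint_count`` waypoints scattered
    around home (Gaussian, ``waypoint_spread_m``), starting and ending at
    home. With probability ``dwell_near_green`` one waypoint is placed
    within 100 m of a random green space.
    """
    rng = np.random.default_rng(seed)
    home_lat, home_lon = params.home
    m_per_deg_lat = 111_194.93  # pi/180 * mean Earth radius
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(home_lat))

    n_wp = params.waypoint_count
    dx = rng.normal(0.0, params.waypoint_spread_m, size=n_wp)
    dy = rng.normal(0.0, params.waypoint_spread_m, size=n_wp)
    lats = home_lat + dy / m_per_deg_lat
    lons = home_lon + dx / m_per_deg_lon

    if len(green_space_db) > 0 and rng.random() < params.dwell_near_green:
        idx = int(rng.integers(n_wp))
        space = green_space_db.spaces[int(rng.integers(len(green_space_db)))]
        bearing = float(rng.uniform(0.0, 360.0))
        dist = float(rng.uniform(0.0, 100.0))
        near = destination_point(space.lat, space.lon, bearing, dist)
        lats[idx], lons[idx] = near.lat, near.lon

    anchor_lats = np.concatenate([[home_lat], lats, [home_lat]])
    anchor_lons = np.concatenate([[home_lon], lons, [home_lon]])
    anchor_minutes = np.linspace(0, 1439, num=n_wp + 2)
    minutes = np.arange(1440)
    track = np.column_stack(
        [
            np.interp(minutes, anchor_minutes, anchor_lats),
            np.interp(minutes, anchor_minutes, anchor_lons),
        ]
    )
    return track


def constant_track(pos: Position | tuple[float, float]) -> np.ndarray:
    """A track that sits on one position all day (geofence dwell scenarios)."""
    return np.tile(np.asarray(pos, dtype=float), (1440, 1))


def gen_green_spaces(
    n: int, bbox: tuple[float, float, float, float], seed: int
) -> GreenSpaceDB:
    """``n`` green spaces uniform in ``bbox`` = (lat_min, lon_min, lat_max,
    lon_max), types cycling through park / forest / walking trail."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lat_min, lon_min, lat_max, lon_max = bbox
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError(f"invalid bounding box {bbox!r}")
    rng = np.random.default_rng(seed)
    types = list(GreenSpaceType)
    spaces = []
    for i in range(n):
        spaces.append(
            GreenSpace(
                space_id=f"g{i + 1:03d}",
                name=f"Green space {i + 1}",
                type=types[i % len(types)],
                lat=float(rng.uniform(lat_min, lat_max)),
                lon=float(rng.uniform(lon_min, lon_max)),
            )
        )
    return GreenSpaceDB(spaces)


def build_scenario(
    profile: UserProfile,
    params: ScenarioParams,
    dates: Sequence[dt.date],
    green_space_db: GreenSpaceDB,
    seed: "int | np.random.SeedSequence",
) -> UserScenario:
    """Bundle per-day step feeds and GPS tracks for one user."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(dates) + 1)
    sensor_rng = np.random.default_rng(children[-1])
    sensor = Sensor.PEDOMETER if int(sensor_rng.integers(2)) == 0 else Sensor.ACCELEROMETER
    scenario = UserScenario(user_id=profile.user_id)
    for i, date in enumerate(dates):
        step_seed = children[2 * i]
        track_seed = children[2 * i + 1]
        scenario.step_feed[date] = gen_step_trajectory(
            params, date, step_seed, sensor=sensor
        )
        scenario.tracks[date] = gen_gps_track(params, date, green_space_db, track_seed)
    return scenario


def build_scenarios(
    roster: Sequence[UserProfile],
    params: ScenarioParams,
    dates: Sequence[dt.date],
    green_space_db: GreenSpaceDB,
    seed: int,
) -> dict[str, UserScenario]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(roster))
    return {
        p.user_id: build_scenario(p, params, dates, green_space_db, child)
        for p, child in zip(roster, children)
    }


# ---------------------------------------------------------------------------
# Message-library fixture generator
# ---------------------------------------------------------------------------

# Published example messages, one per BCT, used as the seed rows of every
# generated library.
_STEP_TEXTS = {
    Stratum.LOW: (
        "So far you have taken <number> steps today, <name>. A short stroll "
        "around the block right now would be a great way to get going again."
    ),
    Stratum.MID: (
        "So far you have taken <number> steps today, <name>. Well done! "
        "You can be proud of yourself."
    ),
    Stratum.HIGH: (
        "Wow <name>, you have already taken <number> steps today! Fantastic "
        "work, keep that energy going for the rest of the day."
    ),
}

_GEO_TEXT = (
    "Do you want to get some extra steps in today? You are close to a "
    "<green_space_type> where you can enjoy a nice walk."
)

_BCT_TEXTS = {
    "action_planning": (
        "Good preparation is half the battle won! Plan and write down when "
        "and where you will go for a walk in the coming days."
    ),
    "reward": (
        "Hey <name>, keep up the good work! Try to keep walking every day. "
        "You can do it."
    ),
    "social_comparison": (
        "Hi <name>, here's a little fact: last week, 73% of SNapp users "
        "took enough steps every day!"
    ),
    "consequences": (
        "Did you know that walking can help relieve stress? Walking makes "
        "your brain release chemicals that stimulate relaxation and improve "
        "your mood."
    ),
    "barrier_identification": (
        "No time to go for a walk? Get your steps in throughout the day by "
        "taking the stairs, getting off the bus a stop earlier, or parking "
        "further away."
    ),
    "social_support": (
        "Hey <name>, have you told your friends or family about your "
        "walking goals? That way, they can support or join you for a walk!"
    ),
    "social_approval": (
        "Good morning <name>. If you manage to keep walking regularly, your "
        "friends and family will surely be proud of you."
    ),
    "goal_setting": (
        "What's your new goal, <name>? Set yourself an achievable walking "
        "goal for this week."
    ),
    "self_monitoring": (
        "Curious to know how many steps you've already taken today? Try to "
        "keep track by checking the step counter every day."
    ),
    "review_goals": (
        "Did you achieve this week's walking goal, <name>? If so, good job! "
        "If not, try to think of a new goal for next week."
    ),
}

_VARIANT_FILLERS = (
    "Every single step you take today counts toward a healthier you.",
    "Remember, small daily walks add up to a big difference over time.",
    "A little fresh air and movement can really brighten up your whole day.",
    "Keep your shoes by the door so heading out stays quick and easy.",
)


def gen_message_library(per_pool: int = 1, seed: int = 0) -> MessageLibrary:
    """A complete fixture library: ``per_pool`` templates for each STEP
    stratum, each green-space type, and each of the 10 preference BCTs
    (3 + 3 + 10 pools). The published example texts seed the first variant
    of every pool, so ``per_pool=1`` yields 16 templates."""
    if per_pool < 1:
        raise ValueError("per_pool must be >= 1")
    rng = np.random.default_rng(seed)
    templates: list[MessageTemplate] = []

    def variants(base: str, k: int) -> list[str]:
        out = [base]
        fillers = list(_VARIANT_FILLERS)
        for j in range(1, k):
            filler = fillers[int(rng.integers(len(fillers)))]
            out.append(f"{base} {filler}")
        return out

    for stratum in Stratum:
        for j, text in enumerate(variants(_STEP_TEXTS[stratum], per_pool), start=1):
            templates.append(
                MessageTemplate(
                    message_id=f"step_{stratum.value.lower()}_{j:03d}",
                    category=Category.STEP,
                    bct_tag=STEP_FEEDBACK_BCT,
                    stratum=stratum,
                    text=text,
                )
            )
    for gst in GreenSpaceType:
        for j, text in enumerate(variants(_GEO_TEXT, per_pool), start=1):
            templates.append(
                MessageTemplate(
                    message_id=f"geo_{gst.value}_{j:03d}",
                    category=Category.GEO,
                    bct_tag=GEO_PROMPT_BCT,
                    green_space_type=gst,
                    text=text,
                )
            )
    for tag in PREFERENCE_BCTS:
        for j, text in enumerate(variants(_BCT_TEXTS[tag], per_pool), start=1):
            templates.append(
                MessageTemplate(
                    message_id=f"bct_{tag}_{j:03d}",
                    category=Category.BCT,
                    bct_tag=tag,
                    text=text,
                )
            )
    return MessageLibrary(templates)
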