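"""The three message-selection algorithms.

Selection is elimination-based: the library is filtered down by channel and
context until a small eligible pool remains, then a random choice is made.

* STEP channel: filter to step-feedback messages, keep those matching the
  user's current performance stratum (or ANY), choose uniformly.
* GEO channel: filter to green-space prompts, keep those matching the
  encountered space type (or ANY), choose uniformly.
* BCT channel: filter to preference-tailored messages legal for the current
  weekday and slot, draw a subset of k=4 without replacement with
  probability proportional to the user's preference score for each
  message's BCT, then choose uniformly among the subset. A message whose
  BCT scores 10 is thus ~10x more likely to be sent than one scoring 1.

Empty pools are a logged non-event (``NO_ELIGIBLE_MESSAGE``), never an
exception: a coaching engine must not crash on a sparse library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .geofence import GreenSpaceType
from .library import (
    Category,
    MessageLibrary,
    MessageTemplate,
    RenderContext,
    Slot,
    render_message,
)
from .users import (
    STRATUM_LOW_MAX,
    STRATUM_MID_MAX,
    Stratum,
    UserProfile,
    classify_step_stratum,
)


class SelectionReason(str, Enum):
    SELECTED = "SELECTED"
    NO_ELIGIBLE_MESSAGE = "NO_ELIGIBLE_MESSAGE"


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of one selection attempt, with an auditable trace."""

    message_id: Optional[str]
    rendered_text: Optional[str]
    reason: SelectionReason
    trace: dict = field(default_factory=dict)

    @property
    def selected(self) -> bool:
        return self.reason is SelectionReason.SELECTED


def weighted_subset(
    item_ids: Sequence[str],
    weights: Sequence[float],
    k: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw ``min(k, n)`` items without replacement, proportional to weight.

    Equivalent to successive draws where each draw is proportional to the
    remaining weights (implemented as an exponential race: item i gets key
    Exp(1)/w_i and the k smallest keys win, in key order). Selection order
    is preserved in the returned list.
    """
    ids = list(item_ids)
    w = np.asarray(weights, dtype=float)
    if len(ids) != w.size:
        raise ValueError("item_ids and weights must have equal length")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if w.size and (not np.all(np.isfinite(w)) or np.any(w <= 0)):
        raise ValueError("all weights must be positive and finite")
    if len(ids) <= k:
        return ids
    keys = rng.exponential(size=w.size) / w
    order = np.argsort(keys, kind="stable")[:k]
    return [ids[i] for i in order]


def _uniform_choice(pool: Sequence[MessageTemplate], rng: np.random.Generator):
    return pool[int(rng.integers(len(pool)))]


def select_step_message(
    lib: MessageLibrary,
    profile: UserProfile,
    steps: int,
    stale: bool,
    rng: np.random.Generator,
    low_max: int = STRATUM_LOW_MAX,
    mid_max: int = STRATUM_MID_MAX,
) -> SelectionOutcome:
    """Midday step-feedback selection.

    When the step feed is stale the LOW stratum is used with a count of 0 so
    the scheduled contact still happens; the trace flags the condition.
    """
    if stale:
        steps = 0
    stratum = classify_step_stratum(steps, low_max=low_max, mid_max=mid_max)
    pool = [
        t
        for t in lib.by_category(Category.STEP)
        if t.stratum in (None, stratum)
    ]
    trace = {
        "channel": "STEP",
        "pool_size": len(pool),
        "stratum": stratum.value,
        "steps": steps,
        "stale_steps": stale,
    }
    if not pool:
        return SelectionOutcome(None, None, SelectionReason.NO_ELIGIBLE_MESSAGE, trace)
    chosen = _uniform_choice(pool, rng)
    text = render_message(
        chosen, RenderContext(first_name=profile.first_name, number=steps)
    )
    return SelectionOutcome(chosen.message_id, text, SelectionReason.SELECTED, trace)


def select_geo_message(
    lib: MessageLibrary,
    profile: UserProfile,
    green_space_type: GreenSpaceType,
    rng: np.random.Generator,
) -> SelectionOutcome:
    """Contextual prompt for the type of green space the user is near."""
    green_space_type = GreenSpaceType(green_space_type)
    pool = [
        t
        for t in lib.by_category(Category.GEO)
        if t.green_space_type in (None, green_space_type)
    ]
    trace = {
        "channel": "GEO",
        "pool_size": len(pool),
        "green_space_type": green_space_type.value,
    }
    if not pool:
        return SelectionOutcome(None, None, SelectionReason.NO_ELIGIBLE_MESSAGE, trace)
    chosen = _uniform_choice(pool, rng)
    text = render_message(
        chosen,
        RenderContext(
            first_name=profile.first_name,
            green_space_type=green_space_type.display,
        ),
    )
    return SelectionOutcome(chosen.message_id, text, SelectionReason.SELECTED, trace)


def select_bct_message(
    lib: MessageLibrary,
    profile: UserProfile,
    slot: Slot,
    weekday: str,
    rng: np.random.Generator,
    k: int = 4,
) -> SelectionOutcome:
    """Preference-weighted morning/evening coaching selection."""
    slot = Slot(slot)
    pool = [
        t
        for t in lib.by_category(Category.BCT)
        if slot in t.allowed_slots and weekday in t.allowed_weekdays
    ]
    trace = {
        "channel": "BCT",
        "pool_size": len(pool),
        "slot": slot.value,
        "weekday": weekday,
    }
    if not pool:
        return SelectionOutcome(None, None, SelectionReason.NO_ELIGIBLE_MESSAGE, trace)
    ids = [t.message_id for t in pool]
    weights = [profile.scores[t.bct_tag] for t in pool]
    subset_ids = weighted_subset(ids, weights, k, rng)
    trace["subset_ids"] = list(subset_ids)
    chosen_id = subset_ids[int(rng.integers(len(subset_ids)))]
    chosen = lib.get(chosen_id)
    trace["bct_tag"] = chosen.bct_tag
    text = render_message(chosen, RenderContext(first_name=profile.first_name))
    return SelectionOutcome(chosen.message_id, text, SelectionReason.SELECTED, trace)
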