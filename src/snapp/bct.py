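"""Behavior change technique (BCT) vocabulary used to tag coaching messages.

Twelve techniques are in play. Ten of them are *preference-tailored*: each
user rates them in a baseline survey and the ratings weight message
selection on the morning/evening coaching channel. The remaining two are
bound to fixed channels: feedback on performance carries the midday
step-count message, and provide-instruction carries the geofenced
green-space prompt.
"""

PREFERENCE_BCTS: tuple[str, ...] = (
    "action_planning",
    "reward",
    "social_comparison",
    "consequences",
    "barrier_identification",
    "social_support",
    "social_approval",
    "goal_setting",
    "self_monitoring",
    "review_goals",
)

#: BCT carried by the midday step-feedback channel.
STEP_FEEDBACK_BCT = "feedback_on_performance"

#: BCT carried by the geofenced green-space prompt channel.
GEO_PROMPT_BCT = "provide_instruction"

ALL_BCTS: tuple[str, ...] = PREFERENCE_BCTS + (STEP_FEEDBACK_BCT, GEO_PROMPT_BCT)

#: CSV column names of the preference survey, in canonical order.
PREFERENCE_COLUMNS: tuple[str, ...] = tuple(f"bct_{t}" for t in PREFERENCE_BCTS)
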