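"""The tailored message library: loading, validation, and rendering.

Messages live in three pools. STEP messages give feedback on the day's step
count and are stratified by performance level; GEO messages prompt a walk
when the user is near a green space of a given type; BCT messages carry one
of the ten preference-tailored behavior change techniques and may be
restricted to particular weekdays or delivery slots (morning/evening).
Personalization happens at render time through literal angle-bracket
placeholders: ``<name>``, ``<number>``, and ``<green_space_type>``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, Field, model_validator

from .bct import GEO_PROMPT_BCT, PREFERENCE_BCTS, STEP_FEEDBACK_BCT
from .geofence import GreenSpaceType
from .users import Stratum

WEEKDAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class Slot(str, Enum):
    MORNING = "morning"
    EVENING = "evening"


class Category(str, Enum):
    STEP = "STEP"
    GEO = "GEO"
    BCT = "BCT"


class LibraryError(ValueError):
    """Malformed message file or template definition."""


class RenderError(KeyError):
    """A template placeholder has no value in the render context."""


#: Placeholder tokens recognized in message text.
KNOWN_PLACEHOLDERS = frozenset({"name", "number", "green_space_type"})
_PLACEHOLDER_RE = re.compile(r"<([^<>]*)>")

# Word-count lint bounds: messages should read like a short mobile text.
WORD_COUNT_RANGE = (20, 30)


def placeholders_in(text: str) -> set[str]:
    return set(_PLACEHOLDER_RE.findall(text))


class MessageTemplate(BaseModel):
    """One selectable coaching message with its relevance constraints.

    ``stratum`` (STEP only) and ``green_space_type`` (GEO only) of ``None``
    mean ANY. ``allowed_weekdays`` / ``allowed_slots`` default to
    unrestricted; slots are meaningful only on the BCT channel.
    """

    model_config = {"frozen": True}

    message_id: str = Field(min_length=1)
    category: Category
    bct_tag: str
    text: str = Field(min_length=1)
    stratum: Optional[Stratum] = None
    green_space_type: Optional[GreenSpaceType] = None
    allowed_weekdays: frozenset[str] = frozenset(WEEKDAYS)
    allowed_slots: frozenset[Slot] = frozenset(Slot)

    @model_validator(mode="after")
    def _check(self) -> "MessageTemplate":
        tokens = placeholders_in(self.text)
        unknown = tokens - KNOWN_PLACEHOLDERS
        if unknown:
            raise ValueError(f"unknown placeholder(s) {sorted(unknown)} in text")
        bad_days = self.allowed_weekdays - set(WEEKDAYS)
        if bad_days:
            raise ValueError(f"unknown weekday(s) {sorted(bad_days)}")
        if not self.allowed_weekdays:
            raise ValueError("allowed_weekdays must not be empty")
        if not self.allowed_slots:
            raise ValueError("allowed_slots must not be empty")
        if self.category is Category.STEP:
            if self.bct_tag != STEP_FEEDBACK_BCT:
                raise ValueError(f"STEP templates carry bct_tag {STEP_FEEDBACK_BCT!r}")
            if self.green_space_type is not None:
                raise ValueError("green_space_type applies to GEO templates only")
            if "green_space_type" in tokens:
                raise ValueError("only GEO templates may use <green_space_type>")
        elif self.category is Category.GEO:
            if self.bct_tag != GEO_PROMPT_BCT:
                raise ValueError(f"GEO templates carry bct_tag {GEO_PROMPT_BCT!r}")
            if self.stratum is not None:
                raise ValueError("stratum applies to STEP templates only")
            if "number" in tokens:
                raise ValueError("only STEP templates may use <number>")
        else:  # BCT
            if self.bct_tag not in PREFERENCE_BCTS:
                raise ValueError(
                    f"BCT templates must carry one of the preference BCTs, got {self.bct_tag!r}"
                )
            if self.stratum is not None or self.green_space_type is not None:
                raise ValueError("stratum/green_space_type apply to STEP/GEO templates only")
            if tokens - {"name"}:
                raise ValueError("BCT templates may use only <name>")
        if self.category is not Category.BCT and self.allowed_slots != frozenset(Slot):
            raise ValueError("allowed_slots restrictions apply to BCT templates only")
        return self

    def word_count(self) -> int:
        return len(self.text.split())


class MessageLibrary:
    """Ordered, id-unique collection of templates (row order preserved)."""

    def __init__(self, templates: Iterable[MessageTemplate]) -> None:
        self.templates: list[MessageTemplate] = list(templates)
        seen: set[str] = set()
        for t in self.templates:
            if t.message_id in seen:
                raise LibraryError(f"duplicate message_id {t.message_id!r}")
            seen.add(t.message_id)
        self._by_id = {t.message_id: t for t in self.templates}

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self) -> Iterator[MessageTemplate]:
        return iter(self.templates)

    def __eq__(self, other) -> bool:
        return isinstance(other, MessageLibrary) and self.templates == other.templates

    def get(self, message_id: str) -> MessageTemplate:
        return self._by_id[message_id]

    def by_category(self, category: Category) -> list[MessageTemplate]:
        return [t for t in self.templates if t.category is category]


class RenderContext(BaseModel):
    """Values available for placeholder substitution."""

    first_name: str = Field(min_length=1)
    number: Optional[int] = Field(default=None, ge=0)
    green_space_type: Optional[str] = None


def render_message(template: MessageTemplate, ctx: RenderContext) -> str:
    """Substitute every placeholder; integers render without separators."""
    values = {"name": ctx.first_name}
    if ctx.number is not None:
        values["number"] = str(int(ctx.number))
    if ctx.green_space_type is not None:
        values["green_space_type"] = ctx.green_space_type

    def _sub(match: re.Match) -> str:
        token = match.group(1)
        if token not in values:
            raise RenderError(f"no value for placeholder <{token}>")
        return values[token]

    return _PLACEHOLDER_RE.sub(_sub, template.text)


@dataclass
class LibraryReport:
    """Validation findings: coverage errors are fatal, word counts lint-only."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    word_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_library(lib: MessageLibrary) -> LibraryReport:
    """Check pool coverage and lint message length.

    Every selectable pool must be nonempty: each STEP stratum, each
    green-space type, each of the ten preference BCTs (ANY templates count
    toward every stratum/type). Word counts outside the house style of
    roughly 20-30 words raise warnings only.
    """
    report = LibraryReport()
    lo, hi = WORD_COUNT_RANGE
    for t in lib:
        n = t.word_count()
        report.word_counts[t.message_id] = n
        if not lo <= n <= hi:
            report.warnings.append(
                f"{t.message_id}: {n} words (house style is {lo}-{hi})"
            )
    steps = lib.by_category(Category.STEP)
    for stratum in Stratum:
        if not any(t.stratum in (None, stratum) for t in steps):
            report.errors.append(f"no STEP template for stratum {stratum.value}")
    geos = lib.by_category(Category.GEO)
    for gst in GreenSpaceType:
        if not any(t.green_space_type in (None, gst) for t in geos):
            report.errors.append(f"no GEO template for green-space type {gst.value}")
    bcts = lib.by_category(Category.BCT)
    for tag in PREFERENCE_BCTS:
        if not any(t.bct_tag == tag for t in bcts):
            report.errors.append(f"no BCT template for tag {tag}")
    return report


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_CSV_HEADER = (
    "message_id",
    "category",
    "bct_tag",
    "stratum",
    "green_space_type",
    "allowed_weekdays",
    "allowed_slots",
    "text",
)


def load_library(path) -> MessageLibrary:
    """Load messages.csv; empty cells mean ANY / unrestricted."""
    templates: list[MessageTemplate] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _CSV_HEADER if c not in fields]
        if missing:
            raise LibraryError(f"message file missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            mid = (row["message_id"] or "").strip()
            if mid in seen:
                raise LibraryError(f"row {i}: duplicate message_id {mid!r}")
            seen.add(mid)
            try:
                templates.append(_template_from_row(row))
            except (ValueError, KeyError) as exc:
                raise LibraryError(f"row {i} ({mid!r}): {exc}") from exc
    return MessageLibrary(templates)


def _template_from_row(row: dict) -> MessageTemplate:
    def cell(name: str) -> str:
        return (row[name] or "").strip()

    kwargs: dict = {
        "message_id": cell("message_id"),
        "category": Category(cell("category")),
        "bct_tag": cell("bct_tag"),
        "text": row["text"],
    }
    if cell("stratum"):
        kwargs["stratum"] = Stratum(cell("stratum"))
    if cell("green_space_type"):
        kwargs["green_space_type"] = GreenSpaceType(cell("green_space_type"))
    if cell("allowed_weekdays"):
        kwargs["allowed_weekdays"] = frozenset(cell("allowed_weekdays").split("|"))
    if cell("allowed_slots"):
        kwargs["allowed_slots"] = frozenset(
            Slot(s) for s in cell("allowed_slots").split("|")
        )
    return MessageTemplate(**kwargs)


def write_library(lib: MessageLibrary, path) -> None:
    """Write messages.csv in the schema read by :func:`load_library`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for t in lib:
            weekdays = (
                ""
                if t.allowed_weekdays == frozenset(WEEKDAYS)
                else "|".join(d for d in WEEKDAYS if d in t.allowed_weekdays)
            )
            slots = (
                ""
                if t.allowed_slots == frozenset(Slot)
                else "|".join(s.value for s in Slot if s in t.allowed_slots)
            )
            writer.writerow(
                [
                    t.message_id,
                    t.category.value,
                    t.bct_tag,
                    t.stratum.value if t.stratum else "",
                    t.green_space_type.value if t.green_space_type else "",
                    weekdays,
                    slots,
                    t.text,
                ]
            )
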