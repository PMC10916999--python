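"""Key-press event-log and participant-table formats, validation, and protocol segmentation.

No standard interchange format exists for keystroke-dynamics event logs, so this
module defines one: a long-form UTF-8 CSV with one key event per row
(``participant_id, test_type, hand, block_index, key_label, down_ms, up_ms``),
and a participant CSV mirroring the scalar fields of :class:`ParticipantRecord`
with booleans written ``yes``/``no``.  Timestamps are integer milliseconds
relative to the start of the tapping block; absolute wall-clock time is outside
the data model.

The tapping protocol has two tests:

* **single-key** — tap the spacebar with the dominant hand as fast as possible
  for 10 s, repeated for four blocks;
* **alternate-key** — tap the "s" and ";" keys alternately with one hand for
  30 s, once per hand.

A key-down with a missing key-up (a key still held when the block ended) is
truncated to the block end and flagged, never dropped: this preserves press
counts (hence frequency) while keeping dwell time defined.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "TestType",
    "Hand",
    "KeyEvent",
    "TappingBlock",
    "ParticipantRecord",
    "Cohort",
    "ProtocolReport",
    "SchemaError",
    "EventValidationError",
    "KEY_ALIASES",
    "EDUCATION_LEVELS",
    "read_events",
    "write_events",
    "read_participants",
    "write_participants",
    "segment_protocol",
    "block_duration_s",
]


class TestType(str, enum.Enum):
    SINGLE_KEY = "single_key"
    ALTERNATE_KEY = "alternate_key"


TestType.__test__ = False  # not a pytest collection target


class Hand(str, enum.Enum):
    DOMINANT = "dominant"
    NON_DOMINANT = "non_dominant"


#: Protocol block durations in seconds.
PROTOCOL_DURATION_S = {TestType.SINGLE_KEY: 10.0, TestType.ALTERNATE_KEY: 30.0}

#: Number of blocks each test contributes to a complete protocol.
PROTOCOL_BLOCKS = {
    TestType.SINGLE_KEY: [(Hand.DOMINANT, i) for i in (1, 2, 3, 4)],
    TestType.ALTERNATE_KEY: [(Hand.DOMINANT, 1), (Hand.NON_DOMINANT, 1)],
}

#: Alias map from raw captured labels/keycodes to normalized lowercase names.
KEY_ALIASES = {
    " ": "space",
    "spacebar": "space",
    ";": "semicolon",
    ":": "semicolon",
    "'": "apostrophe",
    ",": "comma",
    ".": "period",
    "/": "slash",
    "[": "bracketleft",
}

#: The six education attainment levels, lowest first (reference level in models).
EDUCATION_LEVELS = (
    "left_school_before_16",
    "left_school_at_16",
    "left_school_17_or_18",
    "undergraduate",
    "masters",
    "phd",
)

_EVENT_COLUMNS = [
    "participant_id",
    "test_type",
    "hand",
    "block_index",
    "key_label",
    "down_ms",
    "up_ms",
]

_BOOL_FIELDS = (
    "memory_change",
    "dementia_dx",
    "memory_impairment_dx",
    "pd_dx",
    "ms_dx",
)

_COUNT_FIELDS = ("paltea6", "swmbe6", "swms")


class SchemaError(ValueError):
    """A required column is missing or a file does not match the documented schema."""


class EventValidationError(ValueError):
    """One or more rows violate event invariants; ``rows`` holds 1-based line numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


def block_duration_s(test_type: TestType) -> float:
    """Protocol duration of one block of the given test, in seconds."""
    return PROTOCOL_DURATION_S[TestType(test_type)]


def normalize_key(label: str, aliases: dict[str, str] | None = None) -> str:
    """Normalize a raw key label to its lowercase canonical name."""
    amap = KEY_ALIASES if aliases is None else aliases
    lowered = str(label).lower()
    if lowered in amap:  # check before stripping: " " is the spacebar
        return amap[lowered]
    stripped = lowered.strip()
    return amap.get(stripped, stripped)


@dataclass(slots=True, eq=True)
class KeyEvent:
    """One key press: label plus key-down / key-up times in ms from block start.

    ``truncated`` marks presses whose key-up was missing in the raw log and was
    imputed as the block end.
    """

    key_label: str
    down_ms: int
    up_ms: int
    truncated: bool = False

    def __post_init__(self):
        if self.down_ms < 0:
            raise ValueError(f"down_ms must be non-negative, got {self.down_ms}")
        if self.up_ms <= self.down_ms:
            raise ValueError(
                f"up_ms must exceed down_ms, got down={self.down_ms} up={self.up_ms}"
            )

    @property
    def dwell_ms(self) -> int:
        return self.up_ms - self.down_ms


@dataclass(slots=True)
class TappingBlock:
    """An ordered stream of key events from one protocol block."""

    test_type: TestType
    hand: Hand
    block_index: int
    duration_s: float
    events: list[KeyEvent] = field(default_factory=list)

    def __post_init__(self):
        self.test_type = TestType(self.test_type)
        self.hand = Hand(self.hand)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.test_type is TestType.SINGLE_KEY and self.hand is not Hand.DOMINANT:
            raise ValueError("single-key blocks are performed with the dominant hand")
        self.events = sorted(self.events, key=lambda e: (e.down_ms, e.up_ms))
        limit = round(self.duration_s * 1000)
        bad = [e for e in self.events if e.down_ms >= limit or e.up_ms > limit]
        if bad:
            raise ValueError(
                f"{len(bad)} event(s) extend beyond the {self.duration_s} s block"
            )

    @property
    def n_presses(self) -> int:
        return len(self.events)

    def key(self) -> tuple[TestType, Hand, int]:
        return (self.test_type, self.hand, self.block_index)


@dataclass(slots=True)
class ParticipantRecord:
    """Demographics, mood, self-report screening answers, cognitive counts, and tapping blocks.

    The three screening booleans correspond to the self-report questions on
    noticed memory change, a dementia diagnosis, and a diagnosed memory
    impairment; any "yes" marks the participant cognitively symptomatic.
    """

    participant_id: str
    age_years: float
    sex: str  # "female" | "male"
    education_level: str
    hads_anxiety: int
    hads_depression: int
    memory_change: bool | None = None
    dementia_dx: bool | None = None
    memory_impairment_dx: bool | None = None
    pd_dx: bool | None = None
    ms_dx: bool | None = None
    paltea6: int | None = None
    swmbe6: int | None = None
    swms: int | None = None
    blocks: list[TappingBlock] = field(default_factory=list)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.education_level not in EDUCATION_LEVELS:
            raise ValueError(
                f"education_level {self.education_level!r} not one of {EDUCATION_LEVELS}"
            )
        for name in ("hads_anxiety", "hads_depression"):
            v = getattr(self, name)
            if not (0 <= v <= 21):
                raise ValueError(f"{name} must be in [0, 21], got {v}")
        for name in _COUNT_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be a non-negative count, got {v}")


@dataclass(slots=True)
class Cohort:
    """A list of participants plus free-text provenance metadata."""

    participants: list[ParticipantRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.participants)

    def by_id(self) -> dict[str, ParticipantRecord]:
        return {p.participant_id: p for p in self.participants}


@dataclass(slots=True)
class ProtocolReport:
    """Completeness report for one participant's tapping protocol."""

    participant_id: str
    complete: bool
    missing: list[str]
    duplicates: list[str]


# ---------------------------------------------------------------------------
# event log I/O
# ---------------------------------------------------------------------------


def _block_label(test_type: TestType, hand: Hand, block_index: int) -> str:
    if test_type is TestType.SINGLE_KEY:
        return f"single_key block {block_index}"
    return f"alternate_key {hand.value}"


def read_events(
    path,
    aliases: dict[str, str] | None = None,
) -> dict[str, list[TappingBlock]]:
    """Read a long-form event-log CSV into tapping blocks keyed by participant.

    Rows are grouped by (participant_id, test_type, hand, block_index); events
    within each block are sorted by ``down_ms``.  An empty ``up_ms`` cell is
    interpreted as a key still held at block end: the event is truncated to the
    block duration and flagged.  Malformed rows raise
    :class:`EventValidationError` listing their 1-based line numbers (header is
    line 1).
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "key_label": str})
    missing_cols = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"event log is missing required column(s): {missing_cols}")

    bad_rows: list[int] = []
    problems: list[str] = []
    blocks: dict[str, dict[tuple, list[KeyEvent]]] = {}

    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after header
        try:
            tt = TestType(row.test_type)
            hand = Hand(row.hand)
            dur_ms = round(block_duration_s(tt) * 1000)
            down = int(row.down_ms)
            if isinstance(row.up_ms, float) and math.isnan(row.up_ms):
                up, truncated = dur_ms, True
            else:
                up, truncated = int(row.up_ms), False
            ev = KeyEvent(
                key_label=normalize_key(row.key_label, aliases),
                down_ms=down,
                up_ms=up,
                truncated=truncated,
            )
            if down >= dur_ms or up > dur_ms:
                raise ValueError(
                    f"event at {down}-{up} ms extends beyond the {dur_ms} ms block"
                )
            key = (str(row.participant_id), tt, hand, int(row.block_index))
        except (ValueError, TypeError) as exc:
            bad_rows.append(line)
            problems.append(f"line {line}: {exc}")
            continue
        blocks.setdefault(key[0], {}).setdefault(key[1:], []).append(ev)

    if bad_rows:
        raise EventValidationError(
            "invalid event rows:\n" + "\n".join(problems), rows=bad_rows
        )

    out: dict[str, list[TappingBlock]] = {}
    for pid, groups in blocks.items():
        out[pid] = [
            TappingBlock(
                test_type=tt,
                hand=hand,
                block_index=bi,
                duration_s=block_duration_s(tt),
                events=evs,
            )
            for (tt, hand, bi), evs in sorted(
                groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2])
            )
        ]
    return out


def events_to_frame(blocks_by_pid: dict[str, list[TappingBlock]]) -> pd.DataFrame:
    """Flatten blocks into the long-form event table (truncated key-ups become empty)."""
    rows = []
    for pid in blocks_by_pid:
        for b in blocks_by_pid[pid]:
            for e in b.events:
                rows.append(
                    (
                        pid,
                        b.test_type.value,
                        b.hand.value,
                        b.block_index,
                        e.key_label,
                        e.down_ms,
                        "" if e.truncated else e.up_ms,
                    )
                )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(blocks_by_pid: dict[str, list[TappingBlock]], path) -> None:
    """Write tapping blocks to the long-form event-log CSV."""
    events_to_frame(blocks_by_pid).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# participant table I/O
# ---------------------------------------------------------------------------


def _parse_bool(value, column: str, line: int) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    v = str(value).strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0"):
        return False
    raise EventValidationError(
        f"line {line}: column {column!r} must be yes/no, got {value!r}", rows=[line]
    )


def _parse_count(value):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def read_participants(path) -> Cohort:
    """Read the participant table CSV (no tapping blocks attached)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = [
        "participant_id",
        "age_years",
        "sex",
        "education_level",
        "hads_anxiety",
        "hads_depression",
    ]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"participant table is missing required column(s): {missing_cols}"
        )

    participants = []
    for pos, row in df.iterrows():
        line = pos + 2
        kwargs = dict(
            participant_id=str(row["participant_id"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            education_level=str(row["education_level"]),
            hads_anxiety=int(row["hads_anxiety"]),
            hads_depression=int(row["hads_depression"]),
        )
        for name in _BOOL_FIELDS:
            kwargs[name] = _parse_bool(row.get(name), name, line)
        for name in _COUNT_FIELDS:
            kwargs[name] = _parse_count(row.get(name))
        try:
            participants.append(ParticipantRecord(**kwargs))
        except ValueError as exc:
            raise EventValidationError(f"line {line}: {exc}", rows=[line]) from exc
    return Cohort(participants=participants, provenance={"source": str(path)})


def participants_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Scalar participant fields as a DataFrame (booleans as yes/no strings)."""
    rows = []
    for p in cohort.participants:
        row = {
            "participant_id": p.participant_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "education_level": p.education_level,
            "hads_anxiety": p.hads_anxiety,
            "hads_depression": p.hads_depression,
        }
        for name in _BOOL_FIELDS:
            v = getattr(p, name)
            row[name] = "" if v is None else ("yes" if v else "no")
        for name in _COUNT_FIELDS:
            v = getattr(p, name)
            row[name] = "" if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def write_participants(cohort: Cohort, path) -> None:
    """Write the participant table CSV."""
    participants_to_frame(cohort).to_csv(path, index=False)


def attach_blocks(
    cohort: Cohort, blocks_by_pid: dict[str, list[TappingBlock]]
) -> Cohort:
    """Return a cohort whose participants carry the given tapping blocks."""
    participants = [
        replace(p, blocks=list(blocks_by_pid.get(p.participant_id, [])))
        for p in cohort.participants
    ]
    return Cohort(participants=participants, provenance=dict(cohort.provenance))


# ---------------------------------------------------------------------------
# protocol segmentation / completeness
# ---------------------------------------------------------------------------


def segment_protocol(
    blocks: list[TappingBlock], participant_id: str = ""
) -> ProtocolReport:
    """Report whether one participant's blocks form a complete protocol.

    Complete means exactly four single-key blocks (indices 1-4, dominant hand)
    and one alternate-key block per hand.  Duplicate (test, hand, index)
    combinations and missing slots are listed; this is report-only and never
    raises.
    """
    seen: dict[tuple, int] = {}
    for b in blocks:
        seen[b.key()] = seen.get(b.key(), 0) + 1

    missing: list[str] = []
    duplicates: list[str] = []
    for tt, slots in PROTOCOL_BLOCKS.items():
        for hand, bi in slots:
            n = seen.get((tt, hand, bi), 0)
            if n == 0:
                missing.append(_block_label(tt, hand, bi))
            elif n > 1:
                duplicates.append(_block_label(tt, hand, bi))
    for tt, hand, bi in seen:
        if (hand, bi) not in PROTOCOL_BLOCKS[tt]:
            duplicates.append(f"unexpected {_block_label(tt, hand, bi)}")

    return ProtocolReport(
        participant_id=participant_id,
        complete=not missing and not duplicates,
        missing=missing,
        duplicates=duplicates,
    )


def protocol_complete(participant: ParticipantRecord) -> bool:
    """True iff the participant finished all 4 single-key and both alternate-key blocks."""
    return segment_protocol(participant.blocks, participant.participant_id).complete
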