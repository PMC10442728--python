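"""Chat administration of a day-framed 13-item short mood questionnaire.

The instrument is the Short Mood and Feelings Questionnaire re-framed to the
current day ("I feel sad today.") instead of the usual two-week window, and
answered over chat by typing 0, 1, or 2. Each prompt carries the item
statement plus an anchor reminder (0=no, 1=sometimes, 2=yes) — a fix that
came out of piloting, where bare numeric instructions confused respondents.
Answers can be corrected until the day's cycle closes; the total score is
the plain item sum, 0..26.

Item statements ship as replaceable config data: the default wording below
is a day-framed stand-in, and deployments substitute the licensed
instrument text for their locale.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

N_ITEMS = 13

ANCHORS: dict[int, str] = {0: "no", 1: "sometimes", 2: "yes"}

ANCHOR_REMINDER = "(0=no, 1=sometimes, 2=yes)"

# Day-framed default statements; synthetic stand-in wording, one item per
# symptom domain of the instrument. Deployments replace these with licensed
# text via the protocol config.
DEFAULT_ITEMS: tuple[str, ...] = (
    "I feel sad today.",
    "I don't feel like enjoying anything today.",
    "I feel so tired today that I just sit around and do nothing.",
    "I feel very restless today.",
    "I feel I am no good today.",
    "I cry a lot today.",
    "I find it hard to think properly or concentrate today.",
    "I hate myself today.",
    "I feel I am a bad person today.",
    "I feel lonely today.",
    "I think nobody really loves me today.",
    "I think I can never be as good as other kids today.",
    "I feel I do everything wrong today.",
)

SCORE_MAX = 2 * N_ITEMS  # 26


class ProtocolError(ValueError):
    """Questionnaire misuse: bad item index or premature scoring."""


@dataclass(frozen=True)
class SmfqForm:
    items: tuple[str, ...] = DEFAULT_ITEMS
    anchors: dict[int, str] = field(default_factory=lambda: dict(ANCHORS))

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ProtocolError(f"form must have exactly {N_ITEMS} items")
        if set(self.anchors) != {0, 1, 2}:
            raise ProtocolError("anchor keys must be exactly {0, 1, 2}")

    @property
    def anchor_reminder(self) -> str:
        return "(" + ", ".join(f"{k}={self.anchors[k]}" for k in (0, 1, 2)) + ")"


@dataclass(frozen=True)
class Correction:
    item_index: int
    old: int
    new: int
    at: Optional[dt.datetime] = None


@dataclass
class SmfqResponse:
    """Mutable per-cycle answer sheet with a correction trail."""

    answers: list[Optional[int]] = field(default_factory=lambda: [None] * N_ITEMS)
    answered_at: list[Optional[dt.datetime]] = field(
        default_factory=lambda: [None] * N_ITEMS
    )
    corrections: list[Correction] = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return all(a is not None for a in self.answers)

    @property
    def next_unanswered(self) -> Optional[int]:
        for i, a in enumerate(self.answers):
            if a is None:
                return i
        return None


def item_prompt(form: SmfqForm, index: int, participant_name: str = "") -> str:
    """The outbound text for one item: statement plus anchor reminder."""
    if not 0 <= index < N_ITEMS:
        raise ProtocolError(f"item index {index} out of range 0..{N_ITEMS - 1}")
    return f"{form.items[index]} {form.anchor_reminder}"


def record_answer(
    response: SmfqResponse,
    index: int,
    value: int,
    at: Optional[dt.datetime] = None,
) -> SmfqResponse:
    """Store a 0/1/2 answer; re-answering an item appends a correction."""
    if not 0 <= index < N_ITEMS:
        raise ProtocolError(f"item index {index} out of range 0..{N_ITEMS - 1}")
    if value not in (0, 1, 2):
        raise ProtocolError(f"answer must be 0, 1 or 2, got {value!r}")
    old = response.answers[index]
    if old is not None and old != value:
        response.corrections.append(Correction(item_index=index, old=old, new=value, at=at))
    response.answers[index] = value
    response.answered_at[index] = at
    return response


def score(response: SmfqResponse) -> int:
    """Total score: sum of the 13 answers, range [0, 26]."""
    if not response.completed:
        raise ProtocolError("cannot score an incomplete response")
    return sum(a for a in response.answers if a is not None)
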