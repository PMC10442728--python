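"""Messaging adapter contract and the append-only JSONL event log.

Every inbound message, outbound message, and state transition is one Event:
one JSON object per line, UTF-8, ISO-8601 timestamps with zone offset. The
log is the system's persistence and the analytics substrate; audio content
is carried as (descriptor, duration) only — the engine's logic depends on
duration alone, and keeping media bytes out of the core minimizes what can
leak.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Protocol

from pydantic import BaseModel, ConfigDict, model_validator

Direction = Literal["inbound", "outbound", "system"]
EventKind = Literal[
    "text",
    "audio",
    "state_transition",
    "snooze",
    "expiry_notice",
    "acknowledgment",
]


class LogParseError(ValueError):
    """A JSONL line failed validation; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class Event(BaseModel):
    model_config = ConfigDict(frozen=True)

    timestamp: dt.datetime
    participant_id: str
    direction: Direction
    kind: EventKind
    body: str = ""
    audio_duration: Optional[float] = None  # seconds, audio events only
    day_index: Optional[int] = None         # None = unprompted interaction
    excluded: bool = False                  # day-0 data, flagged not dropped

    @model_validator(mode="after")
    def _audio_consistency(self) -> "Event":
        if self.kind == "audio":
            if self.audio_duration is None or self.audio_duration <= 0:
                raise ValueError("audio events require audio_duration > 0")
        elif self.audio_duration is not None:
            raise ValueError("audio_duration only valid on audio events")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamps must carry a zone offset")
        return self

    def to_json(self) -> str:
        data = self.model_dump(mode="json")
        return json.dumps(data, ensure_ascii=False, separators=(",", ":"))


def parse_event(line: str, lineno: int = 0) -> Event:
    try:
        data = json.loads(line)
    except json.JSONDecodeError as exc:
        raise LogParseError(lineno, f"invalid JSON: {exc}") from exc
    try:
        return Event.model_validate(data)
    except Exception as exc:
        raise LogParseError(lineno, str(exc)) from exc


def read_log(path: str | Path) -> list[Event]:
    """Read an ordered event sequence; malformed lines report their number."""
    events: list[Event] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            events.append(parse_event(line, lineno))
    return events


def append_event(path: str | Path, event: Event) -> None:
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(event.to_json() + "\n")


def write_log(path: str | Path, events: Iterable[Event]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for event in events:
            fh.write(event.to_json() + "\n")


def dumps_log(events: Iterable[Event]) -> str:
    return "".join(e.to_json() + "\n" for e in events)


class TransportError(RuntimeError):
    """Retriable adapter failure (e.g. messaging-platform API outage)."""


class DeliveryReceipt(BaseModel):
    model_config = ConfigDict(frozen=True)

    participant_id: str
    delivered_at: dt.datetime


class Transport(Protocol):
    """Adapter contract: deliveries are ordered per participant.

    A production adapter wraps a messaging-platform API; tests use
    :class:`MockTransport`. ``deliver`` is called after the engine's typing
    delay has elapsed and must either return a receipt or raise
    :class:`TransportError`.
    """

    def deliver(self, participant_id: str, body: str, at: dt.datetime) -> DeliveryReceipt: ...


class MockTransport:
    """In-memory transport recording deliveries; can be told to fail."""

    def __init__(self) -> None:
        self.delivered: list[tuple[str, str, dt.datetime]] = []
        self.fail_next = 0

    def deliver(self, participant_id: str, body: str, at: dt.datetime) -> DeliveryReceipt:
        if self.fail_next > 0:
            self.fail_next -= 1
            raise TransportError("simulated adapter failure")
        self.delivered.append((participant_id, body, at))
        return DeliveryReceipt(participant_id=participant_id, delivered_at=at)


class ConsoleTransport:
    """Prints outbound messages; used by the interactive chat command."""

    def deliver(self, participant_id: str, body: str, at: dt.datetime) -> DeliveryReceipt:
        print(f"[{at:%a day %H:%M}] bot: {body}")
        return DeliveryReceipt(participant_id=participant_id, delivered_at=at)
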