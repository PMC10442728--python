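"""Virtual-clock scheduler for daily interaction cycles.

A cycle opens at the first-prompt time (13:30 by default). While the
participant has not replied, reminders repeat at a fixed interval (3 h) but
never at or after the next-morning window close (06:00). A snooze replaces
the reminder train and re-prompts at the requested time, capped at 03:00 the
next day. A cycle that is not completed by window close expires; a single
expiry notice fires at 10:00 the next morning and nothing else is ever sent
between window close and the next cycle's first prompt.

Time is injected: the engine and simulator consume an object with a
``now()`` method, so the full multi-day protocol replays deterministically
in test time, and a wall-clock implementation satisfies the same contract.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Protocol

from .protocol import ProtocolConfig


class Clock(Protocol):
    def now(self) -> dt.datetime: ...


@dataclass
class VirtualClock:
    """Discretely advanced clock; never moves backwards."""

    current: dt.datetime

    def now(self) -> dt.datetime:
        return self.current

    def advance_to(self, when: dt.datetime) -> None:
        if when < self.current:
            raise ValueError(f"clock cannot move backwards ({when} < {self.current})")
        self.current = when

    def advance(self, delta: dt.timedelta) -> None:
        self.advance_to(self.current + delta)


class CycleStatus(str, enum.Enum):
    PENDING = "PENDING"
    PROMPTED = "PROMPTED"
    SNOOZED = "SNOOZED"
    IN_PROGRESS = "IN_PROGRESS"
    COMPLETED = "COMPLETED"
    EXPIRED = "EXPIRED"


TERMINAL_STATUSES = frozenset({CycleStatus.COMPLETED, CycleStatus.EXPIRED})

# Legal state-machine moves; terminal states have no successors.
_TRANSITIONS: dict[CycleStatus, frozenset[CycleStatus]] = {
    CycleStatus.PENDING: frozenset({CycleStatus.PROMPTED, CycleStatus.EXPIRED}),
    CycleStatus.PROMPTED: frozenset(
        {CycleStatus.SNOOZED, CycleStatus.IN_PROGRESS, CycleStatus.EXPIRED}
    ),
    CycleStatus.SNOOZED: frozenset({CycleStatus.PROMPTED, CycleStatus.EXPIRED}),
    CycleStatus.IN_PROGRESS: frozenset(
        {CycleStatus.SNOOZED, CycleStatus.COMPLETED, CycleStatus.EXPIRED}
    ),
    CycleStatus.COMPLETED: frozenset(),
    CycleStatus.EXPIRED: frozenset(),
}


class FireKind(str, enum.Enum):
    FIRST_PROMPT = "FIRST_PROMPT"
    REMINDER = "REMINDER"
    SNOOZE_PROMPT = "SNOOZE_PROMPT"
    EXPIRY_NOTICE = "EXPIRY_NOTICE"


class SnoozeRejected(ValueError):
    """Requested snooze time is not in the future; caller should re-prompt."""


@dataclass(frozen=True)
class CycleClockState:
    cycle_date: dt.date
    status: CycleStatus = CycleStatus.PENDING
    prompts_sent: int = 0
    snoozed_until: Optional[dt.datetime] = None
    last_prompt_at: Optional[dt.datetime] = None
    expiry_notice_sent: bool = False

    def transition(self, new_status: CycleStatus) -> "CycleClockState":
        if new_status != self.status and new_status not in _TRANSITIONS[self.status]:
            raise ValueError(f"illegal transition {self.status.value} -> {new_status.value}")
        return replace(self, status=new_status)


def _at(date: dt.date, t: dt.time, config: ProtocolConfig) -> dt.datetime:
    return dt.datetime.combine(date, t, tzinfo=config.tzinfo)


def window_open(cycle_date: dt.date, config: ProtocolConfig) -> dt.datetime:
    return _at(cycle_date, config.first_prompt_time, config)


def window_close(cycle_date: dt.date, config: ProtocolConfig) -> dt.datetime:
    return _at(cycle_date + dt.timedelta(days=1), config.response_window_end, config)


def snooze_limit(cycle_date: dt.date, config: ProtocolConfig) -> dt.datetime:
    return _at(cycle_date + dt.timedelta(days=1), config.snooze_limit_time, config)


def expiry_notice_at(cycle_date: dt.date, config: ProtocolConfig) -> dt.datetime:
    return _at(cycle_date + dt.timedelta(days=1), config.expiry_notice_time, config)


def within_response_window(
    cycle_date: dt.date, now: dt.datetime, config: ProtocolConfig
) -> bool:
    """True iff ``now`` lies in the half-open window [13:30, next-day 06:00)."""
    return window_open(cycle_date, config) <= now < window_close(cycle_date, config)


def next_event(
    state: CycleClockState, config: ProtocolConfig, now: dt.datetime
) -> Optional[tuple[FireKind, dt.datetime]]:
    """Decide the next scheduled outbound action for a cycle, or None.

    Rules:

    * PENDING: the first prompt at cycle-date 13:30.
    * PROMPTED with no reply: a reminder ``reminder_interval`` after the last
      prompt, suppressed once it would land at or past window close.
    * SNOOZED: a re-prompt at the snoozed-until time.
    * Any non-terminal cycle past window close: the expiry notice at 10:00.
    * Terminal, or notice already sent: nothing.
    """
    if state.status in TERMINAL_STATUSES and not (
        state.status is CycleStatus.EXPIRED and not state.expiry_notice_sent
    ):
        return None

    close = window_close(state.cycle_date, config)
    notice = expiry_notice_at(state.cycle_date, config)

    if state.status is CycleStatus.EXPIRED:
        return (FireKind.EXPIRY_NOTICE, notice)

    if state.status is CycleStatus.PENDING:
        return (FireKind.FIRST_PROMPT, window_open(state.cycle_date, config))

    if state.status is CycleStatus.SNOOZED:
        assert state.snoozed_until is not None
        return (FireKind.SNOOZE_PROMPT, state.snoozed_until)

    if state.status is CycleStatus.PROMPTED:
        assert state.last_prompt_at is not None
        due = state.last_prompt_at + config.reminder_interval
        if due < close:
            return (FireKind.REMINDER, due)
        return (FireKind.EXPIRY_NOTICE, notice)

    # IN_PROGRESS: the dialog is reply-driven; the only scheduled action left
    # is expiry if the participant goes silent past window close.
    return (FireKind.EXPIRY_NOTICE, notice)


def apply_snooze(
    state: CycleClockState,
    requested_time: dt.datetime,
    config: ProtocolConfig,
    now: dt.datetime,
) -> CycleClockState:
    """Defer the cycle to ``requested_time``, capped at next-day 03:00.

    Requests past the cap clamp to it (the limit reads as a cap, not a
    validity test); requests not strictly in the future raise
    :class:`SnoozeRejected` so the engine can re-prompt.
    """
    if state.status not in (CycleStatus.PROMPTED, CycleStatus.IN_PROGRESS):
        raise ValueError(f"cannot snooze a cycle in status {state.status.value}")
    if requested_time <= now:
        raise SnoozeRejected("requested snooze time is in the past")
    limit = snooze_limit(state.cycle_date, config)
    when = min(requested_time, limit)
    if when <= now:  # clamp interval (now, limit] is empty past the limit
        raise SnoozeRejected("snoozing is no longer possible for this cycle")
    return replace(state.transition(CycleStatus.SNOOZED), snoozed_until=when)


def max_reminders(config: ProtocolConfig) -> int:
    """Upper bound on reminders per cycle: ceil(window length / interval)."""
    length = window_close(dt.date(2021, 1, 4), config) - window_open(
        dt.date(2021, 1, 4), config
    )
    return -(-length // config.reminder_interval)
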