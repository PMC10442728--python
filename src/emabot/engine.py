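"""Conversation state machine driving one participant through the protocol.

The engine consumes inbound messages (text, or audio as a duration), decides
what each one means in its dialog context, advances the day's script, and
emits outbound messages through a transport adapter after a typing delay
proportional to message length. All traffic and every cycle state change is
appended to the participant's event log, and the engine is a pure function
of (config, schedule, inbound sequence): replaying a log reproduces both the
state and the log itself byte for byte.

Reply understanding is deliberately rule-based — exact text matches after a
light normalization — mirroring how the deployed bot worked. The only
"vocabulary" is: the digits 0/1/2 during the questionnaire, yes/no at gates,
a small closure-word set (so "thank you" at the end of a day is not probed),
snooze requests, and a correction keyword.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass, field
from typing import Optional

from . import smfq as smfq_mod
from .protocol import (
    CLOSING_TEXT,
    DAY0_SCRIPT,
    FOLLOWUP_1_TEXT,
    FOLLOWUP_2_TEXT,
    OPENING_TEXT,
    DayMode,
    Expects,
    ProtocolConfig,
    ProtocolSchedule,
    render_prompt,
)
from .scheduler import (
    Clock,
    CycleClockState,
    CycleStatus,
    FireKind,
    SnoozeRejected,
    TERMINAL_STATUSES,
    apply_snooze,
    expiry_notice_at,
    next_event,
    within_response_window,
)
from .transport import Event, Transport, TransportError

REMINDER_TEXT = (
    "Hi [participant]! I'm still here. Are you available to answer "
    "today's questions?"
)
SNOOZE_RETURN_TEXT = "Hi [participant]! I'm back, as you asked."
SNOOZE_CONFIRM_TEXT = "Ok! I'll come back to you at {when}."
SNOOZE_REJECT_TEXT = (
    "That time has already passed. Can you tell me a later time today?"
)
AUDIO_ACK_TEXT = "Thank you for sending this audio!"
UNPROMPTED_CLARIFY_TEXT = (
    "Could you send me an audio message telling me more about that?"
)
AUDIO_REPROMPT_TEXT = "Could you answer with an audio recording, please?"
YESNO_REPROMPT_TEXT = "Please answer with 'yes' or 'no'."
NUMERIC_REPROMPT_TEXT = "Please answer by typing 0, 1 or 2 {anchors}."
FU2_GO_AHEAD_TEXT = "Great! Go ahead, I'm listening."
CORRECTION_WHICH_TEXT = "Sure! Which question would you like to correct? (1-13)"
CORRECTION_VALUE_TEXT = "What is your new answer for question {item}? {anchors}"
CORRECTION_DONE_TEXT = "Done! I changed question {item} to {value}."
EXPIRY_TEXT = (
    "Today's cycle has ended without completion — no problem! "
    "A new cycle begins today; I'll message you at {next_time}."
)
EXPIRY_FINAL_TEXT = (
    "Today's cycle has ended without completion. That was the last day — "
    "thank you for taking part!"
)

_YES_WORDS = frozenset({"yes", "yeah", "yep", "y", "sim"})
_NO_WORDS = frozenset({"no", "nope", "n", "nao", "não"})
_SNOOZE_RE = re.compile(r"\b(snooze|later)\b")
_TIME_RE = re.compile(r"\b(\d{1,2})(?::(\d{2}))?\s*h?\b")
_TERMINAL_PUNCT = ".,!?;:…"


class IntentKind(str, enum.Enum):
    CLOSURE = "CLOSURE"
    NUMERIC_ANSWER = "NUMERIC_ANSWER"
    YES = "YES"
    NO = "NO"
    SNOOZE_REQUEST = "SNOOZE_REQUEST"
    AUDIO = "AUDIO"
    FREE_TEXT = "FREE_TEXT"
    CORRECTION_REQUEST = "CORRECTION_REQUEST"
    UNSUPPORTED = "UNSUPPORTED"


@dataclass(frozen=True)
class ReplyIntent:
    kind: IntentKind
    value: Optional[int] = None            # 0/1/2 for NUMERIC_ANSWER
    time_of_day: Optional[dt.time] = None  # for SNOOZE_REQUEST, if stated
    duration: Optional[float] = None       # seconds, for AUDIO


def normalize(text: str) -> str:
    return text.strip().rstrip(_TERMINAL_PUNCT).strip().lower()


def _is_emoji_only(text: str) -> bool:
    stripped = text.strip()
    return bool(stripped) and not any(ch.isalnum() for ch in stripped)


def classify_reply(
    text: Optional[str],
    audio_duration: Optional[float],
    context: Optional[Expects],
    config: ProtocolConfig,
) -> ReplyIntent:
    """Classify one inbound message in its dialog context.

    Total over all inbound messages: anything unrecognized is FREE_TEXT, or
    UNSUPPORTED when the slot demands structured input (0/1/2 or yes/no).
    Closure words match exactly after lowercasing, trimming, and stripping
    terminal punctuation; no fuzzy matching.
    """
    if audio_duration is not None:
        return ReplyIntent(kind=IntentKind.AUDIO, duration=audio_duration)
    if text is None:
        raise ValueError("message must carry text or audio")

    norm = normalize(text)
    if norm in config.closure_words:
        return ReplyIntent(kind=IntentKind.CLOSURE)
    if config.emoji_closure and _is_emoji_only(text):
        return ReplyIntent(kind=IntentKind.CLOSURE)

    if _SNOOZE_RE.search(norm):
        tod: Optional[dt.time] = None
        match = _TIME_RE.search(_SNOOZE_RE.sub("", norm))
        if match:
            hour = int(match.group(1))
            minute = int(match.group(2) or 0)
            if 0 <= hour < 24 and 0 <= minute < 60:
                tod = dt.time(hour, minute)
        return ReplyIntent(kind=IntentKind.SNOOZE_REQUEST, time_of_day=tod)

    if context is Expects.NUMERIC and norm in config.correction_keywords:
        return ReplyIntent(kind=IntentKind.CORRECTION_REQUEST)
    if context is Expects.NUMERIC:
        if norm in ("0", "1", "2"):
            return ReplyIntent(kind=IntentKind.NUMERIC_ANSWER, value=int(norm))
        return ReplyIntent(kind=IntentKind.UNSUPPORTED)
    if context is Expects.YESNO:
        if norm in _YES_WORDS:
            return ReplyIntent(kind=IntentKind.YES)
        if norm in _NO_WORDS:
            return ReplyIntent(kind=IntentKind.NO)
        return ReplyIntent(kind=IntentKind.UNSUPPORTED)

    return ReplyIntent(kind=IntentKind.FREE_TEXT)


def typing_delay(outbound_text_length: int, config: ProtocolConfig) -> float:
    """Outbound pacing in seconds: linear in length between the clamps."""
    return config.typing_delay(outbound_text_length)


class ProbeDecision(str, enum.Enum):
    COMPLETE = "COMPLETE"
    FOLLOWUP_1 = "FOLLOWUP_1"
    FOLLOWUP_2 = "FOLLOWUP_2"


@dataclass
class Slot:
    """The reply the dialog is currently waiting for."""

    tag: str          # opening | q1gate | q1 | q2 | fu1 | fu2gate | fu2 | item
    expects: Expects
    prompt_text: str = ""
    reprompted: bool = False


@dataclass
class DailyCycle:
    day_index: int
    mode: DayMode
    clock: CycleClockState
    audio_seconds: float = 0.0
    followups_sent: int = 0
    primary_answered: int = 0  # of the 2 daily audio questions
    smfq: Optional[smfq_mod.SmfqResponse] = None
    engaged: bool = False
    had_snooze: bool = False
    slot: Optional[Slot] = None
    correction_stage: Optional[str] = None  # 'which' | 'value'
    correction_item: Optional[int] = None

    @property
    def status(self) -> CycleStatus:
        return self.clock.status


@dataclass
class Session:
    participant_id: str
    name: str
    onboarded_at: Optional[dt.datetime] = None
    cycles: dict[int, DailyCycle] = field(default_factory=dict)
    unprompted_events: list[Event] = field(default_factory=list)


def accumulate_audio(
    cycle: DailyCycle, new_audio: float, config: ProtocolConfig
) -> ProbeDecision:
    """Add a recording to the day's total and decide whether to probe.

    The daily goal is at least ``audio_target`` seconds across the answers.
    A total that has not strictly exceeded the target still triggers a probe
    (platforms report whole seconds, so a total landing exactly on the
    boundary is treated as not yet safely past it): first the open follow-up
    question, then the yes/no-gated one, never more than two per day.
    """
    if new_audio < 0:
        raise ValueError("audio duration cannot be negative")
    cycle.audio_seconds += new_audio
    if cycle.audio_seconds > config.audio_target:
        return ProbeDecision.COMPLETE
    if cycle.followups_sent == 0:
        return ProbeDecision.FOLLOWUP_1
    if cycle.followups_sent == 1:
        return ProbeDecision.FOLLOWUP_2
    return ProbeDecision.COMPLETE


class ChatEngine:
    """One participant's session: scheduler-driven prompts, reply handling.

    Time comes from an injected clock; ``pump()`` fires every scheduled
    action due at or before the current time (using the scheduled fire time,
    not the call time, as the timestamp base, so late pumping is harmless
    and replay is exact).
    """

    def __init__(
        self,
        config: ProtocolConfig,
        schedule: ProtocolSchedule,
        transport: Transport,
        clock: Clock,
        participant_id: str,
        name: str,
        form: Optional[smfq_mod.SmfqForm] = None,
    ) -> None:
        self.config = config
        self.schedule = schedule
        self.transport = transport
        self.clock = clock
        self.form = form or smfq_mod.SmfqForm()
        self.session = Session(participant_id=participant_id, name=name)
        self.events: list[Event] = []
        self._last_ts: Optional[dt.datetime] = None

    # -- event plumbing -----------------------------------------------------

    def _stamp(self, candidate: dt.datetime) -> dt.datetime:
        if self._last_ts is not None and candidate < self._last_ts:
            candidate = self._last_ts
        self._last_ts = candidate
        return candidate

    def _log(self, event: Event) -> Event:
        self.events.append(event)
        return event

    def _log_inbound(
        self,
        at: dt.datetime,
        kind: str,
        body: str,
        day_index: Optional[int],
        audio_duration: Optional[float] = None,
        excluded: bool = False,
    ) -> Event:
        event = Event(
            timestamp=self._stamp(at),
            participant_id=self.session.participant_id,
            direction="inbound",
            kind=kind,  # type: ignore[arg-type]
            body=body,
            audio_duration=audio_duration,
            day_index=day_index,
            excluded=excluded,
        )
        if day_index is not None and day_index > 0 and kind in ("text", "audio"):
            cycle = self.session.cycles.get(day_index)
            if cycle is not None:
                cycle.engaged = True
        return self._log(event)

    def _send(
        self,
        body: str,
        day_index: Optional[int],
        at: dt.datetime,
        kind: str = "text",
        excluded: bool = False,
    ) -> Optional[Event]:
        """Deliver one outbound message after its typing delay and log it.

        A transport failure is logged as a system event and swallowed: the
        engine's dialog state is left as-is and the message is simply lost,
        as with a messaging-API outage.
        """
        body = render_prompt(body, self.session.name)
        delay = dt.timedelta(seconds=typing_delay(len(body), self.config))
        base = at if self._last_ts is None else max(at, self._last_ts)
        delivered_at = base + delay
        try:
            receipt = self.transport.deliver(
                self.session.participant_id, body, delivered_at
            )
        except TransportError as exc:
            self._log(
                Event(
                    timestamp=self._stamp(delivered_at),
                    participant_id=self.session.participant_id,
                    direction="system",
                    kind="text",
                    body=f"delivery failed: {exc}",
                    day_index=day_index,
                    excluded=excluded,
                )
            )
            return None
        return self._log(
            Event(
                timestamp=self._stamp(receipt.delivered_at),
                participant_id=self.session.participant_id,
                direction="outbound",
                kind=kind,  # type: ignore[arg-type]
                body=body,
                day_index=day_index,
                excluded=excluded,
            )
        )

    def _log_transition(
        self, cycle: DailyCycle, new_status: CycleStatus, at: dt.datetime
    ) -> None:
        old = cycle.clock.status
        cycle.clock = cycle.clock.transition(new_status)
        self._log(
            Event(
                timestamp=self._stamp(at),
                participant_id=self.session.participant_id,
                direction="system",
                kind="state_transition",
                body=f"{old.value}->{new_status.value}",
                day_index=cycle.day_index,
                excluded=cycle.day_index == 0,
            )
        )

    # -- scheduler integration ----------------------------------------------

    def pump(self) -> None:
        """Fire every scheduled action due at or before the clock's now."""
        now = self.clock.now()
        while True:
            due: list[tuple[dt.datetime, int, FireKind, DailyCycle]] = []
            for cycle in self.session.cycles.values():
                pending = next_event(cycle.clock, self.config, now)
                if pending is not None and pending[1] <= now:
                    due.append((pending[1], cycle.day_index, pending[0], cycle))
            if not due:
                return
            due.sort(key=lambda item: (item[0], item[1]))
            when, _, kind, cycle = due[0]
            self._fire(cycle, kind, when)

    def _fire(self, cycle: DailyCycle, kind: FireKind, when: dt.datetime) -> None:
        from dataclasses import replace

        if kind is FireKind.FIRST_PROMPT:
            self._log_transition(cycle, CycleStatus.PROMPTED, when)
            cycle.clock = replace(
                cycle.clock, prompts_sent=cycle.clock.prompts_sent + 1,
                last_prompt_at=when,
            )
            cycle.slot = Slot(tag="opening", expects=Expects.ANY,
                              prompt_text=OPENING_TEXT)
            self._send(OPENING_TEXT, cycle.day_index, when)
        elif kind is FireKind.REMINDER:
            cycle.clock = replace(
                cycle.clock, prompts_sent=cycle.clock.prompts_sent + 1,
                last_prompt_at=when,
            )
            self._send(REMINDER_TEXT, cycle.day_index, when)
        elif kind is FireKind.SNOOZE_PROMPT:
            self._log_transition(cycle, CycleStatus.PROMPTED, when)
            cycle.clock = replace(
                cycle.clock, prompts_sent=cycle.clock.prompts_sent + 1,
                last_prompt_at=when, snoozed_until=None,
            )
            self._send(SNOOZE_RETURN_TEXT, cycle.day_index, when)
            if cycle.slot is not None and cycle.slot.tag != "opening":
                # Mid-dialog snooze: repeat the question that was pending.
                self._send(cycle.slot.prompt_text, cycle.day_index, when)
        elif kind is FireKind.EXPIRY_NOTICE:
            if cycle.clock.status not in TERMINAL_STATUSES:
                self._log_transition(cycle, CycleStatus.EXPIRED, when)
            cycle.clock = replace(cycle.clock, expiry_notice_sent=True)
            cycle.slot = None
            if cycle.day_index + 1 < self.config.n_days:
                body = EXPIRY_TEXT.format(
                    next_time=self.config.first_prompt_time.strftime("%H:%M")
                )
            else:
                body = EXPIRY_FINAL_TEXT
            self._send(body, cycle.day_index, when, kind="expiry_notice")

    # -- inbound handling ---------------------------------------------------

    def handle_inbound(
        self,
        text: Optional[str] = None,
        audio_duration: Optional[float] = None,
        at: Optional[dt.datetime] = None,
    ) -> None:
        at = at or self.clock.now()
        if self.session.onboarded_at is None:
            self.run_onboarding(text, audio_duration, at)
            return
        cycle = self._awaiting_cycle(at)
        if cycle is None:
            self._handle_unprompted(text, audio_duration, at)
            return
        context = cycle.slot.expects if cycle.slot is not None else None
        intent = classify_reply(text, audio_duration, context, self.config)
        self._dispatch(cycle, intent, text, audio_duration, at)

    def _awaiting_cycle(self, at: dt.datetime) -> Optional[DailyCycle]:
        """The cycle this message belongs to, if any dialog is open.

        A cycle accepts input while prompted or snoozed inside its response
        window; a dialog already in progress may run on past window close
        (grace continuation) until the expiry notice fires.
        """
        for cycle in self.session.cycles.values():
            if cycle.day_index == 0 or cycle.clock.status in TERMINAL_STATUSES:
                continue
            if cycle.clock.status in (CycleStatus.PROMPTED, CycleStatus.SNOOZED):
                if within_response_window(cycle.clock.cycle_date, at, self.config):
                    return cycle
            elif cycle.clock.status is CycleStatus.IN_PROGRESS:
                if at < expiry_notice_at(cycle.clock.cycle_date, self.config):
                    return cycle
        return None

    # -- onboarding ---------------------------------------------------------

    def run_onboarding(
        self,
        text: Optional[str],
        audio_duration: Optional[float],
        at: dt.datetime,
    ) -> None:
        """Activate the session: any first message starts day 0.

        The day-0 sequence reviews how the bot works, states that audio is
        not listened to immediately and that the bot is not a help channel.
        All day-0 events carry the excluded flag. Idempotent: once onboarded,
        later messages route through normal handling.
        """
        kind = "audio" if audio_duration is not None else "text"
        self._log_inbound(
            at, kind, text or "(audio)", day_index=0,
            audio_duration=audio_duration, excluded=True,
        )
        self.session.onboarded_at = at
        start = at.date()
        self.session.cycles[0] = DailyCycle(
            day_index=0,
            mode=DayMode.INTRODUCTION,
            clock=CycleClockState(cycle_date=start, status=CycleStatus.COMPLETED),
        )
        for day in range(1, self.config.n_days):
            plan = self.schedule.day(day)
            self.session.cycles[day] = DailyCycle(
                day_index=day,
                mode=plan.mode,
                clock=CycleClockState(cycle_date=start + dt.timedelta(days=day)),
            )
        for message in DAY0_SCRIPT:
            self._send(message, 0, at, excluded=True)

    # -- unprompted interactions --------------------------------------------

    def _handle_unprompted(
        self,
        text: Optional[str],
        audio_duration: Optional[float],
        at: dt.datetime,
    ) -> None:
        intent = classify_reply(text, audio_duration, None, self.config)
        if intent.kind is IntentKind.AUDIO:
            event = self._log_inbound(
                at, "audio", "(unprompted audio)", day_index=None,
                audio_duration=audio_duration,
            )
            self.session.unprompted_events.append(event)
            self._send(AUDIO_ACK_TEXT, None, at, kind="acknowledgment")
        elif intent.kind is IntentKind.CLOSURE:
            # Closure words or a bare emoji: logged silently, no probe.
            event = self._log_inbound(at, "acknowledgment", text or "", day_index=None)
            self.session.unprompted_events.append(event)
        else:
            event = self._log_inbound(at, "text", text or "", day_index=None)
            self.session.unprompted_events.append(event)
            self._send(UNPROMPTED_CLARIFY_TEXT, None, at)

    # -- dialog dispatch ----------------------------------------------------

    def _dispatch(
        self,
        cycle: DailyCycle,
        intent: ReplyIntent,
        text: Optional[str],
        audio_duration: Optional[float],
        at: dt.datetime,
    ) -> None:
        if intent.kind is IntentKind.CLOSURE:
            self._log_inbound(at, "acknowledgment", text or "", cycle.day_index)
            return
        if intent.kind is IntentKind.SNOOZE_REQUEST:
            self._handle_snooze(cycle, intent, text or "", at)
            return
        if cycle.clock.status is CycleStatus.SNOOZED:
            # The participant came back before the snoozed prompt fired.
            self._log_transition(cycle, CycleStatus.PROMPTED, at)
        if cycle.clock.status is CycleStatus.PROMPTED:
            self._log_transition(cycle, CycleStatus.IN_PROGRESS, at)
            if cycle.slot is None or cycle.slot.tag == "opening":
                self._log_availability_reply(cycle, intent, text, audio_duration, at)
                self._start_dialog(cycle, at)
                return
        assert cycle.slot is not None
        handler = {
            "q1gate": self._on_q1gate,
            "q1": self._on_q1,
            "q2": self._on_q2,
            "fu1": self._on_fu1,
            "fu2gate": self._on_fu2gate,
            "fu2": self._on_fu2,
            "item": self._on_item,
        }[cycle.slot.tag]
        handler(cycle, intent, text, audio_duration, at)

    def _log_availability_reply(
        self,
        cycle: DailyCycle,
        intent: ReplyIntent,
        text: Optional[str],
        audio_duration: Optional[float],
        at: dt.datetime,
    ) -> None:
        if intent.kind is IntentKind.AUDIO:
            self._log_inbound(
                at, "audio", "(audio)", cycle.day_index,
                audio_duration=audio_duration,
            )
        else:
            self._log_inbound(at, "text", text or "", cycle.day_index)

    def _handle_snooze(
        self, cycle: DailyCycle, intent: ReplyIntent, raw_text: str, at: dt.datetime
    ) -> None:
        self._log_inbound(at, "snooze", raw_text, cycle.day_index)
        if cycle.clock.status is CycleStatus.SNOOZED:
            cycle.clock = cycle.clock.transition(CycleStatus.PROMPTED)
        if intent.time_of_day is not None:
            candidate = dt.datetime.combine(
                at.date(), intent.time_of_day, tzinfo=at.tzinfo
            )
            if candidate <= at:  # next occurrence of that wall time
                candidate += dt.timedelta(days=1)
        else:
            candidate = at + self.config.reminder_interval
        try:
            cycle.clock = apply_snooze(cycle.clock, candidate, self.config, at)
        except SnoozeRejected:
            self._send(SNOOZE_REJECT_TEXT, cycle.day_index, at)
            return
        cycle.had_snooze = True
        assert cycle.clock.snoozed_until is not None
        self._send(
            SNOOZE_CONFIRM_TEXT.format(
                when=cycle.clock.snoozed_until.strftime("%H:%M")
            ),
            cycle.day_index,
            at,
        )

    def _start_dialog(self, cycle: DailyCycle, at: dt.datetime) -> None:
        plan = self.schedule.day(cycle.day_index)
        if cycle.mode is DayMode.AUDIO_QUESTIONS:
            first = plan.prompts[0]
            if first.expects is Expects.YESNO:
                cycle.slot = Slot(tag="q1gate", expects=Expects.YESNO,
                                  prompt_text=first.text)
            else:
                cycle.slot = Slot(tag="q1", expects=Expects.AUDIO,
                                  prompt_text=first.text)
            self._send(first.text, cycle.day_index, at)
        elif cycle.mode is DayMode.QUESTIONNAIRE:
            cycle.smfq = smfq_mod.SmfqResponse()
            self._send_item(cycle, 0, at)
        else:  # pragma: no cover - INTRODUCTION days never reach here
            raise ValueError(f"day {cycle.day_index} has no dialog")

    # -- audio-day handlers --------------------------------------------------

    def _record_audio(
        self, cycle: DailyCycle, duration: float, at: dt.datetime
    ) -> None:
        self._log_inbound(
            at, "audio", "(audio)", cycle.day_index, audio_duration=duration
        )

    def _on_q1gate(self, cycle, intent, text, audio_duration, at) -> None:
        plan = self.schedule.day(cycle.day_index)
        gate = plan.prompts[0]
        if intent.kind in (IntentKind.YES, IntentKind.NO):
            self._log_inbound(at, "text", text or "", cycle.day_index)
            branch = gate.branch_yes if intent.kind is IntentKind.YES else gate.branch_no
            assert branch is not None
            cycle.slot = Slot(tag="q1", expects=Expects.AUDIO, prompt_text=branch)
            self._send(branch, cycle.day_index, at)
        elif intent.kind is IntentKind.AUDIO:
            # Audio straight through the gate answers the first question.
            self._record_audio(cycle, intent.duration or 0.0, at)
            cycle.audio_seconds += intent.duration or 0.0
            cycle.primary_answered = 1
            self._ask_q2(cycle, at)
        else:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            self._send(YESNO_REPROMPT_TEXT, cycle.day_index, at)

    def _ask_q2(self, cycle: DailyCycle, at: dt.datetime) -> None:
        q2 = self.schedule.day(cycle.day_index).prompts[1]
        cycle.slot = Slot(tag="q2", expects=Expects.AUDIO, prompt_text=q2.text)
        self._send(q2.text, cycle.day_index, at)

    def _on_q1(self, cycle, intent, text, audio_duration, at) -> None:
        if intent.kind is IntentKind.AUDIO:
            self._record_audio(cycle, intent.duration or 0.0, at)
            cycle.audio_seconds += intent.duration or 0.0
            cycle.primary_answered = 1
            self._ask_q2(cycle, at)
        else:
            self._on_text_in_audio_slot(cycle, text or "", at, after_accept=self._ask_q2)

    def _on_text_in_audio_slot(self, cycle, raw_text, at, after_accept) -> None:
        """Text where audio is expected: one gentle reprompt, then accept.

        The accepted text counts as a data point (never discard what the
        participant offered) but contributes nothing to the audio total.
        """
        assert cycle.slot is not None
        if not cycle.slot.reprompted:
            cycle.slot.reprompted = True
            self._log_inbound(at, "text", raw_text, cycle.day_index)
            self._send(AUDIO_REPROMPT_TEXT, cycle.day_index, at)
        else:
            self._log_inbound(at, "text", raw_text, cycle.day_index)
            if cycle.slot.tag in ("q1",):
                cycle.primary_answered = 1
                after_accept(cycle, at)
            elif cycle.slot.tag in ("q2", "fu1"):
                cycle.primary_answered = 2
                self._apply_probe_decision(
                    cycle, accumulate_audio(cycle, 0.0, self.config), at
                )
            else:  # fu2
                self._complete(cycle, at)

    def _on_q2(self, cycle, intent, text, audio_duration, at) -> None:
        if intent.kind is IntentKind.AUDIO:
            self._record_audio(cycle, intent.duration or 0.0, at)
            cycle.primary_answered = 2
            decision = accumulate_audio(cycle, intent.duration or 0.0, self.config)
            self._apply_probe_decision(cycle, decision, at)
        else:
            self._on_text_in_audio_slot(cycle, text or "", at, after_accept=None)

    def _apply_probe_decision(
        self, cycle: DailyCycle, decision: ProbeDecision, at: dt.datetime
    ) -> None:
        if decision is ProbeDecision.FOLLOWUP_1:
            cycle.followups_sent = 1
            cycle.slot = Slot(tag="fu1", expects=Expects.AUDIO,
                              prompt_text=FOLLOWUP_1_TEXT)
            self._send(FOLLOWUP_1_TEXT, cycle.day_index, at)
        elif decision is ProbeDecision.FOLLOWUP_2:
            cycle.followups_sent = 2
            cycle.slot = Slot(tag="fu2gate", expects=Expects.YESNO,
                              prompt_text=FOLLOWUP_2_TEXT)
            self._send(FOLLOWUP_2_TEXT, cycle.day_index, at)
        else:
            self._complete(cycle, at)

    def _on_fu1(self, cycle, intent, text, audio_duration, at) -> None:
        if intent.kind is IntentKind.AUDIO:
            self._record_audio(cycle, intent.duration or 0.0, at)
            decision = accumulate_audio(cycle, intent.duration or 0.0, self.config)
            self._apply_probe_decision(cycle, decision, at)
        else:
            self._on_text_in_audio_slot(cycle, text or "", at, after_accept=None)

    def _on_fu2gate(self, cycle, intent, text, audio_duration, at) -> None:
        if intent.kind is IntentKind.YES:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            cycle.slot = Slot(tag="fu2", expects=Expects.AUDIO,
                              prompt_text=FU2_GO_AHEAD_TEXT)
            self._send(FU2_GO_AHEAD_TEXT, cycle.day_index, at)
        elif intent.kind is IntentKind.NO:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            self._complete(cycle, at)
        elif intent.kind is IntentKind.AUDIO:
            # Audio without the yes counts as an implicit yes.
            self._record_audio(cycle, intent.duration or 0.0, at)
            cycle.audio_seconds += intent.duration or 0.0
            self._complete(cycle, at)
        else:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            self._send(YESNO_REPROMPT_TEXT, cycle.day_index, at)

    def _on_fu2(self, cycle, intent, text, audio_duration, at) -> None:
        if intent.kind is IntentKind.AUDIO:
            self._record_audio(cycle, intent.duration or 0.0, at)
            cycle.audio_seconds += intent.duration or 0.0
            self._complete(cycle, at)
        else:
            self._on_text_in_audio_slot(cycle, text or "", at, after_accept=None)

    # -- questionnaire handlers ----------------------------------------------

    def _send_item(self, cycle: DailyCycle, index: int, at: dt.datetime) -> None:
        prompt = smfq_mod.item_prompt(self.form, index, self.session.name)
        cycle.slot = Slot(tag="item", expects=Expects.NUMERIC, prompt_text=prompt)
        self._send(prompt, cycle.day_index, at)

    def _resume_items(self, cycle: DailyCycle, at: dt.datetime) -> None:
        assert cycle.smfq is not None
        nxt = cycle.smfq.next_unanswered
        if nxt is None:
            self._complete(cycle, at)
        else:
            self._send_item(cycle, nxt, at)

    def _on_item(self, cycle, intent, text, audio_duration, at) -> None:
        assert cycle.smfq is not None
        if cycle.correction_stage == "which":
            self._log_inbound(at, "text", text or "", cycle.day_index)
            number = normalize(text or "")
            if number.isdigit() and 1 <= int(number) <= smfq_mod.N_ITEMS and \
                    cycle.smfq.answers[int(number) - 1] is not None:
                cycle.correction_item = int(number) - 1
                cycle.correction_stage = "value"
                self._send(
                    CORRECTION_VALUE_TEXT.format(
                        item=number, anchors=self.form.anchor_reminder
                    ),
                    cycle.day_index, at,
                )
            else:
                self._send(CORRECTION_WHICH_TEXT, cycle.day_index, at)
            return
        if cycle.correction_stage == "value":
            if intent.kind is IntentKind.NUMERIC_ANSWER:
                self._log_inbound(at, "text", text or "", cycle.day_index)
                assert cycle.correction_item is not None
                smfq_mod.record_answer(
                    cycle.smfq, cycle.correction_item, intent.value or 0, at=at
                )
                self._send(
                    CORRECTION_DONE_TEXT.format(
                        item=cycle.correction_item + 1, value=intent.value
                    ),
                    cycle.day_index, at,
                )
                cycle.correction_stage = None
                cycle.correction_item = None
                self._resume_items(cycle, at)
            else:
                self._log_inbound(at, "text", text or "", cycle.day_index)
                self._send(
                    NUMERIC_REPROMPT_TEXT.format(anchors=self.form.anchor_reminder),
                    cycle.day_index, at,
                )
            return
        if intent.kind is IntentKind.CORRECTION_REQUEST:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            cycle.correction_stage = "which"
            self._send(CORRECTION_WHICH_TEXT, cycle.day_index, at)
            return
        if intent.kind is IntentKind.NUMERIC_ANSWER:
            self._log_inbound(at, "text", text or "", cycle.day_index)
            index = cycle.smfq.next_unanswered
            assert index is not None
            smfq_mod.record_answer(cycle.smfq, index, intent.value or 0, at=at)
            self._resume_items(cycle, at)
            return
        if intent.kind is IntentKind.AUDIO:
            self._record_audio(cycle, intent.duration or 0.0, at)
        else:
            self._log_inbound(at, "text", text or "", cycle.day_index)
        self._send(
            NUMERIC_REPROMPT_TEXT.format(anchors=self.form.anchor_reminder),
            cycle.day_index, at,
        )

    # -- completion ----------------------------------------------------------

    def _complete(self, cycle: DailyCycle, at: dt.datetime) -> None:
        cycle.slot = None
        self._log_transition(cycle, CycleStatus.COMPLETED, at)
        self._send(CLOSING_TEXT, cycle.day_index, at)


def replay(
    events: list[Event],
    config: ProtocolConfig,
    schedule: ProtocolSchedule,
    name: str,
    form: Optional[smfq_mod.SmfqForm] = None,
) -> ChatEngine:
    """Rebuild engine state by re-running the inbound half of a log.

    Feeding the logged inbound messages back through a fresh engine, with
    the clock advanced to each original timestamp, regenerates the outbound
    half and the state machine exactly (event-sourcing round trip). The
    caller can compare ``engine.events`` with the original log.
    """
    from .scheduler import VirtualClock
    from .transport import MockTransport

    if not events:
        raise ValueError("cannot replay an empty log")
    participant_id = events[0].participant_id
    clock = VirtualClock(current=events[0].timestamp)
    engine = ChatEngine(
        config, schedule, MockTransport(), clock, participant_id, name, form=form
    )
    for event in events:
        if event.timestamp > clock.now():
            clock.advance_to(event.timestamp)
        if event.direction != "inbound":
            engine.pump()
            continue
        engine.pump()
        if event.kind == "audio":
            engine.handle_inbound(
                audio_duration=event.audio_duration, at=event.timestamp
            )
        else:
            engine.handle_inbound(text=event.body, at=event.timestamp)
    engine.pump()
    return engine
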