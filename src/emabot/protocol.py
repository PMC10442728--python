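"""Protocol definition: the 15-day schedule, timing constants and scripted prompts.

The protocol alternates two interaction modes over 14 scorable days after an
onboarding day ("day 0"): on odd days the bot asks two broad audio questions
about daily life and aims to collect at least one minute of recorded audio;
on even days it administers a 13-item day-framed short mood questionnaire
answered with 0/1/2. All timing is time-contingent: a fixed first-prompt
time, fixed reminder intervals, and fixed next-morning deadlines.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

NAME_PLACEHOLDER = "[participant]"
_PLACEHOLDER_RE = re.compile(r"\[participant\]")
_LEFTOVER_RE = re.compile(r"\[[a-z_]+\]")

DEFAULT_CLOSURE_WORDS = frozenset(
    {"ok", "okay", "see you", "bye", "thank you", "thanks", "thx"}
)


class ConfigurationError(ValueError):
    """A protocol configuration violates one of its invariants."""


class TemplateError(ValueError):
    """A prompt template failed to render (unresolved placeholder)."""


class DayMode(str, enum.Enum):
    INTRODUCTION = "INTRODUCTION"
    AUDIO_QUESTIONS = "AUDIO_QUESTIONS"
    QUESTIONNAIRE = "QUESTIONNAIRE"
    # Reserved: the source protocol lists standalone mood-rating interactions
    # but never schedules them on named days; the mode exists, unscheduled.
    MOOD_RATING = "MOOD_RATING"


class Expects(str, enum.Enum):
    """What kind of reply a prompt slot is waiting for."""

    ANY = "any"          # availability/opening: any non-snooze reply advances
    AUDIO = "audio"
    NUMERIC = "numeric"  # 0/1/2 questionnaire item
    YESNO = "yesno"
    NONE = "none"        # closing statements: no reply required


class PromptTemplate(BaseModel):
    """One scripted outbound message, optionally branching on a yes/no reply."""

    model_config = ConfigDict(frozen=True)

    text: str
    expects: Expects = Expects.NONE
    # For yes/no gates: follow-on prompt text per arm (both expect audio).
    branch_yes: Optional[str] = None
    branch_no: Optional[str] = None

    def render(self, participant_name: str) -> str:
        return render_prompt(self.text, participant_name)


def render_prompt(template: str, participant_name: str) -> str:
    """Substitute the participant-name placeholder, preserving emoji tokens.

    Raises :class:`TemplateError` if a bracketed placeholder other than the
    name token survives rendering. Emoji are carried as ``*name* emoji``
    tokens in the script text and pass through verbatim.
    """
    rendered = _PLACEHOLDER_RE.sub(participant_name, template)
    leftover = _LEFTOVER_RE.search(rendered)
    if leftover:
        raise TemplateError(f"unresolved placeholder {leftover.group(0)!r}")
    return rendered


class ProtocolConfig(BaseModel):
    """Timing constants and vocabulary of the daily-cycle protocol.

    Defaults encode the deployed study protocol: first prompt 13:30,
    reminders every 3 h, snoozing allowed until 03:00 the next day, the
    response window closing at 06:00 and the expiry notice at 10:00 the
    next day, with a 60 s daily audio target over 15 days (day 0 + 14).
    """

    model_config = ConfigDict(frozen=True)

    first_prompt_time: dt.time = dt.time(13, 30)
    reminder_interval: dt.timedelta = dt.timedelta(hours=3)
    snooze_limit_time: dt.time = dt.time(3, 0)       # next day
    response_window_end: dt.time = dt.time(6, 0)     # next day
    expiry_notice_time: dt.time = dt.time(10, 0)     # next day
    audio_target: float = 60.0                       # seconds
    n_days: int = 15                                 # day 0 + 14 scorable
    closure_words: frozenset[str] = DEFAULT_CLOSURE_WORDS
    emoji_closure: bool = True
    max_followups: int = 2
    # Outbound typing delay: clamp(base + rate * len(text), base, cap).
    typing_base_s: float = 0.5
    typing_rate_s_per_char: float = 0.05
    typing_cap_s: float = 6.0
    utcoffset_hours: float = -3.0                    # study-site wall clock
    correction_keywords: frozenset[str] = frozenset({"correct", "fix"})

    @field_validator("n_days")
    @classmethod
    def _n_days_min(cls, v: int) -> int:
        if v < 2:
            raise ValueError("n_days must be >= 2 (day 0 plus at least one scorable day)")
        return v

    @field_validator("audio_target")
    @classmethod
    def _audio_target_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("audio_target must be > 0")
        return v

    @field_validator("reminder_interval")
    @classmethod
    def _interval_pos(cls, v: dt.timedelta) -> dt.timedelta:
        if v <= dt.timedelta(0):
            raise ValueError("reminder_interval must be > 0")
        return v

    @model_validator(mode="after")
    def _ordering(self) -> "ProtocolConfig":
        if not (self.snooze_limit_time < self.response_window_end < self.expiry_notice_time):
            raise ValueError(
                "next-day times must satisfy snooze_limit_time < "
                "response_window_end < expiry_notice_time"
            )
        return self

    @property
    def tzinfo(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utcoffset_hours))

    def typing_delay(self, text_length: int) -> float:
        """Outbound delay in seconds, proportional to message length.

        The bot paces its replies to read like typed conversation:
        ``base + rate * length`` clamped to ``[base, cap]``.
        """
        if text_length < 0:
            raise ValueError("text length must be >= 0")
        raw = self.typing_base_s + self.typing_rate_s_per_char * text_length
        return min(max(raw, self.typing_base_s), self.typing_cap_s)


class DayPlan(BaseModel):
    model_config = ConfigDict(frozen=True)

    day_index: int = Field(ge=0)
    mode: DayMode
    prompts: tuple[PromptTemplate, ...] = ()


class ProtocolSchedule(BaseModel):
    model_config = ConfigDict(frozen=True)

    days: tuple[DayPlan, ...]

    def day(self, index: int) -> DayPlan:
        return self.days[index]

    def days_with_mode(self, mode: DayMode) -> list[int]:
        return [d.day_index for d in self.days if d.mode == mode]


# --- default scripts (English rendering of the deployed Portuguese scripts) ---

OPENING_TEXT = (
    f"Hi {NAME_PLACEHOLDER}! Are you available to answer today's questions? "
    "If you prefer, tell me a later time today and I will come back then."
)

CLOSING_TEXT = f"That's all for today. Thank you, {NAME_PLACEHOLDER}!"

FOLLOWUP_1_TEXT = (
    f"Thank you for sending this audio! Tell us a little bit more about it, {NAME_PLACEHOLDER}!"
)
FOLLOWUP_2_TEXT = (
    "It would be very important if you could tell us a little more, okay? "
    "You can choose: type 'yes' or 'no' before sending the audio recording."
)

DAY0_SCRIPT: tuple[str, ...] = (
    f"Hi {NAME_PLACEHOLDER}! Thanks for your message — this is the study chatbot. "
    "Over the next 14 days I will send you questions every day, starting at 1:30 PM.",
    "On some days I will ask you to answer with audio recordings about your daily "
    "life; on the other days I will ask 13 short questions you answer by typing "
    "0, 1, or 2. You can also send me audio recordings on your own at any time.",
    "Two important things: your audio recordings are not listened to immediately, "
    "and I am not a channel for seeking help. If you need support, please use the "
    "contact numbers the research team gave you.",
    "If a question arrives at a bad time, you can ask me to come back later "
    "(until 3 AM). Each day's questions stay open until 6 AM the next morning. "
    "See you tomorrow at 1:30 PM!",
)

# Two audio questions per audio day. Day 3's first question branches on a
# yes/no reply before the audio request.
AUDIO_DAY_QUESTIONS: dict[int, tuple[PromptTemplate, PromptTemplate]] = {
    1: (
        PromptTemplate(text="Can you introduce yourself?", expects=Expects.AUDIO),
        PromptTemplate(
            text="What have you done today? Is your day going according to your usual routine?",
            expects=Expects.AUDIO,
        ),
    ),
    3: (
        PromptTemplate(
            text="Are you at home?",
            expects=Expects.YESNO,
            branch_yes="What are you doing? Is someone else around?",
            branch_no="Who do you live with? Do you get along with the people you live with?",
        ),
        PromptTemplate(
            text="Can you tell me more about your house? Do you like living there?",
            expects=Expects.AUDIO,
        ),
    ),
    5: (
        PromptTemplate(
            text=(
                f"Did you go outside today at all, {NAME_PLACEHOLDER}? Do you spend "
                "more time inside, or do you sometimes go out? When you're out, "
                "what do you normally do?"
            ),
            expects=Expects.AUDIO,
        ),
        PromptTemplate(
            text="And how's your neighborhood? Are there nice things around?",
            expects=Expects.AUDIO,
        ),
    ),
    7: (
        PromptTemplate(
            text=(
                "Today I want to know about your favorite story. What is it? You can "
                "choose a movie, a series, a book... whatever you want!"
            ),
            expects=Expects.AUDIO,
        ),
        PromptTemplate(
            text=f"And why is this your favorite story, {NAME_PLACEHOLDER}?",
            expects=Expects.AUDIO,
        ),
    ),
    9: (
        PromptTemplate(
            text=(
                f"Do you use your mobile phone a lot, {NAME_PLACEHOLDER}? What are "
                "your favorite things to do on the mobile phone?"
            ),
            expects=Expects.AUDIO,
        ),
        PromptTemplate(
            text=(
                "And how much time do you think you spend on the internet each day? "
                "Do you use the internet mostly during the day or at night? Why?"
            ),
            expects=Expects.AUDIO,
        ),
    ),
    11: (
        PromptTemplate(
            text=(
                "Not counting the audio recordings you send here *grinning face with "
                "sweat* emoji, who do you talk to about things that happen in your "
                "life? How's your relationship with this person?"
            ),
            expects=Expects.AUDIO,
        ),
        PromptTemplate(
            text="And why do you trust this person?", expects=Expects.AUDIO
        ),
    ),
    13: (
        PromptTemplate(
            text=(
                f"It's been almost 2 weeks since we started talking, {NAME_PLACEHOLDER}! "
                "How did you feel about answering these questions?"
            ),
            expects=Expects.AUDIO,
        ),
        PromptTemplate(
            text="And how have you been in these last 2 weeks? Has anything different happened?",
            expects=Expects.AUDIO,
        ),
    ),
}

AUDIO_DAYS: tuple[int, ...] = tuple(sorted(AUDIO_DAY_QUESTIONS))


def build_schedule(config: ProtocolConfig) -> ProtocolSchedule:
    """Build the day-by-day plan from a validated configuration.

    Day 0 is the onboarding introduction; audio-question days sit on the odd
    indices 1..13 with their scripted question pairs; questionnaire days fill
    the even indices 2..14. Deterministic: equal configs give equal schedules.
    """
    try:
        ProtocolConfig.model_validate(config.model_dump())
    except Exception as exc:  # re-raise under the protocol's error type
        raise ConfigurationError(str(exc)) from exc

    days: list[DayPlan] = [
        DayPlan(
            day_index=0,
            mode=DayMode.INTRODUCTION,
            prompts=tuple(PromptTemplate(text=t) for t in DAY0_SCRIPT),
        )
    ]
    for index in range(1, config.n_days):
        if index in AUDIO_DAY_QUESTIONS:
            days.append(
                DayPlan(
                    day_index=index,
                    mode=DayMode.AUDIO_QUESTIONS,
                    prompts=AUDIO_DAY_QUESTIONS[index],
                )
            )
        else:
            # Items are administered by the questionnaire module; the plan
            # carries the mode only.
            days.append(DayPlan(day_index=index, mode=DayMode.QUESTIONNAIRE))
    return ProtocolSchedule(days=tuple(days))


# --- config file loading ---------------------------------------------------

_DURATION_FIELDS = {"reminder_interval"}
_TIME_FIELDS = {
    "first_prompt_time",
    "snooze_limit_time",
    "response_window_end",
    "expiry_notice_time",
}


def load_config(path: str | Path) -> ProtocolConfig:
    """Load and validate a protocol configuration from a YAML/JSON document.

    Times are "HH:MM" strings, durations are in hours, closure words a list.
    Unknown keys are rejected so typos surface at load time.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config document must be a mapping")
    data: dict = {}
    known = set(ProtocolConfig.model_fields)
    for key, value in raw.items():
        if key == "days":
            continue  # optional day-script override block, not yet customizable
        if key not in known:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        if key in _TIME_FIELDS and isinstance(value, str):
            hh, mm = value.split(":")
            value = dt.time(int(hh), int(mm))
        elif key in _DURATION_FIELDS and isinstance(value, (int, float)):
            value = dt.timedelta(hours=value)
        elif key in ("closure_words", "correction_keywords") and isinstance(value, list):
            value = frozenset(str(w).lower() for w in value)
        data[key] = value
    try:
        return ProtocolConfig.model_validate(data)
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc
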