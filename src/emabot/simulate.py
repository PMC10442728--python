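"""Synthetic participant behavior for end-to-end protocol runs.

The simulator drives the *real* engine and scheduler on a virtual clock: a
respondent profile specifies onboarding acceptance, day-0 dropout, per-day
response and snooze propensities, response-latency and audio-duration
distributions (lognormal), and a latent daily mood following an AR(1)
process mapped to 0/1/2 questionnaire answers through ordered thresholds.
Every behavioral draw comes from a per-participant stream seeded by
(seed, participant id), so a cohort is byte-reproducible and growing the
cohort never perturbs existing participants' trajectories.

Default parameter values emulate the engagement pattern of the first
implementation wave reported for this protocol: ~81% acceptance, ~1%
initial attrition, ~91% compliance, and roughly a minute of audio per audio
day. They are study conditions, not tuning knobs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import ChatEngine, DailyCycle
from .protocol import Expects, ProtocolConfig, ProtocolSchedule, build_schedule
from .scheduler import (
    CycleStatus,
    TERMINAL_STATUSES,
    VirtualClock,
    expiry_notice_at,
    window_open,
)
from .transport import Event, MockTransport


class LognormalSpec(BaseModel):
    """Lognormal distribution by (mu, sigma) of the underlying normal.

    ``sigma=0`` degenerates to the constant ``exp(mu)``, handy for scripted
    traces (e.g. every recording exactly 20 s).
    """

    model_config = ConfigDict(frozen=True)

    mu: float
    sigma: float = Field(ge=0)

    def draw(self, rng: np.random.Generator) -> float:
        if self.sigma == 0:
            return float(np.exp(self.mu))
        return float(rng.lognormal(self.mu, self.sigma))

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2))


class MoodProcess(BaseModel):
    """Latent daily mood: AR(1) with mean mu, autocorrelation rho.

    The innovation SD defaults to sqrt(1 - rho^2) so the stationary variance
    is 1; item answers arise by adding independent item noise and cutting at
    two ordered thresholds (0 below the first, 2 above the second).
    """

    model_config = ConfigDict(frozen=True)

    mu: float = 0.0
    rho: float = 0.6
    sigma: Optional[float] = None  # innovation SD; default unit stationary var
    item_sd: float = Field(default=0.5, gt=0)
    thresholds: tuple[float, float] = (-0.4, 0.9)

    @model_validator(mode="after")
    def _check(self) -> "MoodProcess":
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly increasing")
        return self

    @property
    def innovation_sd(self) -> float:
        if self.sigma is not None:
            return self.sigma
        return float(np.sqrt(1.0 - self.rho**2))

    def sample_path(self, n_days: int, rng: np.random.Generator) -> np.ndarray:
        sd0 = self.innovation_sd / np.sqrt(1.0 - self.rho**2)
        path = np.empty(n_days)
        path[0] = self.mu + sd0 * rng.standard_normal()
        for d in range(1, n_days):
            path[d] = (
                self.mu
                + self.rho * (path[d - 1] - self.mu)
                + self.innovation_sd * rng.standard_normal()
            )
        return path

    def answer(self, mood: float, rng: np.random.Generator) -> int:
        z = mood + self.item_sd * rng.standard_normal()
        if z < self.thresholds[0]:
            return 0
        if z < self.thresholds[1]:
            return 1
        return 2


class RespondentProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    p_accept: float = Field(default=0.807, ge=0, le=1)
    p_dropout_after_day0: float = Field(default=0.009, ge=0, le=1)
    p_engage: float = Field(default=0.94, ge=0, le=1)
    p_snooze: float = Field(default=0.25, ge=0, le=1)
    p_resnooze: float = Field(default=0.76, ge=0, le=1)
    p_return_after_snooze: float = Field(default=0.54, ge=0, le=1)
    p_followup_yes: float = Field(default=0.5, ge=0, le=1)
    p_closure_message: float = Field(default=0.6, ge=0, le=1)
    p_unprompted_audio: float = Field(default=0.03, ge=0, le=1)
    # First response of the day vs. replies inside a running dialog (minutes).
    latency_dist: LognormalSpec = LognormalSpec(mu=2.08, sigma=1.0)
    reply_latency_dist: LognormalSpec = LognormalSpec(mu=-0.29, sigma=0.6)
    snooze_offset_dist: LognormalSpec = LognormalSpec(mu=0.92, sigma=0.5)  # hours
    audio_dist: LognormalSpec = LognormalSpec(mu=3.09, sigma=0.55)  # seconds
    mood: MoodProcess = MoodProcess()


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    digest = hashlib.sha256(participant_id.encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class Respondent:
    """Behavioral state of one simulated participant."""

    profile: RespondentProfile
    rng: np.random.Generator
    moods: np.ndarray

    def first_latency(self) -> dt.timedelta:
        minutes = min(self.profile.latency_dist.draw(self.rng), 60.0)
        return dt.timedelta(minutes=minutes)

    def reply_latency(self) -> dt.timedelta:
        minutes = min(self.profile.reply_latency_dist.draw(self.rng), 15.0)
        return dt.timedelta(minutes=minutes)

    def snooze_offset(self) -> dt.timedelta:
        hours = min(self.profile.snooze_offset_dist.draw(self.rng), 12.0)
        return dt.timedelta(hours=hours)

    def audio_seconds(self) -> float:
        return max(1.0, self.profile.audio_dist.draw(self.rng))

    def respond(
        self, cycle: DailyCycle, now: dt.datetime
    ) -> tuple[Optional[str], Optional[float]]:
        """Produce the inbound reply for the slot the dialog is waiting on."""
        slot = cycle.slot
        if slot is None:
            return None, None
        if slot.expects is Expects.ANY:
            return "yes", None
        if slot.expects is Expects.AUDIO:
            return None, round(self.audio_seconds(), 1)
        if slot.expects is Expects.NUMERIC:
            assert cycle.smfq is not None
            index = cycle.smfq.next_unanswered
            assert index is not None
            value = self.profile.mood.answer(
                float(self.moods[cycle.day_index]), self.rng
            )
            return str(value), None
        if slot.expects is Expects.YESNO:
            if slot.tag == "fu2gate":
                yes = self.rng.random() < self.profile.p_followup_yes
            else:
                yes = self.rng.random() < 0.5
            return ("yes" if yes else "no"), None
        return "ok", None


@dataclass
class SimulatedParticipant:
    participant_id: str
    events: list[Event]
    engine: Optional[ChatEngine] = None


@dataclass
class CohortResult:
    participants: list[SimulatedParticipant]
    seed: int

    @property
    def eligible_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    @property
    def all_events(self) -> list[Event]:
        out: list[Event] = []
        for p in self.participants:
            out.extend(p.events)
        return out

    def write_logs(self, directory: str | Path) -> list[Path]:
        from .transport import write_log

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for p in self.participants:
            path = directory / f"{p.participant_id}.jsonl"
            write_log(path, p.events)
            paths.append(path)
        return paths


def simulate_participant(
    participant_id: str,
    name: str,
    profile: RespondentProfile,
    schedule: ProtocolSchedule,
    config: ProtocolConfig,
    seed: int,
    start_date: dt.date,
    keep_engine: bool = True,
) -> SimulatedParticipant:
    """Run one simulated participant through the full protocol."""
    rng = _participant_rng(seed, participant_id)
    tz = config.tzinfo
    respondent = Respondent(
        profile=profile,
        rng=rng,
        moods=profile.mood.sample_path(config.n_days, rng),
    )

    if rng.random() >= profile.p_accept:
        return SimulatedParticipant(participant_id, [], None)

    onboard_at = dt.datetime.combine(start_date, dt.time(10, 0), tzinfo=tz) + (
        dt.timedelta(minutes=float(rng.uniform(0, 150)))
    )
    clock = VirtualClock(current=onboard_at)
    engine = ChatEngine(
        config, schedule, MockTransport(), clock, participant_id, name
    )
    engine.handle_inbound(text="hello")

    dropout = rng.random() < profile.p_dropout_after_day0

    for day in range(1, config.n_days):
        cycle = engine.session.cycles[day]
        open_at = window_open(cycle.clock.cycle_date, config)
        clock.advance_to(open_at)
        engine.pump()
        if dropout:
            continue

        responds: bool
        if rng.random() < profile.p_snooze:
            responds = _snooze_phase(engine, cycle, respondent, clock)
        else:
            responds = rng.random() < profile.p_engage
        if responds:
            _run_dialog(engine, cycle, respondent, clock)
            if cycle.clock.status is CycleStatus.COMPLETED:
                if rng.random() < profile.p_closure_message:
                    _reply(engine, clock, respondent.reply_latency(), text="thank you")
                if rng.random() < profile.p_unprompted_audio:
                    _reply(
                        engine,
                        clock,
                        dt.timedelta(minutes=float(rng.uniform(10, 120))),
                        audio=respondent.audio_seconds(),
                    )

    end = dt.datetime.combine(
        start_date + dt.timedelta(days=config.n_days), dt.time(11, 0), tzinfo=tz
    )
    clock.advance_to(end)
    engine.pump()
    return SimulatedParticipant(
        participant_id, engine.events, engine if keep_engine else None
    )


def _reply(
    engine: ChatEngine,
    clock: VirtualClock,
    latency: dt.timedelta,
    text: Optional[str] = None,
    audio: Optional[float] = None,
) -> None:
    base = engine.events[-1].timestamp if engine.events else clock.now()
    at = max(base, clock.now()) + latency
    clock.advance_to(at)
    engine.pump()
    engine.handle_inbound(text=text, audio_duration=audio, at=at)


def _snooze_phase(
    engine: ChatEngine,
    cycle: DailyCycle,
    respondent: Respondent,
    clock: VirtualClock,
) -> bool:
    """Snooze the first prompt; possibly re-snooze; return whether the
    participant comes back to complete the dialog."""
    profile = respondent.profile
    rng = respondent.rng
    while True:
        latency = respondent.first_latency()
        base = engine.events[-1].timestamp if engine.events else clock.now()
        reply_at = max(base, clock.now()) + latency
        target = reply_at + respondent.snooze_offset()
        clock.advance_to(reply_at)
        engine.pump()
        engine.handle_inbound(
            text=f"snooze {target.strftime('%H:%M')}", at=reply_at
        )
        if cycle.clock.status is not CycleStatus.SNOOZED:
            return False  # request rejected (past the limit); goes silent
        assert cycle.clock.snoozed_until is not None
        clock.advance_to(cycle.clock.snoozed_until)
        engine.pump()  # snooze prompt fires
        if rng.random() < profile.p_return_after_snooze:
            return True
        if rng.random() >= profile.p_resnooze:
            return False


def _run_dialog(
    engine: ChatEngine,
    cycle: DailyCycle,
    respondent: Respondent,
    clock: VirtualClock,
) -> None:
    first = True
    while cycle.clock.status not in TERMINAL_STATUSES:
        if cycle.slot is None:
            break
        latency = respondent.first_latency() if first else respondent.reply_latency()
        first = False
        text, audio = respondent.respond(cycle, clock.now())
        _reply(engine, clock, latency, text=text, audio=audio)
        if clock.now() >= expiry_notice_at(cycle.clock.cycle_date, engine.config):
            break  # safety: never loop past the cycle's hard end


def simulate_cohort(
    n: int,
    profile: RespondentProfile,
    schedule: Optional[ProtocolSchedule] = None,
    seed: int = 0,
    config: Optional[ProtocolConfig] = None,
    start_date: dt.date = dt.date(2021, 3, 1),
    keep_engines: bool = False,
) -> CohortResult:
    """Simulate ``n`` eligible participants; non-accepters leave empty logs.

    Identical (n, profile, seed) yield byte-identical logs, and each
    participant's trajectory depends only on (seed, participant id).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or ProtocolConfig()
    schedule = schedule or build_schedule(config)
    participants = []
    for i in range(n):
        pid = f"p{i:05d}"
        participants.append(
            simulate_participant(
                pid, f"Sim{i:05d}", profile, schedule, config, seed,
                start_date, keep_engine=keep_engines,
            )
        )
    return CohortResult(participants=participants, seed=seed)


def load_profile(path: str | Path) -> RespondentProfile:
    """Load a respondent profile from a YAML/JSON scenario file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RespondentProfile.model_validate(raw)


def synthetic_wave_log(
    n_eligible: int,
    n_onboarded: int,
    n_day0_only: int,
    engaged_day_counts: Sequence[int],
    start_date: dt.date = dt.date(2021, 3, 1),
) -> tuple[list[str], list[Event]]:
    """Synthetic minimal cohort log reconstructed from summary counts.

    Builds the smallest event log consistent with printed wave-level counts
    (eligible, onboarded, day-0-only, per-participant engaged-day counts):
    one day-0 inbound for every onboarded participant and one inbound text
    per engaged day. Useful for arithmetic worked examples where only the
    published counts, not raw behavior, are available.
    """
    if n_day0_only + len(engaged_day_counts) != n_onboarded:
        raise ValueError(
            "engaged_day_counts must cover exactly the continuing participants"
        )
    if n_onboarded > n_eligible:
        raise ValueError("onboarded cannot exceed eligible")
    tz = dt.timezone(dt.timedelta(hours=-3))
    eligible = [f"w{i:04d}" for i in range(n_eligible)]
    events: list[Event] = []

    def day_ts(day: int) -> dt.datetime:
        return dt.datetime.combine(
            start_date + dt.timedelta(days=day), dt.time(14, 0), tzinfo=tz
        )

    for i in range(n_onboarded):
        pid = eligible[i]
        events.append(
            Event(
                timestamp=day_ts(0), participant_id=pid, direction="inbound",
                kind="text", body="hello", day_index=0, excluded=True,
            )
        )
    for j, k in enumerate(engaged_day_counts):
        if not 1 <= k <= 14:
            raise ValueError("engaged day counts must be in 1..14")
        pid = eligible[n_day0_only + j]
        for day in range(1, k + 1):
            events.append(
                Event(
                    timestamp=day_ts(day), participant_id=pid,
                    direction="inbound", kind="text", body="1", day_index=day,
                )
            )
    return eligible, events
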