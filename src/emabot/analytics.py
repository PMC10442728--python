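"""Cohort engagement indicators computed from event logs.

Three usability indicators summarize an implementation wave: acceptance
(the share of eligible participants who onboarded), initial attrition (the
share of onboarded participants who never interacted again after the
onboarding day), and compliance (the mean share of the 14 scorable days on
which a participant generated at least one data point). Descriptive audio
and snooze statistics round out the report.

A "data point" is any non-excluded inbound text or audio response; bare
closures/acknowledgments and snooze requests do not count. Onboarding-day
(day 0) events carry an excluded flag and never contribute. The compliance
denominator is fixed at 14: the protocol spans 15 days but day 0 is not
scorable, which is how the published rates are arithmetically defined
(e.g. a mean of 12.8 engaged days reported as 91.4%).
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .transport import Event

N_SCORABLE_DAYS = 14


def round1(value: float) -> float:
    """Round half-up to one decimal, matching how rates are reported."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _is_data_point(event: Event) -> bool:
    return (
        event.direction == "inbound"
        and event.kind in ("text", "audio")
        and not event.excluded
    )


def _by_participant(logs: Iterable[Event]) -> dict[str, list[Event]]:
    grouped: dict[str, list[Event]] = defaultdict(list)
    for event in logs:
        grouped[event.participant_id].append(event)
    return grouped


def onboarded_ids(logs: Iterable[Event]) -> set[str]:
    """Participants with a day-0 interaction (onboarding completed)."""
    return {e.participant_id for e in logs if e.day_index == 0}


def engaged_days(events: Sequence[Event]) -> set[int]:
    """Scorable days (1..14) on which this participant produced a data point."""
    return {
        e.day_index
        for e in events
        if _is_data_point(e) and e.day_index is not None and e.day_index > 0
    }


def continued_ids(logs: Iterable[Event]) -> set[str]:
    """Onboarded participants with any inbound interaction beyond day 0."""
    grouped = _by_participant(logs)
    out = set()
    for pid, events in grouped.items():
        if not any(e.day_index == 0 for e in events):
            continue
        if any(
            e.direction == "inbound" and e.day_index != 0 for e in events
        ):
            out.add(pid)
    return out


def compute_acceptance(
    eligible_ids: Sequence[str], logs: Iterable[Event]
) -> tuple[int, float]:
    """(count, percentage) of eligible participants who onboarded."""
    if not eligible_ids:
        raise ValueError("eligible_ids must be nonempty")
    eligible = set(eligible_ids)
    onboarded = onboarded_ids(logs)
    stray = onboarded - eligible
    if stray:
        warnings.warn(
            f"{len(stray)} onboarded participant(s) not in the eligible set",
            stacklevel=2,
        )
    count = len(onboarded & eligible)
    return count, round1(100.0 * count / len(eligible))


def compute_initial_attrition(logs: Iterable[Event]) -> tuple[int, float]:
    """(count, percentage over onboarded) who only ever interacted on day 0."""
    events = list(logs)
    onboarded = onboarded_ids(events)
    if not onboarded:
        return 0, 0.0
    dropped = onboarded - continued_ids(events)
    return len(dropped), round1(100.0 * len(dropped) / len(onboarded))


def compute_compliance(logs: Iterable[Event]) -> tuple[float, float, float]:
    """(mean engaged days, sd, percentage of 14) over continuing participants."""
    events = list(logs)
    grouped = _by_participant(events)
    continuing = continued_ids(events)
    if not continuing:
        return 0.0, 0.0, 0.0
    counts = np.array(
        [len(engaged_days(grouped[pid])) for pid in sorted(continuing)], dtype=float
    )
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return mean, sd, round1(100.0 * mean / N_SCORABLE_DAYS)


def compute_full_completion(logs: Iterable[Event]) -> tuple[int, float]:
    """(count, percentage over onboarded) engaging on every scorable day."""
    events = list(logs)
    grouped = _by_participant(events)
    onboarded = onboarded_ids(events)
    if not onboarded:
        return 0, 0.0
    full = sum(
        1 for pid in onboarded if len(engaged_days(grouped[pid])) == N_SCORABLE_DAYS
    )
    return full, round1(100.0 * full / len(onboarded))


@dataclass(frozen=True)
class AudioStats:
    mean_seconds_per_day: float   # over participant-days with >=1 audio event
    mean_total_minutes: float     # per continuing participant
    n_days_with_audio: int


def compute_audio_stats(logs: Iterable[Event]) -> AudioStats:
    """Daily and total audio volume; prompted and unprompted both count.

    Unprompted recordings have no cycle day, so they attribute to the
    calendar date they were sent. With no audio at all the means report as
    zero, with the day count making the emptiness explicit.
    """
    events = list(logs)
    per_day: dict[tuple[str, object], float] = defaultdict(float)
    per_participant: dict[str, float] = defaultdict(float)
    for e in events:
        if e.direction != "inbound" or e.kind != "audio" or e.excluded:
            continue
        day_key: object = e.day_index if e.day_index is not None else e.timestamp.date()
        per_day[(e.participant_id, day_key)] += e.audio_duration or 0.0
        per_participant[e.participant_id] += e.audio_duration or 0.0
    n_days = len(per_day)
    if n_days == 0:
        return AudioStats(0.0, 0.0, 0)
    mean_per_day = sum(per_day.values()) / n_days
    continuing = continued_ids(events) or set(per_participant)
    totals = [per_participant.get(pid, 0.0) for pid in sorted(continuing)]
    mean_total_min = (sum(totals) / len(totals)) / 60.0 if totals else 0.0
    return AudioStats(mean_per_day, mean_total_min, n_days)


def compute_snooze_stats(logs: Iterable[Event]) -> tuple[int, int]:
    """(snooze uses, cycles with a snooze that went on to complete)."""
    events = list(logs)
    uses = 0
    snoozed_cycles: set[tuple[str, Optional[int]]] = set()
    completed_cycles: set[tuple[str, Optional[int]]] = set()
    for e in events:
        if e.direction == "inbound" and e.kind == "snooze" and not e.excluded:
            uses += 1
            snoozed_cycles.add((e.participant_id, e.day_index))
        if e.kind == "state_transition" and e.body.endswith("->COMPLETED"):
            completed_cycles.add((e.participant_id, e.day_index))
    completed_after_snooze = len(snoozed_cycles & completed_cycles)
    return uses, completed_after_snooze


class EngagementReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_eligible: int
    n_onboarded: int
    acceptance_pct: float
    n_initial_attrition: int
    initial_attrition_pct: float
    mean_engaged_days: float
    sd_engaged_days: float
    compliance_pct: float
    n_full_completion: int
    full_completion_pct: float
    mean_audio_seconds_per_day: float
    mean_total_audio_minutes: float
    snooze_uses: int
    snooze_completed: int

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.model_dump(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def compute_report(
    eligible_ids: Sequence[str], logs: Iterable[Event]
) -> EngagementReport:
    events = list(logs)
    n_onboarded, acceptance_pct = compute_acceptance(eligible_ids, events)
    n_attrition, attrition_pct = compute_initial_attrition(events)
    mean_days, sd_days, compliance_pct = compute_compliance(events)
    n_full, full_pct = compute_full_completion(events)
    audio = compute_audio_stats(events)
    snooze_uses, snooze_completed = compute_snooze_stats(events)
    return EngagementReport(
        n_eligible=len(set(eligible_ids)),
        n_onboarded=n_onboarded,
        acceptance_pct=acceptance_pct,
        n_initial_attrition=n_attrition,
        initial_attrition_pct=attrition_pct,
        mean_engaged_days=mean_days,
        sd_engaged_days=sd_days,
        compliance_pct=compliance_pct,
        n_full_completion=n_full,
        full_completion_pct=full_pct,
        mean_audio_seconds_per_day=audio.mean_seconds_per_day,
        mean_total_audio_minutes=audio.mean_total_minutes,
        snooze_uses=snooze_uses,
        snooze_completed=snooze_completed,
    )


def per_participant_frame(
    eligible_ids: Sequence[str], logs: Iterable[Event]
) -> pd.DataFrame:
    """One row per eligible participant for CSV export."""
    events = list(logs)
    grouped = _by_participant(events)
    onboarded = onboarded_ids(events)
    continuing = continued_ids(events)
    rows = []
    for pid in sorted(set(eligible_ids) | set(grouped)):
        evts = grouped.get(pid, [])
        days = engaged_days(evts)
        audio_total = sum(
            e.audio_duration or 0.0
            for e in evts
            if e.direction == "inbound" and e.kind == "audio" and not e.excluded
        )
        rows.append(
            {
                "participant_id": pid,
                "onboarded": pid in onboarded,
                "continued": pid in continuing,
                "engaged_days": len(days),
                "full_completion": len(days) == N_SCORABLE_DAYS,
                "total_audio_seconds": audio_total,
                "snooze_uses": sum(
                    1
                    for e in evts
                    if e.direction == "inbound" and e.kind == "snooze" and not e.excluded
                ),
            }
        )
    return pd.DataFrame(rows)
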