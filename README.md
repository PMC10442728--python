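# emabot

A rule-based chatbot engine for **intensive longitudinal mood assessment**
(ecological momentary assessment, EMA) in adolescents, with a deterministic
virtual-clock scheduler, a participant behavior simulator, and an analytics
layer for the engagement indicators used to judge such deployments.

The engine re-implements, as a tested and messaging-platform-agnostic
library, a 15-day EMA protocol delivered over a chat app: after an
onboarding day ("day 0"), the bot alternates for 14 days between

* **audio-question days** (7 days): two scripted questions about daily life
  answered with voice recordings, with a target of at least 60 s of audio
  per day — if the answers fall short, up to two follow-up probes are sent,
  the second gated by a typed yes/no;
* **questionnaire days** (7 days): a 13-item Short Mood and Feelings
  Questionnaire (sMFQ) re-framed to the current day, answered by typing
  0/1/2 (0 = no, 1 = sometimes, 2 = yes), with an anchor reminder on every
  item, an answer-correction dialog, and the usual 0–26 sum score.

Prompting is time-contingent: first prompt at 13:30, reminders every 3 h
while unanswered, participant-requested snoozing until 03:00 the next day,
a response window closing at 06:00, and a single expiry notice at 10:00.
Reply understanding is deliberately rule-based (exact text matches after
normalization), including a closure-word rule so that "thank you" at the
end of a day is acknowledged rather than probed. Everything the engine does
is appended to a JSONL event log from which both the engine state and the
cohort analytics can be reconstructed exactly.

Who this is for: research groups running (or planning) chat-based EMA
studies who need a scriptable, auditable protocol engine they can test
end-to-end without a messaging platform, and a simulator to size and
validate their engagement analytics before touching real participants.

## Engagement indicators

For a cohort of eligible participants the analytics layer computes, from
event logs alone:

* **acceptance** — share of eligible participants who onboarded:
  `100 · n_onboarded / n_eligible`;
* **initial attrition** — share of onboarded participants whose only
  interaction day is day 0;
* **compliance** — mean share of the 14 scorable days with ≥1 data point
  (a non-excluded inbound text or audio response): `100 · mean(engaged
  days) / 14`;
* full completion (all 14 scorable days engaged), audio volume per day and
  per participant, and snooze uses vs. snoozed cycles completed.

## Worked example

Simulate a 25-participant cohort with the default respondent profile and
report the indicators:

```bash
emabot simulate --out demo/logs --n 25 --seed 5
emabot report demo/logs --out demo/report
```

which prints:

```
                  n_eligible: 25
                 n_onboarded: 20
              acceptance_pct: 80.0
         n_initial_attrition: 0
       initial_attrition_pct: 0.0
           mean_engaged_days: 12.9
             sd_engaged_days: 0.9119095061289914
              compliance_pct: 92.1
           n_full_completion: 6
         full_completion_pct: 30.0
  mean_audio_seconds_per_day: 68.96772326618719
    mean_total_audio_minutes: 8.04623438105517
                 snooze_uses: 107
            snooze_completed: 63
```

Reading this: 20 of 25 eligible simulated adolescents onboarded (80.0%
acceptance, matching the profile's `p_accept = 0.807` up to sampling
noise); none dropped out after day 0; continuing participants engaged on
12.9 of 14 days (92.1% compliance); they sent about 69 s of audio per
audio-active day and 8.0 minutes in total; the snooze function was used 107
times and 63 snoozed day-cycles were still completed. A `report.json`,
per-participant `participants.csv` and a reproducibility `manifest.json`
are written to `demo/report/`.

The same machinery is available as a library (`emabot.simulate_cohort`,
`emabot.compute_report`, `emabot.ChatEngine`, `emabot.replay`), and
`emabot chat` walks a human through the protocol in the terminal on an
accelerated clock (`audio 45` stands in for a 45 s recording, `next` jumps
to the next scheduled prompt).

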