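# Methods

## The protocol as a state machine

One participant's study is a `Session`: an onboarding day plus 14 scorable
daily cycles. Each cycle is a small state machine

```
PENDING → PROMPTED → {SNOOZED, IN_PROGRESS} → {COMPLETED, EXPIRED}
```

driven by two inputs only: scheduled timer fires and inbound messages. The
scheduler (`emabot.scheduler`) owns the timers; given a cycle state and a
clock reading it returns the single next action — first prompt at the
day's opening time, a reminder one `reminder_interval` after the last
prompt, the snoozed re-prompt, or the expiry notice — and the engine
(`emabot.engine`) executes it. Time is injected: the engine never calls a
wall clock, so tests and the simulator run the full 15 days in
milliseconds, and replaying a log reproduces the run bit for bit.

Timing constants (defaults; all configurable in `ProtocolConfig`):

| parameter | default | meaning |
|---|---|---|
| `first_prompt_time` | 13:30 | local wall time each cycle opens |
| `reminder_interval` | 3 h | spacing of reminders while unanswered |
| `snooze_limit_time` | 03:00 (+1 d) | latest allowed snooze target |
| `response_window_end` | 06:00 (+1 d) | window close (half-open) |
| `expiry_notice_time` | 10:00 (+1 d) | the one message allowed after close |
| `audio_target` | 60 s | daily audio goal on audio-question days |
| `n_days` | 15 | day 0 + 14 scorable days |

Design choices where the protocol description was genuinely open:

* **Half-open response window** `[13:30, 06:00)`. "Until 6 AM" does not
  state inclusivity; half-open intervals avoid double-counting boundaries.
* **Questionnaire days on even indices 2–14.** The audio-question scripts
  are pinned to days 1, 3, …, 13; placing the questionnaire on the
  remaining days is the only deterministic arrangement consistent with
  "the 7 days without audio prompts".
* **Snooze replaces the reminder train** while active, and requests beyond
  the 03:00 limit are clamped to it rather than rejected (the limit reads
  as a cap). A request whose clamped target is already past — i.e. made
  after 03:00 — is rejected with a re-prompt. A reminder that falls
  between 03:00 and 06:00 after a late snooze is still sent: the window is
  open and nothing says otherwise; flagged as an interpretation.
* **Grace continuation.** A dialog already in progress at 06:00 may finish
  (until the 10:00 notice); cutting a questionnaire off mid-form would
  discard participant effort. Engagement attribution still uses the
  cycle's day.
* **Audio-probe boundary.** The daily goal is *at least* 60 s. The engine
  probes while the running total has not *strictly exceeded* the target:
  platforms report whole seconds, so a total landing exactly on the
  boundary is treated as not safely past it and draws one more probe. For
  continuous real durations the boundary case has probability zero, so
  this choice is observationally equivalent to the strict reading; it
  matters only for scripted constant-duration traces.
* **Closure matching is exact, not fuzzy** (lowercase, trim, strip
  terminal punctuation; default set: ok, okay, see you, bye, thank you,
  thanks, thx). Emoji-only replies also close, switchable via
  `emoji_closure` — the published fix names only words, but the original
  problem included bare emoji.
* **Text where audio is expected** gets one gentle re-prompt, then is
  accepted as a free-text data point contributing 0 s of audio: never
  discard what a participant offered.
* **Unprompted audio is acknowledged but does not count toward the 60 s
  target**, which is defined over the answers to the day's questions.
* **Day-0 events are flagged `excluded`, not dropped** — auditability over
  minimalism; the analytics ignore them.
* A standalone mood-rating interaction mode exists in the enum but is left
  unscheduled: the source protocol names it without pinning it to days, so
  the default schedule does not guess.

## Questionnaire administration

The 13 day-framed items are data, not code (`SmfqForm`): deployments
substitute licensed instrument text. Every item prompt carries the anchor
reminder `(0=no, 1=sometimes, 2=yes)`; invalid replies re-prompt without
consuming the item; a correction keyword ("correct"/"fix") opens a
which-item → new-value sub-dialog, usable until the cycle closes, and
corrections overwrite the answer while keeping an audit trail. The score
is the plain sum, 0–26, defined only for complete responses.

## Event log

One JSON object per line, UTF-8, ISO-8601 timestamps with zone offset:
direction (`inbound`/`outbound`/`system`), kind (`text`, `audio`,
`snooze`, `acknowledgment`, `state_transition`, `expiry_notice`), body,
audio duration (audio only, strictly positive), day index (`null` for
unprompted interactions) and the day-0 `excluded` flag. Audio is carried
as (descriptor, duration) only — the engine's logic depends on duration
alone, and keeping media bytes out of the core is privacy by minimization.
The log is the analytics substrate and the persistence: `emabot.replay`
re-runs the inbound half through a fresh engine and regenerates the
outbound half and the state machine exactly.

## Analytics definitions

* A **data point** is a non-excluded inbound `text` or `audio` event;
  closures/acknowledgments and snooze requests are not data points.
* **Compliance** uses a fixed denominator of 14. The indicator is usually
  described "over the 15 days", but the published arithmetic (a mean of
  12.8 engaged days reported as 91.4%) fixes the denominator at the 14
  scorable days; we follow the arithmetic and document the discrepancy.
* **Snooze completions** are attributed per cycle (a cycle containing ≥1
  snooze that reaches COMPLETED), not per snooze event — the published
  counts are ambiguous between the two; flagged as an interpretation.
* Percentages are rounded half-up to one decimal, matching the reporting
  convention of the field.

## The respondent simulator

`simulate_cohort` drives the real engine — not a mock of it — with
behavior drawn per participant from a `RespondentProfile`. Each
participant's stream is seeded by (seed, participant id), so cohorts are
byte-reproducible and growing a cohort never perturbs existing
trajectories.

Per day, a respondent (after Bernoulli onboarding `p_accept` and a one-off
day-0 dropout `p_dropout_after_day0`): snoozes the first prompt with
probability `p_snooze` (snooze target = reply time + lognormal offset,
median ≈ 2.5 h); a snoozed day completes with probability
`p_return_after_snooze`, else re-snoozes with probability `p_resnooze`;
a non-snoozed day is answered with probability `p_engage`. Latencies are
lognormal (first response median ≈ 8 min, within-dialog replies median
≈ 45 s); audio answers are lognormal (median ≈ 22 s, mean ≈ 26 s — the
probe logic then yields roughly a minute per audio day); the second
follow-up's gate is answered yes with `p_followup_yes`.

Questionnaire answers come from a latent daily mood: an AR(1) process
`m_d − μ = ρ(m_{d−1} − μ) + ε_d` with ρ = 0.6 and unit stationary
variance; each item adds independent N(0, 0.5²) noise and cuts at ordered
thresholds (−0.4, 0.9) — an ordinal-probit-style mapping, the simplest
model giving realistic 0/1/2 marginals (≈ 36/43/21%). The thresholds and
item noise were set by a design calculation so the daily latent dominates:
pooled lag-1 autocorrelation of the 13-item totals is ≈ 0.56, i.e. the
totals actually inherit the AR(1) structure. (Heavily floor-skewed
thresholds would attenuate the autocorrelation to ≈ 0.47.) Note the
protocol administers the questionnaire every second day, so totals
observed in a protocol run are one AR(1) step *squared* apart; the
autocorrelation property is therefore tested on the generator's daily
totals directly.

Default engagement probabilities emulate the first implementation wave of
the source study: `p_accept = 0.807`, `p_dropout_after_day0 = 0.009`,
`p_engage = 0.94`, `p_snooze = 0.25`, `p_return_after_snooze = 0.54`,
`p_resnooze = 0.76`. The last three were derived analytically from the
published snooze bookkeeping (uses per snoozed cycle = 1/(1 − (1 − r)q),
completion per snoozed cycle = r/(1 − (1 − r)q)) so that a simulated wave
reproduces ≈ 91% compliance, ≈ 5 snooze uses per participant and a
uses-to-completions ratio of ≈ 1.8.

What the simulator deliberately does **not** emulate: real data are
overdispersed — participants differ in their engagement propensity, so
engaged-day counts have SD ≈ 3.5 and a large all-14-days mass, whereas
per-day-independent Bernoulli engagement concentrates counts (SD ≈ 1) and
yields fewer full completers. Passing tests therefore validate the engine,
the log schema, and the estimators' consistency — not distributional
realism of engagement heterogeneity, audio content, or free-text behavior
(descriptors only, no content is generated). The published wave-level
rates that depend on the engagement *distribution* (full completion, SDs)
are reproduced as arithmetic worked examples from reconstructed count
fixtures, not from the behavioral simulator.

## Numerical and testing notes

* All times are local wall-clock in a single configurable UTC offset
  (default −03:00); a single-city deployment needs no calendar timezone
  machinery.
* Outbound pacing: `delay = clamp(0.5 + 0.05 · length, 0.5, 6.0)` seconds,
  linear between the clamps. Event timestamps are forced monotone per
  participant.
* Statistical tests use 3-standard-error tolerances at cohort sizes of
  500–1000 (seeded), and the scheduler property suite runs 10,000
  randomized cycles; these sizes keep the default suite under a minute of
  simulation while leaving the binomial bounds tight (±1.1 percentage
  points at n = 1000 × 14 days).
* The lag-1 autocorrelation check uses the pooled (grand-mean) estimator
  across 500 series of 14 days: per-series correlation estimates at this
  length are biased low by roughly (1 + 3ρ)/14, which would swamp the
  effect being tested.

## Known limitations

* No real messaging-platform adapter is included — the transport is a
  contract plus mock/console implementations; API integration, media
  storage and encryption are deployment concerns.
* No NLP: intent handling is exact-match by design, and the engine is not
  equipped for free-text understanding or crisis detection.
* The engine models one participant per engine instance; cross-participant
  concurrency is the transport's problem (ordered-per-participant is the
  only requirement).
* Engagement heterogeneity (see above), item-level psychometrics, and
  audio signal content are out of scope.
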