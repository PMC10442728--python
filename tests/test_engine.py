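import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from emabot.engine import (
    AUDIO_ACK_TEXT,
    DailyCycle,
    FOLLOWUP_1_TEXT,
    FOLLOWUP_2_TEXT,
    IntentKind,
    ProbeDecision,
    UNPROMPTED_CLARIFY_TEXT,
    accumulate_audio,
    classify_reply,
    replay,
    typing_delay,
)
from emabot.protocol import DayMode, Expects, ProtocolConfig
from emabot.scheduler import CycleClockState, CycleStatus
from emabot.transport import TransportError

from conftest import Driver, START


@pytest.fixture(scope="module")
def cfg():
    return ProtocolConfig()


class TestClassifyReply:
    @pytest.mark.parametrize("text", ["thank you", "Thanks!", "ok.", " OK ", "bye"])
    def test_closure_words_with_normalization(self, cfg, text):
        assert classify_reply(text, None, None, cfg).kind is IntentKind.CLOSURE

    def test_emoji_only_is_closure(self, cfg):
        assert classify_reply("\U0001f600", None, None, cfg).kind is IntentKind.CLOSURE

    def test_emoji_closure_config_switchable(self, cfg):
        strict = ProtocolConfig(emoji_closure=False)
        assert (
            classify_reply("\U0001f600", None, None, strict).kind
            is IntentKind.FREE_TEXT
        )

    def test_numeric_answers_in_questionnaire_context(self, cfg):
        intent = classify_reply("1", None, Expects.NUMERIC, cfg)
        assert intent.kind is IntentKind.NUMERIC_ANSWER and intent.value == 1

    @pytest.mark.parametrize("text", ["maybe", "five", "3", "yes"])
    def test_non_numeric_in_questionnaire_context_unsupported(self, cfg, text):
        assert (
            classify_reply(text, None, Expects.NUMERIC, cfg).kind
            is IntentKind.UNSUPPORTED
        )

    def test_yes_no_gate(self, cfg):
        assert classify_reply("Yes!", None, Expects.YESNO, cfg).kind is IntentKind.YES
        assert classify_reply("nao", None, Expects.YESNO, cfg).kind is IntentKind.NO

    def test_audio_payload(self, cfg):
        intent = classify_reply(None, 32.5, Expects.AUDIO, cfg)
        assert intent.kind is IntentKind.AUDIO and intent.duration == 32.5

    def test_snooze_with_time(self, cfg):
        intent = classify_reply("snooze 22:15", None, Expects.ANY, cfg)
        assert intent.kind is IntentKind.SNOOZE_REQUEST
        assert intent.time_of_day == dt.time(22, 15)

    def test_correction_keyword_only_in_questionnaire(self, cfg):
        assert (
            classify_reply("correct", None, Expects.NUMERIC, cfg).kind
            is IntentKind.CORRECTION_REQUEST
        )
        assert (
            classify_reply("correct", None, None, cfg).kind is IntentKind.FREE_TEXT
        )

    @given(st.text(min_size=1, max_size=40))
    def test_total_over_arbitrary_text(self, text):
        cfg = ProtocolConfig()
        for context in (None, Expects.NUMERIC, Expects.YESNO, Expects.AUDIO):
            classify_reply(text, None, context, cfg)  # never raises


class TestTypingDelay:
    def test_zero_length_hits_lower_clamp(self, cfg):
        assert typing_delay(0, cfg) == cfg.typing_base_s

    def test_default_constants_length_40(self, cfg):
        assert typing_delay(40, cfg) == pytest.approx(2.5)

    def test_linear_between_clamps(self, cfg):
        d20, d40 = typing_delay(20, cfg), typing_delay(40, cfg)
        assert d40 - cfg.typing_base_s == pytest.approx(
            2 * (d20 - cfg.typing_base_s)
        )

    def test_upper_clamp(self, cfg):
        assert typing_delay(10_000, cfg) == cfg.typing_cap_s


def _audio_cycle(day=1):
    return DailyCycle(
        day_index=day,
        mode=DayMode.AUDIO_QUESTIONS,
        clock=CycleClockState(cycle_date=START + dt.timedelta(days=day)),
        primary_answered=2,
    )


class TestAccumulateAudio:
    def test_below_target_triggers_first_followup(self, cfg):
        cycle = _audio_cycle()
        cycle.audio_seconds = 25.0
        assert accumulate_audio(cycle, 20.0, cfg) is ProbeDecision.FOLLOWUP_1
        assert cycle.audio_seconds == 45.0

    def test_target_met_on_primary_answers(self, cfg):
        cycle = _audio_cycle()
        cycle.audio_seconds = 40.0
        assert accumulate_audio(cycle, 30.0, cfg) is ProbeDecision.COMPLETE

    def test_second_followup_after_first(self, cfg):
        cycle = _audio_cycle()
        cycle.audio_seconds = 20.0
        cycle.followups_sent = 1
        assert accumulate_audio(cycle, 20.0, cfg) is ProbeDecision.FOLLOWUP_2

    def test_negative_duration_rejected(self, cfg):
        with pytest.raises(ValueError):
            accumulate_audio(_audio_cycle(), -1.0, cfg)

    @given(st.lists(st.floats(min_value=0, max_value=120), min_size=1, max_size=8))
    def test_never_more_than_two_followups(self, durations):
        cfg = ProtocolConfig()
        cycle = _audio_cycle()
        for duration in durations:
            decision = accumulate_audio(cycle, duration, cfg)
            if decision is ProbeDecision.FOLLOWUP_1:
                cycle.followups_sent = 1
            elif decision is ProbeDecision.FOLLOWUP_2:
                cycle.followups_sent = 2
        assert cycle.followups_sent <= cfg.max_followups
        assert cycle.audio_seconds == pytest.approx(sum(durations))


class TestOnboarding:
    def test_any_first_message_starts_day0(self, driver):
        driver.onboard("whatever")
        session = driver.engine.session
        assert session.onboarded_at is not None
        assert 0 in session.cycles and len(session.cycles) == 15
        day0 = [e for e in driver.engine.events if e.day_index == 0]
        assert day0 and all(e.excluded for e in day0)

    def test_repeated_activation_idempotent(self, driver):
        driver.onboard()
        driver.reply(text="hi again")
        session = driver.engine.session
        day0_inbound = [
            e
            for e in driver.engine.events
            if e.day_index == 0 and e.direction == "inbound"
        ]
        assert len(day0_inbound) == 1
        assert session.unprompted_events  # second message treated as unprompted


class TestUnprompted:
    def test_unprompted_audio_acknowledged_not_probed(self, driver):
        driver.onboard()
        driver.reply(audio=30.0)
        events = driver.engine.events
        assert events[-1].kind == "acknowledgment" and events[-1].body == AUDIO_ACK_TEXT
        audio = [e for e in events if e.kind == "audio"]
        assert audio[0].day_index is None and audio[0].audio_duration == 30.0

    def test_unprompted_closure_logged_silently(self, driver):
        driver.onboard()
        n_outbound = len(driver.outbound())
        driver.reply(text="ok")
        assert len(driver.outbound()) == n_outbound  # no reply sent
        assert driver.engine.events[-1].kind == "acknowledgment"

    def test_unprompted_free_text_gets_one_clarification(self, driver):
        driver.onboard()
        driver.reply(text="something happened today")
        assert driver.engine.events[-1].body == UNPROMPTED_CLARIFY_TEXT


class TestAudioDay:
    def _run_day1(self, driver, durations, gate_reply="no"):
        driver.onboard()
        driver.open_day(1)
        driver.reply(text="yes")  # availability
        for duration in durations:
            cycle = driver.cycle(1)
            if cycle.slot is not None and cycle.slot.tag == "fu2gate":
                driver.reply(text=gate_reply)
                if gate_reply == "no":
                    break
            if cycle.clock.status is CycleStatus.COMPLETED:
                break
            driver.reply(audio=duration)
        return driver.cycle(1)

    def test_target_met_no_followups(self, driver):
        cycle = self._run_day1(driver, [40.0, 30.0])
        assert cycle.clock.status is CycleStatus.COMPLETED
        assert cycle.followups_sent == 0 and cycle.audio_seconds == 70.0

    def test_below_target_first_followup(self, driver):
        cycle = self._run_day1(driver, [25.0, 20.0, 30.0])
        assert cycle.followups_sent == 1
        assert cycle.clock.status is CycleStatus.COMPLETED
        assert any(e.body.startswith("Thank you for sending this audio!")
                   for e in driver.outbound(1))

    def test_gated_second_followup_no_ends_cycle(self, driver):
        cycle = self._run_day1(driver, [10.0, 10.0, 20.0, 99.0], gate_reply="no")
        assert cycle.followups_sent == 2
        assert cycle.clock.status is CycleStatus.COMPLETED
        assert cycle.audio_seconds == 40.0  # the 99 s audio was never sent
        assert any("yes" in e.body and "no" in e.body for e in driver.outbound(1)
                   if e.body.startswith("It would be very important"))

    def test_gated_second_followup_yes_collects_more(self, driver):
        cycle = self._run_day1(driver, [10.0, 10.0, 20.0, 15.0], gate_reply="yes")
        assert cycle.clock.status is CycleStatus.COMPLETED
        assert cycle.audio_seconds == 55.0

    def test_day3_branch_follows_yes_no(self, config, schedule):
        driver = Driver(config, schedule)
        driver.onboard()
        driver.open_day(3)
        driver.reply(text="yes")     # availability
        driver.reply(text="yes")     # at home
        branch = driver.outbound(3)[-1].body
        assert branch == "What are you doing? Is someone else around?"
        driver.reply(audio=40.0)
        driver.reply(audio=30.0)
        assert driver.cycle(3).clock.status is CycleStatus.COMPLETED

    def test_text_in_audio_slot_reprompted_then_accepted(self, driver):
        driver.onboard()
        driver.open_day(1)
        driver.reply(text="yes")
        driver.reply(text="I'd rather type")
        assert driver.outbound(1)[-1].body.startswith("Could you answer with an audio")
        driver.reply(text="my day was fine")  # accepted as data, 0 s audio
        cycle = driver.cycle(1)
        assert cycle.primary_answered == 1 and cycle.audio_seconds == 0.0
        assert cycle.engaged


class TestQuestionnaireDay:
    def test_thirteen_prompts_and_completion(self, driver):
        driver.onboard()
        driver.open_day(2)
        driver.reply(text="yes")
        for _ in range(13):
            driver.reply(text="1")
        cycle = driver.cycle(2)
        assert cycle.clock.status is CycleStatus.COMPLETED
        item_prompts = [
            e for e in driver.outbound(2) if "(0=no, 1=sometimes, 2=yes)" in e.body
        ]
        assert len(item_prompts) == 13
        assert [a for a in cycle.smfq.answers] == [1] * 13

    def test_invalid_answer_reprompted_with_anchors(self, driver):
        driver.onboard()
        driver.open_day(2)
        driver.reply(text="yes")
        driver.reply(text="maybe")
        reprompt = driver.outbound(2)[-1].body
        assert "0" in reprompt and "(0=no, 1=sometimes, 2=yes)" in reprompt
        assert driver.cycle(2).smfq.next_unanswered == 0

    def test_correction_dialog(self, driver):
        driver.onboard()
        driver.open_day(2)
        driver.reply(text="yes")
        for _ in range(5):
            driver.reply(text="2")
        driver.reply(text="correct")
        assert "Which question" in driver.outbound(2)[-1].body
        driver.reply(text="3")
        driver.reply(text="0")
        cycle = driver.cycle(2)
        assert cycle.smfq.answers[2] == 0
        assert len(cycle.smfq.corrections) == 1
        for _ in range(8):  # resume to completion
            driver.reply(text="1")
        assert cycle.clock.status is CycleStatus.COMPLETED

    def test_closure_mid_questionnaire_does_not_advance(self, driver):
        driver.onboard()
        driver.open_day(2)
        driver.reply(text="yes")
        driver.reply(text="ok")  # closure word: acknowledged, item unanswered
        assert driver.cycle(2).smfq.next_unanswered == 0


class TestSnoozeFlow:
    def test_snooze_confirm_and_return(self, driver):
        driver.onboard()
        driver.open_day(1)
        driver.reply(text="snooze 22:00")
        cycle = driver.cycle(1)
        assert cycle.clock.status is CycleStatus.SNOOZED
        assert cycle.clock.snoozed_until.time() == dt.time(22, 0)
        driver.advance_to(1, dt.time(22, 0))  # snooze prompt fires
        assert cycle.clock.status is CycleStatus.PROMPTED
        driver.reply(text="yes")
        driver.reply(audio=70.0)
        driver.reply(audio=10.0)
        assert cycle.clock.status is CycleStatus.COMPLETED
        assert cycle.had_snooze

    def test_reminders_suppressed_while_snoozed(self, driver):
        driver.onboard()
        driver.open_day(1)
        driver.reply(text="snooze 23:30")
        driver.advance_to(1, dt.time(23, 0))  # > first prompt + 3 h
        bodies = [e.body for e in driver.outbound(1)]
        assert not any(b.startswith("Hi Ana! I'm still here") for b in bodies)


class TestExpiry:
    def test_ignored_day_expires_with_single_notice_at_10(self, driver, config):
        driver.onboard()
        driver.open_day(1)
        driver.advance_to(2, dt.time(12, 0))
        cycle = driver.cycle(1)
        assert cycle.clock.status is CycleStatus.EXPIRED
        notices = [e for e in driver.engine.events if e.kind == "expiry_notice"]
        assert len(notices) == 1
        base = notices[0].timestamp - dt.timedelta(
            seconds=typing_delay(len(notices[0].body), config)
        )
        assert base.time() == dt.time(10, 0)

    def test_reminders_every_3h_until_window_close(self, driver):
        driver.onboard()
        driver.open_day(1)
        driver.advance_to(2, dt.time(12, 0))
        reminders = [
            e for e in driver.outbound(1) if e.body.startswith("Hi Ana! I'm still here")
        ]
        assert len(reminders) == 5  # 16:30, 19:30, 22:30, 01:30, 04:30


class TestTransportFailure:
    def test_failure_logged_as_system_event_state_unchanged(self, driver):
        driver.onboard()
        statuses = {d: c.clock.status for d, c in driver.engine.session.cycles.items()}
        driver.transport.fail_next = 1
        driver.reply(audio=20.0)  # the acknowledgment delivery fails
        system = [e for e in driver.engine.events if e.direction == "system"
                  and e.body.startswith("delivery failed")]
        assert len(system) == 1
        assert {
            d: c.clock.status for d, c in driver.engine.session.cycles.items()
        } == statuses


class TestReplay:
    def test_event_sourcing_round_trip(self, config, schedule):
        driver = Driver(config, schedule)
        driver.onboard()
        driver.open_day(1)
        driver.reply(text="snooze 21:00")
        driver.advance_to(1, dt.time(21, 0))
        driver.reply(text="yes")
        driver.reply(audio=25.0)
        driver.reply(audio=20.0)
        driver.reply(audio=30.0)  # follow-up 1 -> total 75, complete
        driver.reply(text="thank you")
        driver.open_day(2)
        driver.reply(text="yes")
        for _ in range(13):
            driver.reply(text="2")
        driver.advance_to(3, dt.time(12, 0))

        original = driver.engine.events
        rebuilt = replay(original, config, schedule, name="Ana")
        assert rebuilt.events == original
        for day, cycle in driver.engine.session.cycles.items():
            other = rebuilt.session.cycles[day]
            assert other.clock == cycle.clock
            assert other.audio_seconds == cycle.audio_seconds
            assert other.engaged == cycle.engaged
        assert rebuilt.session.cycles[2].smfq.answers == [2] * 13
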