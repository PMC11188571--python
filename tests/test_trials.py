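"""Trial data model, I/O round-trips, and behavioral preprocessing."""

import numpy as np
import pytest

from forgetq import (SessionLog, TrialRecord, exclude_early_pulls,
                     lever_pull_rate, moving_average_choice, read_trials,
                     threshold_sessions_met, truncate_at_reward_fraction,
                     write_trials)
from forgetq.trials import (TrialValidationError, UndefinedRateError,
                            per_tone_moving_average)

from conftest import make_log


class TestRecordInvariants:
    def test_non_pull_cannot_carry_outcomes(self):
        with pytest.raises(TrialValidationError):
            TrialRecord(0, 0, "A", "non_pull", reward=1, punishment=0)
        with pytest.raises(TrialValidationError):
            TrialRecord(0, 0, "A", "non_pull", reward=0, punishment=1)

    @pytest.mark.parametrize("field,value", [
        ("tone", "C"), ("action", "push"), ("reward", 2)])
    def test_bad_categorical_values_rejected(self, field, value):
        kw = dict(trial_index=0, session_id=0, tone="A", action="pull",
                  reward=1, punishment=0)
        kw[field] = value
        with pytest.raises(TrialValidationError):
            TrialRecord(**kw)

    def test_trial_index_must_strictly_increase(self):
        t = TrialRecord(0, 0, "A", "pull", 1, 0)
        with pytest.raises(TrialValidationError):
            SessionLog([t, t])


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip_identity(self, tmp_path, fmt):
        log = make_log([("A", "pull", 1, 1), ("B", "non_pull", 0, 0),
                        ("B", "pull", 1, 0, True)])
        path = tmp_path / f"trials.{fmt}"
        write_trials(log, path)
        back = read_trials(path, task_label="air_puff")
        assert back.trials == log.trials
        assert back.task_label == log.task_label or fmt == "csv"

    def test_invalid_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "trial_index,session_id,tone,action,reward,punishment,early_pull\n"
            "0,0,A,pull,1,0,0\n"
            "1,0,B,non_pull,1,0,0\n")
        with pytest.raises(TrialValidationError, match="row 3"):
            read_trials(path)

    def test_header_only_file_is_empty_log(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "trial_index,session_id,tone,action,reward,punishment,early_pull\n")
        assert len(read_trials(path)) == 0


class TestEarlyPulls:
    def test_excludes_only_early_trials_preserving_order(self):
        rows = [("A", "pull", 1, 0)] * 4 + [("B", "pull", 1, 0, True)] * 2 \
            + [("B", "non_pull", 0, 0)] * 4
        log = make_log(rows)
        out = exclude_early_pulls(log)
        assert len(out) == 8
        assert [t.trial_index for t in out] == [0, 1, 2, 3, 6, 7, 8, 9]

    def test_idempotent(self):
        log = make_log([("A", "pull", 1, 0, True), ("B", "pull", 1, 0)])
        once = exclude_early_pulls(log)
        twice = exclude_early_pulls(once)
        assert once.trials == twice.trials

    def test_all_early_gives_empty_log(self):
        log = make_log([("A", "pull", 1, 0, True)] * 3)
        assert len(exclude_early_pulls(log)) == 0


class TestRewardTruncation:
    def test_keeps_trials_before_threshold_reward(self):
        # reward on every trial, planned 10, fraction 0.6 -> threshold at
        # the 6th reward, so the first five trials survive
        log = make_log([("B", "pull", 1, 0)] * 12)
        out = truncate_at_reward_fraction(log, planned_rewards=10)
        assert len(out) == 5

    def test_unrewarded_session_kept_whole(self):
        log = make_log([("B", "non_pull", 0, 0)] * 7)
        out = truncate_at_reward_fraction(log, planned_rewards=10)
        assert len(out) == 7

    def test_threshold_above_total_rewards_keeps_all(self):
        log = make_log([("B", "pull", 1, 0)] * 4)
        out = truncate_at_reward_fraction(log, planned_rewards=100,
                                          fraction=1.0)
        assert len(out) == 4

    def test_applied_per_session(self):
        trials = []
        idx = 0
        for sid in range(2):
            for _ in range(10):
                trials.append(TrialRecord(idx, sid, "B", "pull", 1, 0))
                idx += 1
        log = SessionLog(trials, "air_puff")
        out = truncate_at_reward_fraction(log, planned_rewards=10)
        assert len(out) == 10
        assert sorted({t.session_id for t in out}) == [0, 1]

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.2])
    def test_fraction_domain(self, fraction):
        log = make_log([("B", "pull", 1, 0)])
        with pytest.raises(ValueError):
            truncate_at_reward_fraction(log, 10, fraction=fraction)


class TestPullRate:
    def test_counts_only_requested_tone(self):
        log = make_log([("B", "pull", 1, 0)] * 6 + [("B", "non_pull", 0, 0)] * 2
                       + [("A", "pull", 1, 0)] + [("A", "non_pull", 0, 0)] * 3)
        assert lever_pull_rate(log, "B") == pytest.approx(0.75)
        assert lever_pull_rate(log, "A") == pytest.approx(0.25)

    def test_early_pulls_removed_from_denominator(self):
        log = make_log([("B", "pull", 1, 0)] * 2
                       + [("B", "pull", 1, 0, True)] * 2)
        assert lever_pull_rate(log, "B") == 1.0

    def test_no_trials_raises(self):
        log = make_log([("B", "pull", 1, 0)])
        with pytest.raises(UndefinedRateError):
            lever_pull_rate(log, "A")

    def test_invariant_to_reordering(self, rng):
        rows = [("B", "pull", 1, 0)] * 5 + [("B", "non_pull", 0, 0)] * 3
        perm = list(rows)
        rng.shuffle(perm)
        assert (lever_pull_rate(make_log(rows), "B")
                == lever_pull_rate(make_log(perm), "B"))


class TestMovingAverage:
    def test_prefix_rule_hand_example(self):
        out = moving_average_choice([1, 1, 0], window=2)
        assert out.tolist() == [1.0, 1.0, 0.5]

    def test_constant_sequence_and_alternation(self):
        assert np.all(moving_average_choice([1] * 30) == 1.0)
        alt = moving_average_choice([1, 0] * 20, window=10)
        assert np.allclose(alt[9:], 0.5)

    def test_output_aligns_with_input(self):
        assert moving_average_choice([0, 1, 1, 0, 1], 10).shape == (5,)

    def test_window_domain(self):
        with pytest.raises(ValueError):
            moving_average_choice([1, 0], window=0)

    def test_per_tone_sequences_are_separate(self):
        log = make_log([("A", "pull", 1, 0), ("B", "non_pull", 0, 0),
                        ("A", "pull", 1, 0)])
        out = per_tone_moving_average(log, window=2)
        assert out["A"].tolist() == [1.0, 1.0]
        assert out["B"].tolist() == [0.0]


class TestThresholdSessions:
    def test_two_consecutive_qualifying_sessions(self):
        assert threshold_sessions_met([(0.4, 0.7), (0.3, 0.8)]) == (True, 1)

    def test_interrupted_run_does_not_qualify(self):
        assert threshold_sessions_met(
            [(0.4, 0.7), (0.6, 0.8), (0.4, 0.9)]) == (False, None)

    def test_boundary_rates_use_strict_inequality(self):
        assert threshold_sessions_met(
            [(0.5, 0.7), (0.4, 0.8)]) == (False, None)
        assert threshold_sessions_met(
            [(0.4, 0.5), (0.4, 0.8)]) == (False, None)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            threshold_sessions_met([])
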