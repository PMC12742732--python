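"""Clock-judgment errors and binding scores."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topobind.binding import (
    ACTION_ONLY,
    AGENCY_JUDGE_ACTION,
    AGENCY_JUDGE_TONE,
    TONE_ONLY,
    TrialRecord,
    binding_scores,
    group_binding_table,
    judgment_error_ms,
)
from topobind.synthetic import TrialSimConfig, generate_trials

PERIOD = 2560.0


def _trial(actual, reported, condition=ACTION_ONLY):
    return TrialRecord(condition=condition, actual_deg=actual,
                       reported_deg=reported, clock_period_ms=PERIOD)


class TestJudgmentError:
    def test_quarter_turn_late(self):
        assert judgment_error_ms(_trial(90.0, 135.0)) == pytest.approx(320.0)

    def test_exact_report_is_zero(self):
        assert judgment_error_ms(_trial(123.4, 123.4)) == 0.0

    def test_wraparound(self):
        """350 -> 10 degrees is +20 degrees = +142.2 ms, not -340 degrees."""
        err = judgment_error_ms(_trial(350.0, 10.0))
        assert err == pytest.approx(20.0 / 360.0 * PERIOD)
        assert err == pytest.approx(142.2, abs=0.1)

    def test_wraparound_against_unwrapped_oracle(self, rng):
        """An oracle that tracks the cumulative (unwrapped) dot angle gives
        the same error whenever the true discrepancy is under half a turn."""
        for _ in range(200):
            actual_unwrapped = rng.uniform(0, 5 * 360)
            delta = rng.uniform(-170, 170)
            reported_unwrapped = actual_unwrapped + delta
            t = _trial(actual_unwrapped % 360, reported_unwrapped % 360)
            assert judgment_error_ms(t) == pytest.approx(
                delta / 360.0 * PERIOD, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 359.999), st.floats(0, 359.999))
    def test_antisymmetry(self, a, b):
        fwd = judgment_error_ms(_trial(a, b))
        rev = judgment_error_ms(_trial(b, a))
        # the +-half-turn boundary maps to itself, so allow that single tie
        if abs(abs(fwd) - PERIOD / 2) > 1e-6:
            assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_invalid_trial_rejected(self):
        t = _trial(0.0, 10.0)
        t.valid = False
        with pytest.raises(ValueError):
            judgment_error_ms(t)


class TestBindingScores:
    def _trials_with_errors(self, errors_by_condition):
        trials = []
        for cond, errs in errors_by_condition.items():
            for e in errs:
                shift_deg = e / PERIOD * 360.0
                trials.append(_trial(100.0, 100.0 + shift_deg, cond))
        return trials

    def test_all_zero_errors(self):
        trials = self._trials_with_errors({
            ACTION_ONLY: [0, 0], TONE_ONLY: [0, 0],
            AGENCY_JUDGE_ACTION: [0, 0], AGENCY_JUDGE_TONE: [0, 0]})
        sc = binding_scores(trials)
        assert sc.action_binding_ms == 0.0
        assert sc.tone_binding_ms == 0.0
        assert sc.total_binding_ms == 0.0

    def test_sign_convention_total(self):
        """action +40, tone -30 gives total 70 (action minus tone)."""
        trials = self._trials_with_errors({
            ACTION_ONLY: [0.0], TONE_ONLY: [0.0],
            AGENCY_JUDGE_ACTION: [40.0], AGENCY_JUDGE_TONE: [-30.0]})
        sc = binding_scores(trials)
        assert sc.action_binding_ms == pytest.approx(40.0)
        assert sc.tone_binding_ms == pytest.approx(-30.0)
        assert sc.total_binding_ms == pytest.approx(70.0)
        assert "action_binding - tone_binding" in sc.convention

    def test_trial_order_invariance(self, rng):
        cfg = TrialSimConfig(action_shift_ms=55.0, tone_shift_ms=-20.0, seed=3)
        trials = generate_trials(cfg)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        a = binding_scores(trials)
        b = binding_scores(shuffled)
        assert a.total_binding_ms == pytest.approx(b.total_binding_ms)

    def test_constant_shift_property(self):
        """Adding c degrees to every agency-action report moves action
        binding by exactly c * period / 360."""
        cfg = TrialSimConfig(seed=9)
        trials = generate_trials(cfg)
        base = binding_scores(trials)
        c = 10.0
        shifted = [
            dataclasses.replace(t, reported_deg=(t.reported_deg + c) % 360.0)
            if t.condition == AGENCY_JUDGE_ACTION else t
            for t in trials
        ]
        moved = binding_scores(shifted)
        assert (moved.action_binding_ms - base.action_binding_ms
                == pytest.approx(c / 360.0 * PERIOD, abs=1e-6))

    def test_invalid_trials_excluded_and_counted(self):
        trials = self._trials_with_errors({
            ACTION_ONLY: [0.0, 0.0], TONE_ONLY: [0.0],
            AGENCY_JUDGE_ACTION: [40.0, 40.0], AGENCY_JUDGE_TONE: [-30.0]})
        trials[0].valid = False
        sc = binding_scores(trials)
        assert sc.n_valid_trials[ACTION_ONLY] == 1
        assert sc.total_binding_ms == pytest.approx(70.0)

    def test_empty_condition_reported(self):
        trials = self._trials_with_errors({
            ACTION_ONLY: [0.0], AGENCY_JUDGE_ACTION: [1.0]})
        with pytest.raises(ValueError, match=TONE_ONLY):
            binding_scores(trials)

    def test_noisy_recovery_within_2_sem(self):
        """200 seeded replicates at 70 ms judgment noise recover the
        injected total binding within two standard errors."""
        injected = 70.0
        totals = []
        for seed in range(200):
            cfg = TrialSimConfig(action_shift_ms=40.0, tone_shift_ms=-30.0,
                                 judgment_noise_sd_ms=70.0, seed=seed)
            totals.append(binding_scores(generate_trials(cfg)).total_binding_ms)
        totals = np.asarray(totals)
        sem = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - injected) <= 2 * sem


class TestGroupTable:
    def _score(self, subject, total):
        from topobind.binding import BindingScores
        return BindingScores(subject=subject, action_binding_ms=total / 2,
                             tone_binding_ms=-total / 2,
                             total_binding_ms=total, n_valid_trials={})

    def test_identical_subjects_sd_zero(self):
        table = group_binding_table(
            {"SCR": [self._score("a", 100.0), self._score("b", 100.0)]})
        row = table[(table.group == "SCR")
                    & (table.measure == "total_binding_ms")].iloc[0]
        assert row["mean"] == 100.0
        assert row["sd"] == 0.0

    def test_hand_arithmetic(self):
        table = group_binding_table(
            {"G": [self._score("a", 100.0), self._score("b", 140.0)]})
        row = table[table.measure == "total_binding_ms"].iloc[0]
        assert row["mean"] == pytest.approx(120.0)
        assert row["sd"] == pytest.approx(28.2843, abs=1e-3)

    def test_single_subject_sd_undefined(self):
        table = group_binding_table({"G": [self._score("a", 50.0)]})
        assert np.isnan(table["sd"]).all()

    def test_group_means_recovered_at_n30(self):
        """Simulated groups with the configured 123/51/82 ms totals recover
        those means within 2 SEM at n=30 per group."""
        params = {"SCR": (123.0, 75.0), "SLR": (51.0, 41.0),
                  "CTR": (82.0, 54.0)}
        rng = np.random.default_rng(42)
        scores = {g: [] for g in params}
        for g, (mu, sd) in params.items():
            for i in range(30):
                ttb = rng.normal(mu, sd)
                cfg = TrialSimConfig(action_shift_ms=ttb / 2,
                                     tone_shift_ms=-ttb / 2,
                                     judgment_noise_sd_ms=70.0,
                                     seed=int(rng.integers(2 ** 31)))
                scores[g].append(binding_scores(generate_trials(cfg), f"{g}{i}"))
        table = group_binding_table(scores)
        for g, (mu, sd) in params.items():
            row = table[(table.group == g)
                        & (table.measure == "total_binding_ms")].iloc[0]
            sem = row["sd"] / np.sqrt(row["n"])
            assert abs(row["mean"] - mu) <= 2 * sem
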