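"""Single-subject simulation: help ladder, trace invariants, outcome-tree oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from adlsim import (
    INCAPABLE,
    INDEPENDENT,
    build_activity,
    score_trace,
    simulate_subject,
)
from tests.conftest import make_profile, one_step_activity


def test_unimpaired_subject_completes_everything_independently(tea, zero_noise_profile, rng):
    trace = simulate_subject(tea, zero_noise_profile, rng)
    assert all(ev.outcome == "success" and ev.help_level == INDEPENDENT
               for ev in trace.events)
    assert trace.forgot_count == 0
    assert trace.similar_confusion_count == 0
    assert trace.other_confusion_count == 0
    assert score_trace(trace, tea).total == 0


def test_unreachable_threshold_forces_incapable_step(rng):
    # threshold above activation even after max_attempts-1 boosts of 1.0
    act = one_step_activity()
    profile = make_profile(threshold=50.0)
    trace = simulate_subject(act, profile, rng)
    assert trace.step_help_levels()["fetch"] == INCAPABLE
    assert trace.forgot_count == 3  # one omission per attempt
    # later steps still ran: the caregiver completes the skipped step
    assert {e.step_id for e in trace.events} == {s.id for s in act.steps}


def test_trace_has_at_least_one_event_per_step(tea, shipped_profiles):
    trace = simulate_subject(tea, shipped_profiles["cdr2"], np.random.default_rng(0))
    assert {e.step_id for e in trace.events} == {s.id for s in tea.steps}
    assert len(trace.events) >= len(tea.steps)


def test_jsonl_export_one_record_per_event(tea, shipped_profiles):
    trace = simulate_subject(tea, shipped_profiles["cdr1"], np.random.default_rng(1))
    lines = trace.to_jsonl().splitlines()
    assert len(lines) == len(trace.events)
    assert all(line.startswith("{") for line in lines)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), level=st.sampled_from(["cdr0.5", "cdr1", "cdr2", "cdr3"]))
def test_trace_counters_match_events_and_ladder_is_consistent(
    tea, shipped_profiles, seed, level
):
    trace = simulate_subject(tea, shipped_profiles[level], np.random.default_rng(seed))
    trace.check_consistency()  # raises on any ladder/counter violation
    omissions = sum(1 for e in trace.events if e.outcome == "omission")
    commissions = sum(1 for e in trace.events if e.outcome == "commission")
    assert trace.forgot_count == omissions
    assert trace.similar_confusion_count + trace.other_confusion_count == commissions


def test_seeded_determinism_bit_identical_traces(tea, shipped_profiles):
    t1 = simulate_subject(tea, shipped_profiles["cdr3"], np.random.default_rng(77))
    t2 = simulate_subject(tea, shipped_profiles["cdr3"], np.random.default_rng(77))
    assert t1 == t2


def test_commission_records_the_confused_item(shipped_profiles):
    tea = build_activity("tea")
    found = False
    for seed in range(200):
        trace = simulate_subject(tea, shipped_profiles["cdr3"], np.random.default_rng(seed))
        for ev in trace.events:
            if ev.outcome == "commission":
                assert ev.confused_with is not None
                found = True
    assert found, "no commission occurred in 200 severe-AD runs"


class TestOutcomeTreeOracle:
    """One-retrieval-step activity vs exhaustive enumeration of the ladder.

    With a single candidate (no similar chunks) the attempt-k success
    probability has the closed form p_k = P(a_k + eps >= tau) under logistic
    noise, with a_k raised by the boost increment after each failure.  The
    help-level distribution then follows the outcome tree:
    P(0)=p1, P(1)=(1-p1)p2, P(2)=(1-p1)(1-p2)p3, P(3)=remainder.
    """

    def expected_distribution(self, a0, boost, tau, s):
        p = [stats.logistic.sf(tau - (a0 + k * boost), 0, s) for k in range(3)]
        q0 = p[0]
        q1 = (1 - p[0]) * p[1]
        q2 = (1 - p[0]) * (1 - p[1]) * p[2]
        return np.array([q0, q1, q2, 1 - q0 - q1 - q2])

    def test_help_level_distribution_matches_enumeration(self):
        act = one_step_activity()
        s, tau, boostinc = 0.6, 2.2, 1.0
        profile = make_profile(noise_scale_act=s, threshold=tau, boost_increment=boostinc)
        # a0 = W/1 * S = 2.0 (goal associated with the target)
        expected = self.expected_distribution(2.0, boostinc, tau, s)
        n = 100_000
        rng = np.random.default_rng(13)
        counts = np.zeros(4)
        for _ in range(n):
            trace = simulate_subject(act, profile, rng)
            counts[trace.step_help_levels()["fetch"]] += 1
        freq = counts / n
        margins = 3 * np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) < np.maximum(margins, 1e-4)), (
            freq, expected
        )
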