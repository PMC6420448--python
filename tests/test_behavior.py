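"""Behavioral generator: traces, DNMS responses, recall, memory test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from contextwm.behavior import (
    GenerativeParams,
    simulate_dnms,
    simulate_dnms_cohort,
    simulate_memory_test,
    simulate_recall,
    simulate_reinstatement,
)
from contextwm.design import generate_dnms_trials, generate_recall_trials


@pytest.fixture(scope="module")
def dnms_trials(exp3_design, exp3_schedule):
    return generate_dnms_trials(exp3_design, seed=21, n_trials=60, schedule=exp3_schedule)


class TestReinstatement:
    def test_bounds(self, exp3_design, dnms_trials):
        trace = simulate_reinstatement(dnms_trials, exp3_design, GenerativeParams(), 0)
        assert trace.intensity.min() >= 0 and trace.intensity.max() <= 1

    def test_boost_zero_exchangeable(self, exp3_design, exp3_schedule):
        trials = generate_dnms_trials(exp3_design, seed=1, n_trials=999,
                                      schedule=exp3_schedule)
        p = GenerativeParams(reinstate_boost=0.0)
        trace = simulate_reinstatement(trials, exp3_design, p, 0)
        means = trace.intensity.mean(axis=(0, 1))
        assert np.allclose(means, means.mean(), atol=0.02)

    def test_target_context_elevated(self, exp3_design, exp3_schedule):
        trials = generate_dnms_trials(exp3_design, seed=2, n_trials=999,
                                      schedule=exp3_schedule)
        trace = simulate_reinstatement(trials, exp3_design, GenerativeParams(), 0,
                                       memory_strength=0.8)
        ctx_idx = {c: k for k, c in enumerate(trace.context_ids)}
        tgt, non = [], []
        for i, t in enumerate(trials):
            j = ctx_idx[t.context_id]
            tgt.append(trace.intensity[i, 1, j])
            non.append(np.delete(trace.intensity[i, 1, :], j).mean())
        assert np.mean(tgt) > np.mean(non) + 0.2

    def test_zero_memory_strength_flat_delay(self, exp3_design, dnms_trials):
        trace = simulate_reinstatement(dnms_trials, exp3_design, GenerativeParams(), 0,
                                       memory_strength=0.0)
        ctx_idx = {c: k for k, c in enumerate(trace.context_ids)}
        diffs = []
        for i, t in enumerate(dnms_trials):
            j = ctx_idx[t.context_id]
            diffs.append(trace.intensity[i, 1, j] - np.delete(trace.intensity[i, 1, :], j).mean())
        assert abs(np.mean(diffs)) < 0.03

    def test_seed_determinism(self, exp3_design, dnms_trials):
        a = simulate_reinstatement(dnms_trials, exp3_design, GenerativeParams(), 7)
        b = simulate_reinstatement(dnms_trials, exp3_design, GenerativeParams(), 7)
        assert np.array_equal(a.intensity, b.intensity)


class TestDNMSResponses:
    def test_rt_bounds_and_timeouts(self, exp3_design, dnms_trials):
        p = GenerativeParams()
        trace = simulate_reinstatement(dnms_trials, exp3_design, p, 0)
        resp = simulate_dnms(dnms_trials, trace, exp3_design, p, 1)
        for r in resp:
            if r.response != "none":
                assert 0 < r.rt_ms <= 4000

    def test_planted_null_equal_means(self, exp3_design, exp3_schedule):
        trials = generate_dnms_trials(exp3_design, seed=3, n_trials=600,
                                      schedule=exp3_schedule)
        p = GenerativeParams(beta_target_ms=0, beta_lure_ms=0, beta_other_ms=0,
                             gamma_probe_ms=0, gamma_nonprobe_ms=0)
        trace = simulate_reinstatement(trials, exp3_design, p, 0)
        resp = simulate_dnms(trials, trace, exp3_design, p, 1)
        df = pd.DataFrame({"probe_type": [t.probe_type for t in trials],
                           "rt": [r.rt_ms for r in resp]})
        means = df.dropna().groupby("probe_type")["rt"].mean()
        assert means.max() - means.min() < 30  # ~3 SEM at n=200/type

    def test_slow_rts_become_timeouts(self, exp3_design, dnms_trials):
        p = GenerativeParams(rt_mu_ms=4500.0)
        trace = simulate_reinstatement(dnms_trials, exp3_design, p, 0)
        resp = simulate_dnms(dnms_trials, trace, exp3_design, p, 1)
        assert sum(r.response == "none" for r in resp) > len(resp) * 0.9
        assert all(r.rt_ms is None for r in resp if r.response == "none")

    def test_lure_slowing_at_defaults(self, exp3_design, exp3_schedule):
        cohort = simulate_dnms_cohort(exp3_design, GenerativeParams(), 30, 5,
                                      n_trials=60, schedule=exp3_schedule)
        df = cohort["responses"]
        means = df[df["accurate"]].groupby("probe_type")["rt_ms"].mean()
        assert means["lure"] > means["other"]
        assert means["lure"] > means["target"]


class TestRecall:
    def test_degenerate_mixture_all_previous(self, exp1_design):
        trials = generate_recall_trials(exp1_design, seed=1)
        p = GenerativeParams(error_mix=(1.0, 0.0, 0.0),
                             recall_error_prob={"none": 0.5, "break": 0.5, "full": 0.5})
        resp = simulate_recall(trials, exp1_design, p, 0)
        from contextwm.recall import categorize_subject_errors

        errors = categorize_subject_errors(trials, resp, exp1_design)
        first_index = trials[0].index
        non_first = errors[errors["trial"] != first_index]
        assert len(non_first) > 50
        assert (non_first["category"] == "previous_target").all()

    def test_no_distraction_near_zero_errors(self, exp1_design):
        trials = generate_recall_trials(exp1_design, seed=2)
        resp = simulate_recall(trials, exp1_design, GenerativeParams(), 0)
        from contextwm.recall import categorize_subject_errors

        errors = categorize_subject_errors(trials, resp, exp1_design)
        n_none = (errors["condition"] == "none").sum()
        assert n_none <= 4  # 18 trials x 4 words x p=.016 -> ~1 expected

    def test_first_trial_weight_reassignment(self, exp1_design):
        trials = generate_recall_trials(exp1_design, seed=3)
        p = GenerativeParams(error_mix=(1.0, 0.0, 0.0),
                             recall_error_prob={"none": 1.0, "break": 1.0, "full": 1.0})
        resp = simulate_recall(trials, exp1_design, p, 0)
        # first trial has no previous pool; its errors must fall elsewhere
        words = str(resp.iloc[0]["response_words"]).split()
        assert len(words) == 4  # drew a full response without crashing


class TestMemoryTest:
    def test_pure_guessing(self, exp3_design):
        out = simulate_memory_test(exp3_design, GenerativeParams(), 0, pi_mem=0.0)
        acc = np.mean([m.correct for m in out])
        assert abs(acc - 0.25) < 0.2  # 48 words; loose MC band

    def test_perfect_memory(self, exp3_design):
        out = simulate_memory_test(exp3_design, GenerativeParams(), 0, pi_mem=1.0)
        assert all(m.correct for m in out)
        assert all(1 <= m.confidence <= 4 for m in out)

    def test_group_accuracy_calibration(self, exp3_design):
        p = GenerativeParams()
        rng = np.random.default_rng(0)
        accs = []
        for s in range(200):
            pi = rng.beta(*p.memory_beta_ab)
            out = simulate_memory_test(exp3_design, p, rng, pi_mem=pi)
            accs.append(np.mean([m.correct for m in out]))
        # expected group accuracy = pi + (1 - pi)/4 with mean pi = .216
        assert abs(np.mean(accs) - 0.412) < 0.03


class TestCohort:
    def test_same_seed_identical(self, exp3_design, exp3_schedule):
        a = simulate_dnms_cohort(exp3_design, GenerativeParams(), 4, 9, n_trials=12,
                                 schedule=exp3_schedule)
        b = simulate_dnms_cohort(exp3_design, GenerativeParams(), 4, 9, n_trials=12,
                                 schedule=exp3_schedule)
        pd.testing.assert_frame_equal(a["responses"], b["responses"])
        pd.testing.assert_frame_equal(a["memory"], b["memory"])

    def test_log_rt_roughly_normal(self, exp3_design, exp3_schedule):
        from scipy import stats

        cohort = simulate_dnms_cohort(exp3_design, GenerativeParams(), 12, 2,
                                      n_trials=60, schedule=exp3_schedule)
        df = cohort["responses"].dropna(subset=["rt_ms"])
        skews = df.groupby("subject")["rt_ms"].apply(lambda g: stats.skew(np.log(g)))
        assert abs(skews.mean()) < 0.8
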