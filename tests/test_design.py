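"""Design generator: partitions, schedules, trial sequences, overlap."""

import collections
import dataclasses

import numpy as np
import pytest

from contextwm.design import (
    DesignParams,
    DNMSTrialSpec,
    LearningTrial,
    build_design,
    compute_overlap,
    exp1_design_params,
    exp3_design_params,
    generate_dnms_trials,
    generate_learning_schedule,
    generate_recall_trials,
)


class TestBuildDesign:
    def test_exp1_counts(self, exp1_design):
        assert len(exp1_design.words) == 72
        assert len(exp1_design.context_sets) == 6
        assert all(cs.picture_kind == "scene" for cs in exp1_design.context_sets)

    def test_exp3_context_kinds_each_once(self, exp3_design):
        assert len(exp3_design.words) == 48
        combos = {(cs.picture_kind, cs.side) for cs in exp3_design.context_sets}
        assert combos == {("face", "left"), ("face", "right"),
                          ("scene", "left"), ("scene", "right")}

    def test_partition(self, exp1_design):
        seen = [w for cs in exp1_design.context_sets for w in cs.word_ids]
        assert sorted(seen) == sorted(exp1_design.words)
        assert len(set(seen)) == len(seen)

    def test_minimal_design(self, minimal_design):
        assert len(minimal_design.words) == 4

    def test_vocabulary_too_small(self):
        with pytest.raises(ValueError, match="vocabulary"):
            build_design(exp1_design_params(), seed=0, vocabulary=[f"w{i}" for i in range(10)])

    def test_seed_determinism(self):
        a = build_design(exp3_design_params(), seed=5)
        b = build_design(exp3_design_params(), seed=5)
        c = build_design(exp3_design_params(), seed=6)
        assert a == b
        assert a.context_sets != c.context_sets


class TestLearningSchedule:
    def test_exp3_counts_brute_force(self, exp3_design):
        sched = generate_learning_schedule(exp3_design, seed=1)
        assert len(sched) == 36  # 4 * 12 * 3 / 4
        counts = collections.Counter(w for t in sched for w in t.word_ids)
        assert set(counts.values()) == {3}
        assert set(counts) == set(exp3_design.words)

    def test_words_share_trial_context(self, exp3_design):
        sched = generate_learning_schedule(exp3_design, seed=2)
        for t in sched:
            ctxs = {exp3_design.context_of(w) for w in t.word_ids}
            assert ctxs == {t.context_id}
            assert len(set(t.word_ids)) == 4

    def test_minimal_forced_composition(self, minimal_design):
        sched = generate_learning_schedule(minimal_design, seed=0)
        assert len(sched) == 3
        for t in sched:
            assert sorted(t.word_ids) == sorted(minimal_design.words)

    def test_divisibility_error(self):
        d = build_design(DesignParams(n_sets=1, words_per_set=5, words_per_trial=4,
                                      repetitions=3), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            generate_learning_schedule(d, seed=0)

    def test_seed_determinism(self, exp3_design):
        assert generate_learning_schedule(exp3_design, 9) == generate_learning_schedule(exp3_design, 9)


class TestRecallTrials:
    def test_condition_counts(self, exp1_design):
        trials = generate_recall_trials(exp1_design, seed=4)
        counts = collections.Counter(t.condition for t in trials)
        assert counts == {"none": 18, "break": 18, "full": 18}
        assert len(trials) == 54

    def test_no_consecutive_context_brute_scan(self, exp1_design):
        for seed in range(5):
            trials = generate_recall_trials(exp1_design, seed=seed)
            for a, b in zip(trials, trials[1:]):
                assert a.context_id != b.context_id

    def test_scaled_minimum(self, exp1_design):
        trials = generate_recall_trials(exp1_design, seed=0, n_per_condition=1)
        assert len(trials) == 3
        assert {t.condition for t in trials} == {"none", "break", "full"}

    def test_single_context_error(self, minimal_design):
        with pytest.raises(ValueError, match="context"):
            generate_recall_trials(minimal_design, seed=0)


class TestDNMSTrials:
    def test_probe_type_counts(self, exp3_design):
        trials = generate_dnms_trials(exp3_design, seed=1, n_trials=60)
        counts = collections.Counter(t.probe_type for t in trials)
        assert counts == {"target": 20, "lure": 20, "other": 20}

    def test_probe_membership_brute_force(self, exp3_design):
        trials = generate_dnms_trials(exp3_design, seed=2, n_trials=60)
        for t in trials:
            cs = exp3_design.set_by_id(t.context_id)
            if t.probe_type == "target":
                assert t.probe_id in t.target_ids
                assert t.correct_response == "match"
            elif t.probe_type == "lure":
                candidates = [w for w in cs.word_ids if w not in t.target_ids]
                assert len(candidates) == 8
                assert t.probe_id in candidates
                assert t.correct_response == "mismatch"
            else:
                assert exp3_design.context_of(t.probe_id) != t.context_id
                assert t.correct_response == "mismatch"

    def test_pool_partition(self, exp3_design):
        trials = generate_dnms_trials(exp3_design, seed=3, n_trials=3)
        for t in trials:
            cs = exp3_design.set_by_id(t.context_id)
            targets = set(t.target_ids)
            lures = set(cs.word_ids) - targets
            others = set(exp3_design.words) - set(cs.word_ids)
            assert len(targets) == 4 and len(lures) == 8 and len(others) == 36
            assert targets | lures | others == set(exp3_design.words)

    def test_minimum_one_each(self, exp3_design):
        trials = generate_dnms_trials(exp3_design, seed=5, n_trials=3)
        assert collections.Counter(t.probe_type for t in trials) == {
            "target": 1, "lure": 1, "other": 1}

    def test_not_divisible_error(self, exp3_design):
        with pytest.raises(ValueError, match="divisible"):
            generate_dnms_trials(exp3_design, seed=0, n_trials=20)


def _brute_overlap(schedule, trial):
    """Independent oracle: enumerate (learning trial, target) pairs."""
    total = 0
    for lt in schedule:
        if trial.probe_id not in lt.word_ids:
            continue
        for tgt in trial.target_ids:
            if tgt != trial.probe_id and tgt in lt.word_ids:
                total += 1
    return total


class TestOverlap:
    def _trial(self, probe, targets, **kw):
        return DNMSTrialSpec(index=0, context_id="ctx0", target_ids=tuple(targets),
                             probe_id=probe, probe_type=kw.get("probe_type", "lure"),
                             correct_response=kw.get("correct_response", "mismatch"))

    def test_never_copresented_is_zero(self):
        sched = [LearningTrial(0, "ctx0", ("a", "b", "c", "d"))]
        t = self._trial("a", ["e", "f", "g", "h"])
        assert compute_overlap(sched, t) == 0

    def test_handcrafted_two_trial_schedule(self):
        # probe p with 2 targets in trial A and 1 target in trial B -> 3
        sched = [
            LearningTrial(0, "ctx0", ("p", "t1", "t2", "x")),
            LearningTrial(1, "ctx0", ("p", "t3", "y", "z")),
        ]
        t = self._trial("p", ["t1", "t2", "t3", "t4"])
        assert compute_overlap(sched, t) == 3
        assert _brute_overlap(sched, t) == 3

    def test_attainable_maximum_nine(self):
        sched = [LearningTrial(i, "ctx0", ("p", "t1", "t2", "t3")) for i in range(3)]
        t = self._trial("p", ["t1", "t2", "t3", "t4"])
        assert compute_overlap(sched, t) == 9

    def test_probe_absent_raises(self):
        sched = [LearningTrial(0, "ctx0", ("a", "b", "c", "d"))]
        with pytest.raises(ValueError, match="never appears"):
            compute_overlap(sched, self._trial("zz", ["a", "b", "c", "d"]))

    def test_matches_brute_force_on_random_designs(self, exp3_design):
        rng = np.random.default_rng(42)
        for seed in range(20):
            sched = generate_learning_schedule(exp3_design, seed=seed)
            trials = generate_dnms_trials(exp3_design, seed=seed + 100, n_trials=30,
                                          schedule=sched)
            for t in trials:
                assert t.overlap == _brute_overlap(sched, t)
                assert 0 <= t.overlap <= 9

    def test_range_across_seeds(self, exp3_design):
        for seed in range(30):
            sched = generate_learning_schedule(exp3_design, seed=seed)
            trials = generate_dnms_trials(exp3_design, seed=seed, n_trials=12, schedule=sched)
            assert all(0 <= t.overlap <= 9 for t in trials)
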