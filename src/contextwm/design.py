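"""Experiment designs: vocabulary, context sets, learning schedules, trial sequences.

The designs mirror a word/context paradigm: a vocabulary is partitioned into
context sets of 12 words, each set bound to a picture context (a scene, or a
face/scene shown on the left or right).  A learning schedule presents every
word exactly ``repetitions`` times, always in quadruples drawn from its own
set.  Downstream tasks draw their trials from these sets: free recall under
three distraction conditions, and a delayed-nonmatch-to-sample (DNMS) task
with target, lure and other-context probes.

The ``overlap`` statistic counts, for a DNMS probe, how many times the probe
word was co-presented with one of the current targets during context
learning, at (learning-trial, target)-pair granularity; with 3 repetitions
and 3 companions per presentation it is bounded by 9.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DesignParams",
    "ContextSet",
    "ExperimentDesign",
    "LearningTrial",
    "RecallTrialSpec",
    "DNMSTrialSpec",
    "RECALL_CONDITIONS",
    "PROBE_TYPES",
    "exp1_design_params",
    "exp3_design_params",
    "build_design",
    "generate_learning_schedule",
    "generate_recall_trials",
    "generate_dnms_trials",
    "compute_overlap",
]

RECALL_CONDITIONS = ("none", "break", "full")
PROBE_TYPES = ("target", "lure", "other")


@dataclass(frozen=True)
class DesignParams:
    """Counts defining a design.

    ``context_kinds`` gives one (picture_kind, side) pair per set; ``None``
    means every context is a scene with no lateralization (the behavioral
    design).
    """

    n_sets: int = 6
    words_per_set: int = 12
    words_per_trial: int = 4
    repetitions: int = 3
    context_kinds: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.words_per_set < self.words_per_trial:
            raise ValueError("words_per_set must be >= words_per_trial")
        if self.context_kinds is not None and len(self.context_kinds) != self.n_sets:
            raise ValueError("context_kinds must have one entry per set")


@dataclass(frozen=True)
class ContextSet:
    id: str
    picture_kind: str  # "scene" or "face"
    side: str  # "left", "right" or "none"
    word_ids: tuple[str, ...]


@dataclass(frozen=True)
class ExperimentDesign:
    words: tuple[str, ...]
    context_sets: tuple[ContextSet, ...]
    params: DesignParams
    seed: int

    def __post_init__(self):
        seen: set[str] = set()
        for cs in self.context_sets:
            if len(cs.word_ids) != self.params.words_per_set:
                raise ValueError(f"set {cs.id} does not have words_per_set words")
            overlap = seen.intersection(cs.word_ids)
            if overlap:
                raise ValueError(f"words assigned to more than one set: {overlap}")
            seen.update(cs.word_ids)
        if seen != set(self.words):
            raise ValueError("context sets must partition the vocabulary")

    @property
    def context_ids(self) -> tuple[str, ...]:
        return tuple(cs.id for cs in self.context_sets)

    def context_of(self, word_id: str) -> str:
        return self._word_to_context()[word_id]

    def set_by_id(self, context_id: str) -> ContextSet:
        for cs in self.context_sets:
            if cs.id == context_id:
                return cs
        raise KeyError(context_id)

    def _word_to_context(self) -> dict[str, str]:
        # cached lazily on the instance (frozen dataclass: use object.__setattr__)
        cache = getattr(self, "_w2c", None)
        if cache is None:
            cache = {w: cs.id for cs in self.context_sets for w in cs.word_ids}
            object.__setattr__(self, "_w2c", cache)
        return cache


@dataclass(frozen=True)
class LearningTrial:
    index: int
    context_id: str
    word_ids: tuple[str, ...]


@dataclass(frozen=True)
class RecallTrialSpec:
    index: int
    context_id: str
    target_ids: tuple[str, ...]
    condition: str  # one of RECALL_CONDITIONS


@dataclass(frozen=True)
class DNMSTrialSpec:
    index: int
    context_id: str
    target_ids: tuple[str, ...]
    probe_id: str
    probe_type: str  # one of PROBE_TYPES
    correct_response: str  # "match" or "mismatch"
    overlap: int = 0


def exp1_design_params() -> DesignParams:
    """Six scene contexts of 12 words (behavioral free-recall design)."""
    return DesignParams(n_sets=6, context_kinds=tuple(("scene", "none") for _ in range(6)))


def exp3_design_params() -> DesignParams:
    """Four contexts of 12 words: face/scene x left/right, each used once."""
    kinds = (("face", "left"), ("face", "right"), ("scene", "left"), ("scene", "right"))
    return DesignParams(n_sets=4, context_kinds=kinds)


def build_design(
    params: DesignParams,
    seed: int,
    vocabulary: list[str] | None = None,
) -> ExperimentDesign:
    """Partition a vocabulary into context sets, randomized by ``seed``."""
    rng = np.random.default_rng(seed)
    n_words = params.n_sets * params.words_per_set
    if vocabulary is None:
        vocabulary = [f"w{i:03d}" for i in range(n_words)]
    if len(vocabulary) < n_words:
        raise ValueError(
            f"vocabulary has {len(vocabulary)} words; need {n_words}"
        )
    words = tuple(rng.permutation(np.asarray(vocabulary[:n_words], dtype=object)).tolist())
    kinds = params.context_kinds or tuple(("scene", "none") for _ in range(params.n_sets))
    # randomize which (picture_kind, side) pairing each set receives
    kind_order = [kinds[i] for i in rng.permutation(params.n_sets)]
    sets = []
    for s in range(params.n_sets):
        block = words[s * params.words_per_set : (s + 1) * params.words_per_set]
        pk, side = kind_order[s]
        sets.append(ContextSet(id=f"ctx{s}", picture_kind=pk, side=side, word_ids=block))
    return ExperimentDesign(words=tuple(sorted(words)), context_sets=tuple(sets),
                            params=params, seed=seed)


def _schedule_one_set(cs: ContextSet, params: DesignParams, rng: np.random.Generator,
                      max_tries: int = 5000) -> list[tuple[str, ...]]:
    """Quota-respecting random grouping: every word appears exactly
    ``repetitions`` times, trials of ``words_per_trial`` distinct words.
    Rejection sampling over shuffles of the word-slot multiset."""
    slots = np.repeat(np.asarray(cs.word_ids, dtype=object), params.repetitions)
    k = params.words_per_trial
    for _ in range(max_tries):
        perm = rng.permutation(slots)
        groups = [tuple(perm[i : i + k]) for i in range(0, len(perm), k)]
        if all(len(set(g)) == k for g in groups):
            return groups
    raise RuntimeError("could not construct a duplicate-free learning schedule")


def generate_learning_schedule(design: ExperimentDesign, seed: int) -> list[LearningTrial]:
    """Learning schedule: each word shown exactly ``repetitions`` times with
    companions randomly sampled from its own set."""
    p = design.params
    if (p.words_per_set * p.repetitions) % p.words_per_trial != 0:
        raise ValueError("words_per_set * repetitions must be divisible by words_per_trial")
    rng = np.random.default_rng(seed)
    trials: list[tuple[str, tuple[str, ...]]] = []
    for cs in design.context_sets:
        for grp in _schedule_one_set(cs, p, rng):
            trials.append((cs.id, grp))
    order = rng.permutation(len(trials))
    return [
        LearningTrial(index=i, context_id=trials[j][0], word_ids=trials[j][1])
        for i, j in enumerate(order)
    ]


def generate_recall_trials(
    design: ExperimentDesign,
    seed: int,
    n_per_condition: int = 18,
) -> list[RecallTrialSpec]:
    """Free-recall trial sequence: conditions randomly intermixed, and no two
    consecutive trials share a context (so previous-trial and same-context
    error pools never intersect)."""
    if len(design.context_sets) < 2:
        raise ValueError("need >= 2 context sets for the consecutive-context constraint")
    rng = np.random.default_rng(seed)
    conditions = np.repeat(np.asarray(RECALL_CONDITIONS, dtype=object), n_per_condition)
    conditions = rng.permutation(conditions)
    ctx_ids = design.context_ids
    # sequential construction: each trial's context uniform over all but the
    # previous trial's, so no two consecutive trials share a context
    seq = np.empty(len(conditions), dtype=int)
    seq[0] = rng.integers(len(ctx_ids))
    for i in range(1, len(conditions)):
        choices = [c for c in range(len(ctx_ids)) if c != seq[i - 1]]
        seq[i] = rng.choice(choices)
    out = []
    for i, (cond, ci) in enumerate(zip(conditions, seq)):
        cs = design.context_sets[int(ci)]
        targets = tuple(rng.choice(np.asarray(cs.word_ids, dtype=object),
                                   size=design.params.words_per_trial, replace=False))
        out.append(RecallTrialSpec(index=i, context_id=cs.id, target_ids=targets,
                                   condition=str(cond)))
    return out


def generate_dnms_trials(
    design: ExperimentDesign,
    seed: int,
    n_trials: int = 60,
    schedule: list[LearningTrial] | None = None,
) -> list[DNMSTrialSpec]:
    """DNMS trial sequence with equal numbers of target, lure and
    other-context probes.  If a learning ``schedule`` is given, each trial's
    ``overlap`` with it is populated via :func:`compute_overlap`."""
    if n_trials % 3 != 0:
        raise ValueError("n_trials must be divisible by 3")
    if len(design.context_sets) < 2:
        raise ValueError("need >= 2 context sets for other-context probes")
    rng = np.random.default_rng(seed)
    probe_types = rng.permutation(
        np.repeat(np.asarray(PROBE_TYPES, dtype=object), n_trials // 3)
    )
    trials = []
    for i, ptype in enumerate(probe_types):
        cs = design.context_sets[int(rng.integers(len(design.context_sets)))]
        targets = tuple(rng.choice(np.asarray(cs.word_ids, dtype=object),
                                   size=design.params.words_per_trial, replace=False))
        if ptype == "target":
            probe = str(rng.choice(np.asarray(targets, dtype=object)))
            correct = "match"
        elif ptype == "lure":
            pool = [w for w in cs.word_ids if w not in targets]
            probe = str(rng.choice(np.asarray(pool, dtype=object)))
            correct = "mismatch"
        else:
            other_words = [w for other in design.context_sets if other.id != cs.id
                           for w in other.word_ids]
            probe = str(rng.choice(np.asarray(other_words, dtype=object)))
            correct = "mismatch"
        t = DNMSTrialSpec(index=i, context_id=cs.id, target_ids=targets,
                          probe_id=probe, probe_type=str(ptype), correct_response=correct)
        if schedule is not None:
            t = replace(t, overlap=compute_overlap(schedule, t))
        trials.append(t)
    return trials


def compute_overlap(schedule: list[LearningTrial], trial: DNMSTrialSpec) -> int:
    """Count (learning-trial, target) co-presentations of the probe with the
    current targets.  The probe itself is excluded from the target set, so a
    target probe counts only co-presentations with the *other* targets."""
    targets = set(trial.target_ids) - {trial.probe_id}
    seen = False
    total = 0
    for lt in schedule:
        if trial.probe_id in lt.word_ids:
            seen = True
            total += len(targets.intersection(lt.word_ids))
    if not seen:
        raise ValueError(f"probe {trial.probe_id!r} never appears in the schedule")
    return total
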