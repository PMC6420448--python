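"""Synthetic behavior: reinstatement traces, DNMS responses, recall, memory test.

The generative model is deliberately simple and linear.  A latent
*reinstatement trace* assigns each trial x period x context an intensity in
[0, 1]: every context fluctuates around a baseline, and the context the
targets were studied in is elevated by a boost — during the delay period the
boost is scaled by the subject's memory strength (a subject who never
learned the contexts reinstates nothing specific).  The same trace later
drives the synthetic BOLD signal, so decoded evidence and behavior are
coupled through a single latent quantity.

Reaction times are additive on the millisecond scale:

    RT = mu + b_subject + beta[probe_type]
         + gamma_probe * e(probe context, delay) * 1[mismatch trial]
         + gamma_overlap * e(probe context, delay) * overlap * 1[lure trial]
         - gamma_nonprobe * mean_e(nonprobe contexts, delay)
         + eps,   eps ~ N(0, sigma^2)

Responses slower than the 4-second deadline become timeouts (no response);
response errors are injected at rate (1 - accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    DNMSTrialSpec,
    ExperimentDesign,
    LearningTrial,
    RecallTrialSpec,
    generate_dnms_trials,
)

__all__ = [
    "PERIODS",
    "GenerativeParams",
    "ReinstatementTrace",
    "DNMSResponse",
    "MemoryTestResponse",
    "simulate_reinstatement",
    "simulate_dnms",
    "simulate_recall",
    "simulate_memory_test",
    "draw_subjects",
    "simulate_dnms_cohort",
]

PERIODS = ("target_presentation", "delay", "probe_presentation")
TIMEOUT_MS = 4000.0


@dataclass(frozen=True)
class GenerativeParams:
    """Defaults define the study conditions the analyses are tested under.

    RT offsets (ms) are calibrated so that the cohort-level mean z-scored log
    RTs per probe type approximate the reference condition means
    (lure +0.14, target -0.11, other -0.03); error rates and the memory
    parameter are calibrated to the corresponding group-level accuracies.
    """

    # --- free recall ---------------------------------------------------
    # per-word substitution probability by distraction condition
    recall_error_prob: dict = field(
        default_factory=lambda: {"none": 0.016, "break": 0.080, "full": 0.151}
    )
    # mixture over error categories (previous-target, same-context, other)
    error_mix: tuple[float, float, float] = (0.48, 0.31, 0.21)

    # --- DNMS reaction times (ms) --------------------------------------
    rt_mu_ms: float = 910.0
    subject_sd_ms: float = 100.0
    beta_target_ms: float = -1.8
    beta_lure_ms: float = 19.2
    beta_other_ms: float = 0.0
    rt_sigma_ms: float = 150.0
    accuracy: float = 0.95

    # --- latent reinstatement ------------------------------------------
    reinstate_baseline: float = 0.30
    reinstate_boost: float = 0.50
    trace_noise_sd: float = 0.10

    # --- evidence -> RT couplings (ms per intensity unit) ---------------
    gamma_probe_ms: float = 35.0
    gamma_nonprobe_ms: float = 60.0
    gamma_overlap_ms: float = 0.0

    # --- posttask context-memory test ----------------------------------
    pi_mem: float = 0.216  # population mean; group accuracy = pi + (1-pi)/4
    memory_beta_ab: tuple[float, float] = (1.5, 5.44)  # mean 0.216

    def __post_init__(self):
        w = np.asarray(self.error_mix, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("error_mix must be nonnegative and sum to 1")
        for name in ("subject_sd_ms", "rt_sigma_ms", "trace_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def recovery_params(**overrides) -> GenerativeParams:
    """Low-noise generative settings for parameter-recovery experiments.

    Residual RT noise and trace noise are set for power at small cohort
    sizes (12 subjects x 60 trials): sigma = 40 ms and trace SD 0.15 give a
    delay-coupling standard error small enough that recovery and trend
    checks are informative rather than vacuous.  Planted couplings default
    to the study conditions and are overridden per experiment.
    """
    base = dict(rt_sigma_ms=40.0, trace_noise_sd=0.15, subject_sd_ms=60.0)
    base.update(overrides)
    return GenerativeParams(**base)


@dataclass
class ReinstatementTrace:
    """Latent intensities, shape (n_trials, n_periods, n_contexts), in [0, 1]."""

    intensity: np.ndarray
    context_ids: tuple[str, ...]

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != len(PERIODS):
            raise ValueError("intensity must be (n_trials, n_periods, n_contexts)")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1):
            raise ValueError("intensities must lie in [0, 1]")

    def value(self, trial: int, period: str, context_id: str) -> float:
        return float(
            self.intensity[trial, PERIODS.index(period), self.context_ids.index(context_id)]
        )

    def period_matrix(self, period: str) -> np.ndarray:
        """(n_trials, n_contexts) slice for one period."""
        return self.intensity[:, PERIODS.index(period), :]


@dataclass(frozen=True)
class DNMSResponse:
    trial: int
    response: str  # "match", "mismatch" or "none"
    rt_ms: float | None
    accurate: bool

    def __post_init__(self):
        if (self.response == "none") != (self.rt_ms is None):
            raise ValueError("response == 'none' iff rt_ms is absent")
        if self.rt_ms is not None and not (0 < self.rt_ms <= TIMEOUT_MS):
            raise ValueError("rt_ms must lie in (0, 4000]")


@dataclass(frozen=True)
class MemoryTestResponse:
    word_id: str
    chosen_context_id: str
    confidence: int
    correct: bool

    def __post_init__(self):
        if self.confidence not in (1, 2, 3, 4):
            raise ValueError("confidence must be in 1..4")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_reinstatement(
    trials: list[DNMSTrialSpec] | list[RecallTrialSpec],
    design: ExperimentDesign,
    params: GenerativeParams,
    seed,
    memory_strength: float = 1.0,
) -> ReinstatementTrace:
    """Latent per-trial, per-period, per-context reinstatement intensities.

    The target-set context receives ``reinstate_boost`` on top of the shared
    baseline; during the delay the boost is multiplied by the subject's
    ``memory_strength``.  Gaussian noise is added everywhere and the result
    clipped to [0, 1].  With boost = 0 all contexts are exchangeable.
    """
    rng = _rng(seed)
    ctx_ids = design.context_ids
    n = len(trials)
    base = params.reinstate_baseline + rng.normal(
        0.0, params.trace_noise_sd, size=(n, len(PERIODS), len(ctx_ids))
    )
    boost = np.zeros((n, len(PERIODS), len(ctx_ids)))
    delay_idx = PERIODS.index("delay")
    for i, t in enumerate(trials):
        j = ctx_ids.index(t.context_id)
        boost[i, :, j] = params.reinstate_boost
        boost[i, delay_idx, j] = params.reinstate_boost * memory_strength
    return ReinstatementTrace(np.clip(base + boost, 0.0, 1.0), ctx_ids)


def simulate_dnms(
    trials: list[DNMSTrialSpec],
    trace: ReinstatementTrace,
    design: ExperimentDesign,
    params: GenerativeParams,
    seed,
    subject_intercept_ms: float = 0.0,
) -> list[DNMSResponse]:
    """Draw responses and RTs for one subject from the linear RT model."""
    rng = _rng(seed)
    if trace.intensity.shape[0] < len(trials):
        raise ValueError("trace does not cover all trials")
    betas = {
        "target": params.beta_target_ms,
        "lure": params.beta_lure_ms,
        "other": params.beta_other_ms,
    }
    out = []
    delay = trace.period_matrix("delay")
    ctx_index = {c: k for k, c in enumerate(trace.context_ids)}
    for i, t in enumerate(trials):
        probe_ctx = design.context_of(t.probe_id)
        j = ctx_index[probe_ctx]
        e_probe = delay[i, j]
        nonprobe = np.delete(delay[i], j)
        rt = (
            params.rt_mu_ms
            + subject_intercept_ms
            + betas[t.probe_type]
            + params.gamma_probe_ms * e_probe * (t.correct_response == "mismatch")
            + params.gamma_overlap_ms * e_probe * t.overlap * (t.probe_type == "lure")
            - params.gamma_nonprobe_ms * float(nonprobe.mean())
            + rng.normal(0.0, params.rt_sigma_ms)
        )
        accurate = bool(rng.random() < params.accuracy)
        if rt > TIMEOUT_MS or rt <= 0:
            out.append(DNMSResponse(trial=t.index, response="none", rt_ms=None, accurate=False))
            continue
        resp = t.correct_response if accurate else (
            "match" if t.correct_response == "mismatch" else "mismatch"
        )
        out.append(DNMSResponse(trial=t.index, response=resp, rt_ms=float(rt), accurate=accurate))
    return out


def _error_pools(
    trial: RecallTrialSpec,
    prev_trial: RecallTrialSpec | None,
    design: ExperimentDesign,
) -> dict[str, list[str]]:
    targets = set(trial.target_ids)
    prev = [] if prev_trial is None else [w for w in prev_trial.target_ids if w not in targets]
    same = [w for w in design.set_by_id(trial.context_id).word_ids
            if w not in targets and w not in prev]
    other = [w for w in design.words if w not in targets and w not in prev and w not in same]
    return {"previous_target": prev, "same_context": same, "other": other}


def simulate_recall(
    trials: list[RecallTrialSpec],
    design: ExperimentDesign,
    params: GenerativeParams,
    seed,
) -> pd.DataFrame:
    """One subject's recall responses.

    Per trial the number of substitution errors is Binomial(4, p_condition);
    each error's word is drawn from the category mixture.  On the first trial
    the previous-target pool is empty and its mixture mass is reassigned
    proportionally to the remaining categories.
    """
    rng = _rng(seed)
    w = np.asarray(params.error_mix, dtype=float)
    rows = []
    prev = None
    for t in trials:
        p_err = params.recall_error_prob[t.condition]
        n_err = int(rng.binomial(design.params.words_per_trial, p_err))
        pools = _error_pools(t, prev, design)
        weights = w.copy()
        for k, name in enumerate(("previous_target", "same_context", "other")):
            if not pools[name]:
                weights[k] = 0.0
        if weights.sum() == 0:  # all mixture mass sat on empty pools
            weights = np.array([float(bool(pools[n]))
                                for n in ("previous_target", "same_context", "other")])
        weights = weights / weights.sum()
        n_correct = design.params.words_per_trial - n_err
        recalled = list(rng.choice(np.asarray(t.target_ids, dtype=object),
                                   size=n_correct, replace=False))
        used: set[str] = set()
        for _ in range(n_err):
            name = ("previous_target", "same_context", "other")[
                int(rng.choice(3, p=weights))
            ]
            avail = [x for x in pools[name] if x not in used]
            if not avail:  # tiny pool exhausted; fall back to the union
                avail = [x for pool in pools.values() for x in pool if x not in used]
            word = str(rng.choice(np.asarray(avail, dtype=object)))
            used.add(word)
            recalled.append(word)
        rows.append(
            {"trial": t.index, "condition": t.condition,
             "response_words": " ".join(recalled)}
        )
        prev = t
    return pd.DataFrame(rows)


def simulate_memory_test(
    design: ExperimentDesign,
    params: GenerativeParams,
    seed,
    pi_mem: float | None = None,
) -> list[MemoryTestResponse]:
    """Posttask context-memory test: every word judged against all contexts.

    A word's context is *known* with probability ``pi_mem``; otherwise the
    subject guesses uniformly over the contexts.  Confidence is drawn higher
    for correct responses than for incorrect ones.
    """
    rng = _rng(seed)
    pi = params.pi_mem if pi_mem is None else pi_mem
    ctx_ids = design.context_ids
    out = []
    for word in design.words:
        true_ctx = design.context_of(word)
        if rng.random() < pi:
            chosen = true_ctx
        else:
            chosen = str(rng.choice(np.asarray(ctx_ids, dtype=object)))
        correct = chosen == true_ctx
        conf = 1 + int(rng.binomial(3, 0.75 if correct else 0.35))
        out.append(MemoryTestResponse(word_id=word, chosen_context_id=chosen,
                                      confidence=conf, correct=correct))
    return out


def draw_subjects(params: GenerativeParams, n_subjects: int, seed) -> pd.DataFrame:
    """Subject-level random effects: RT intercept and memory strength.

    Memory strength ~ Beta(a, b) gates both the delay-period reinstatement
    boost and the posttask memory test, so the behavioral memory score and
    the neural coupling share a common cause.
    """
    rng = _rng(seed)
    a, b = params.memory_beta_ab
    return pd.DataFrame(
        {
            "subject": [f"s{i:03d}" for i in range(n_subjects)],
            "intercept_ms": rng.normal(0.0, params.subject_sd_ms, size=n_subjects),
            "memory_strength": rng.beta(a, b, size=n_subjects),
        }
    )


def simulate_dnms_cohort(
    design: ExperimentDesign,
    params: GenerativeParams,
    n_subjects: int,
    seed: int,
    n_trials: int = 60,
    schedule: list[LearningTrial] | None = None,
) -> dict:
    """Simulate a DNMS cohort: per-subject trials, traces, responses, memory.

    Returns a dict with ``responses`` (tidy DataFrame), ``subjects``,
    ``memory`` (one row per subject x word), and per-subject ``trials`` and
    ``traces`` keyed by subject id.
    """
    root = np.random.default_rng(seed)
    subjects = draw_subjects(params, n_subjects, root)
    resp_rows, mem_rows = [], []
    trials_by_subject: dict[str, list[DNMSTrialSpec]] = {}
    traces_by_subject: dict[str, ReinstatementTrace] = {}
    for _, subj in subjects.iterrows():
        sid = subj["subject"]
        trial_seed = int(root.integers(2**31))
        trials = generate_dnms_trials(design, trial_seed, n_trials=n_trials,
                                      schedule=schedule)
        trace = simulate_reinstatement(trials, design, params, root,
                                       memory_strength=float(subj["memory_strength"]))
        responses = simulate_dnms(trials, trace, design, params, root,
                                  subject_intercept_ms=float(subj["intercept_ms"]))
        mem = simulate_memory_test(design, params, root,
                                   pi_mem=float(subj["memory_strength"]))
        trials_by_subject[sid] = trials
        traces_by_subject[sid] = trace
        for t, r in zip(trials, responses):
            resp_rows.append(
                {"subject": sid, "trial": t.index, "probe_type": t.probe_type,
                 "context_id": t.context_id, "probe_id": t.probe_id,
                 "overlap": t.overlap, "correct_response": t.correct_response,
                 "response": r.response, "rt_ms": r.rt_ms, "accurate": r.accurate}
            )
        for m in mem:
            mem_rows.append(
                {"subject": sid, "word_id": m.word_id,
                 "chosen_context_id": m.chosen_context_id,
                 "confidence": m.confidence, "correct": m.correct}
            )
    return {
        "subjects": subjects,
        "responses": pd.DataFrame(resp_rows),
        "memory": pd.DataFrame(mem_rows),
        "trials": trials_by_subject,
        "traces": traces_by_subject,
    }
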