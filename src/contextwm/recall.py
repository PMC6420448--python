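"""Free-recall scoring, substitution-error taxonomy, and the bootstrap null.

Substitution errors fall into three disjoint pools relative to the current
trial: the 4 previous-trial targets, the 8 same-context non-targets, and the
remaining studied words (56 in the six-set design; 4 + 8 + 56 = 68
candidate words in total).  The chance analysis asks whether a category is
over-represented relative to errors drawn uniformly from those 68 words.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign, RecallTrialSpec

__all__ = [
    "ERROR_CATEGORIES",
    "BootstrapResult",
    "score_recall",
    "categorize_error",
    "categorize_subject_errors",
    "bootstrap_category_null",
    "condition_error_test",
]

ERROR_CATEGORIES = ("previous_target", "same_context", "other")


@dataclass(frozen=True)
class BootstrapResult:
    category: str
    observed_mean: float  # per-subject mean count
    null_mean: float
    null_sd: float
    B: int
    p: float
    degenerate: bool = False


def score_recall(
    spec: RecallTrialSpec,
    response_words: list[str],
    design: ExperimentDesign,
) -> tuple[int, list[str]]:
    """Score one trial: (number of targets recalled, substitution errors).

    Out-of-vocabulary tokens are dropped (and can be logged by the caller);
    repeated responses count once.
    """
    vocab = set(design.words)
    seen: list[str] = []
    for w in response_words:
        if w in vocab and w not in seen:
            seen.append(w)
    targets = set(spec.target_ids)
    n_correct = sum(1 for w in seen if w in targets)
    errors = [w for w in seen if w not in targets]
    return n_correct, errors


def categorize_error(
    word: str,
    trial: RecallTrialSpec,
    prev_trial: RecallTrialSpec | None,
    design: ExperimentDesign,
) -> str:
    """Assign a substitution error to previous_target / same_context / other.

    Precedence previous_target > same_context; with the consecutive-context
    design constraint the two pools never intersect, so precedence is moot.
    """
    if word in trial.target_ids:
        raise ValueError("current targets are correct recalls, not errors")
    if word not in design.words:
        raise ValueError(f"{word!r} is not in the experiment vocabulary")
    if prev_trial is not None and word in prev_trial.target_ids:
        return "previous_target"
    if word in design.set_by_id(trial.context_id).word_ids:
        return "same_context"
    return "other"


def categorize_subject_errors(
    trials: list[RecallTrialSpec],
    responses: pd.DataFrame,
    design: ExperimentDesign,
    subject: str = "s000",
) -> pd.DataFrame:
    """Score and categorize a subject's recall responses.

    ``responses`` has one row per trial with columns ``trial`` and
    ``response_words`` (space-separated).  Returns one row per error.
    """
    by_index = {t.index: t for t in trials}
    rows = []
    prev = None
    for t in trials:
        resp = responses.loc[responses["trial"] == t.index, "response_words"]
        words = str(resp.iloc[0]).split() if len(resp) else []
        _, errors = score_recall(t, words, design)
        for w in errors:
            rows.append(
                {"subject": subject, "trial": t.index, "condition": t.condition,
                 "word_id": w, "category": categorize_error(w, t, prev, design)}
            )
        prev = t
    return pd.DataFrame(rows, columns=["subject", "trial", "condition", "word_id", "category"])


def bootstrap_category_null(
    per_subject_errors: pd.DataFrame,
    category: str,
    category_pool_size: int,
    total_pool: int = 68,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Bootstrap chance analysis for one error category.

    ``per_subject_errors`` has columns ``subject`` and ``category``.  Each
    iteration replaces each subject's observed errors with uniform draws
    over the ``total_pool`` candidate words — the category count is then
    Binomial(n_subject_errors, k / total_pool) — and averages counts across
    subjects.  One-sided add-one p: (1 + #{null >= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if category_pool_size > total_pool:
        raise ValueError("category pool larger than total pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = per_subject_errors.groupby("subject").size()
    n_subjects = len(counts)
    if n_subjects == 0 or counts.sum() == 0:
        return BootstrapResult(category=category, observed_mean=0.0, null_mean=0.0,
                               null_sd=0.0, B=B, p=1.0, degenerate=True)
    observed = (
        per_subject_errors.groupby("subject")
        .apply(lambda g: (g["category"] == category).sum(), include_groups=False)
        .reindex(counts.index, fill_value=0)
        .mean()
    )
    p_cat = category_pool_size / total_pool
    n_i = counts.to_numpy()
    null = rng.binomial(n_i[None, :].repeat(B, axis=0), p_cat).mean(axis=1)
    p = (1.0 + float(np.sum(null >= observed))) / (B + 1.0)
    return BootstrapResult(category=category, observed_mean=float(observed),
                           null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
                           B=B, p=p)


def condition_error_test(per_subject_totals: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t tests on per-subject error totals between the three
    distraction conditions.

    ``per_subject_totals`` has columns ``subject``, ``condition``, ``n_errors``.
    """
    wide = per_subject_totals.pivot(index="subject", columns="condition", values="n_errors")
    if wide.isna().any().any() or len(wide) < 2:
        raise ValueError("need >= 2 subjects with totals for every condition")
    pairs = [("full", "break"), ("full", "none"), ("break", "none")]
    rows = []
    for a, b in pairs:
        diff = wide[a] - wide[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
        rows.append({"contrast": f"{a}_vs_{b}", "t": float(t), "df": len(wide) - 1,
                     "p": float(p), "mean_diff": float(diff.mean())})
    return pd.DataFrame(rows)
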