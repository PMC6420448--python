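"""Reaction-time pipeline: exclusions, within-subject zRT, probe contrasts.

RTs are natural-log transformed and z-scored within subject (ddof = 1) to
absorb between-subject differences in mean speed and the right skew of raw
RT distributions.  Probe-type effects are then tested with paired t tests
on per-subject condition means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "apply_exclusions",
    "zscore_log_rt",
    "probe_type_contrasts",
    "target_memory_scores",
    "split_by_target_memory",
]


def apply_exclusions(
    responses: pd.DataFrame,
    chance_accuracy: float = 2.0 / 3.0,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Apply subject- and trial-level exclusions.

    Subjects whose overall accuracy is strictly below ``chance_accuracy``
    (the rate of a constant-"mismatch" responder when probe types are
    balanced) are removed entirely.  Timeout trials (no response) are
    removed; inaccurate trials are kept but flagged ``included=False`` so RT
    analyses skip them while accuracy summaries retain them.

    Returns (kept trials, excluded subject ids, excluded trials).
    """
    df = responses.copy()
    acc = df.groupby("subject")["accurate"].mean()
    bad_subjects = sorted(acc.index[acc < chance_accuracy])
    excl_subj = df["subject"].isin(bad_subjects)
    timeout = df["response"].eq("none") | df["rt_ms"].isna()
    excluded = df[excl_subj | timeout].copy()
    excluded["exclusion_reason"] = np.where(
        excl_subj[excl_subj | timeout], "below_chance_subject", "no_response"
    )
    kept = df[~excl_subj & ~timeout].copy()
    kept["included"] = kept["accurate"].astype(bool)
    kept["exclusion_reason"] = np.where(kept["included"], None, "inaccurate")
    return kept, bad_subjects, excluded


def zscore_log_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``log_rt`` and within-subject ``zrt`` columns over included trials.

    zrt = (ln rt - subject mean ln rt) / subject SD ln rt (ddof = 1).
    Subjects with fewer than 2 included trials or zero log-RT variance are
    flagged ``zrt_valid=False`` and get NaN zrt.
    """
    df = trials.copy()
    if "included" not in df:
        df["included"] = True
    df["log_rt"] = np.log(df["rt_ms"].astype(float))
    df["zrt"] = np.nan
    df["zrt_valid"] = False
    for sid, g in df[df["included"]].groupby("subject"):
        if len(g) < 2:
            continue
        sd = g["log_rt"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        df.loc[g.index, "zrt"] = (g["log_rt"] - g["log_rt"].mean()) / sd
        df.loc[df["subject"] == sid, "zrt_valid"] = True
    return df


def _paired_t(wide: pd.DataFrame, a: str, b: str) -> dict:
    diff = wide[a] - wide[b]
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(wide[a], wide[b])
    return {"contrast": f"{a}_vs_{b}", "t": float(t), "df": int(len(wide) - 1),
            "p": float(p), "mean_diff": float(diff.mean()),
            f"mean_{a}": float(wide[a].mean()), f"mean_{b}": float(wide[b].mean())}


def probe_type_contrasts(zrt_table: pd.DataFrame, value: str = "zrt") -> pd.DataFrame:
    """Paired t tests (lure vs other, lure vs target, target vs other) on
    per-subject probe-type means of ``value`` over included, zrt-valid
    trials.  Subjects missing a probe type are dropped."""
    df = zrt_table
    mask = df.get("included", pd.Series(True, index=df.index)).astype(bool)
    if value == "zrt":
        mask &= df["zrt_valid"].astype(bool) & df["zrt"].notna()
    means = (
        df[mask].groupby(["subject", "probe_type"])[value].mean().unstack("probe_type")
    )
    means = means.dropna()
    if len(means) < 2:
        raise ValueError("need >= 2 subjects with all probe types")
    rows = [_paired_t(means, a, b)
            for a, b in (("lure", "other"), ("lure", "target"), ("target", "other"))]
    return pd.DataFrame(rows)


def target_memory_scores(
    responses: pd.DataFrame,
    memory: pd.DataFrame,
    trials_by_subject: dict,
) -> pd.DataFrame:
    """Per-trial TargetMemoryScore: of the 4 target words, how many were
    assigned to the correct context in the posttask memory test (0-4).

    Trials whose target words were not all tested are dropped (returned
    without a score is impossible; they simply do not appear).
    """
    mem_correct = {
        (r.subject, r.word_id): bool(r.correct) for r in memory.itertuples()
    }
    rows = []
    for sid, trials in trials_by_subject.items():
        for t in trials:
            vals = [mem_correct.get((sid, w)) for w in t.target_ids]
            if any(v is None for v in vals):
                continue
            rows.append({"subject": sid, "trial": t.index,
                         "target_memory_score": int(sum(vals))})
    return pd.DataFrame(rows)


def split_by_target_memory(
    zrt_table: pd.DataFrame,
    scores: pd.DataFrame,
    threshold: float = 0.5,
) -> dict:
    """Split trials by whether the target context was learned and run the
    lure-vs-other contrast within each subset.

    A trial is *learned* iff target_memory_score / 4 > ``threshold``.
    Returns {"learned": df, "unlearned": df, "contrasts": {subset: table}}.
    """
    merged = zrt_table.merge(scores, on=["subject", "trial"], how="inner")
    learned_mask = merged["target_memory_score"] / 4.0 > threshold
    out = {"learned": merged[learned_mask], "unlearned": merged[~learned_mask],
           "contrasts": {}}
    for name in ("learned", "unlearned"):
        sub = out[name]
        try:
            out["contrasts"][name] = probe_type_contrasts(sub)
        except ValueError:
            out["contrasts"][name] = None
    return out
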