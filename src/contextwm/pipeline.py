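"""End-to-end synthetic experiments and the real-data entry point.

Seed discipline: a single run seed expands into per-stage seeds through
:func:`child_seed` (CRC32 of the stage name mixed into a SeedSequence), so
any stage can be re-run in isolation and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cwio
from .behavior import (
    PERIODS,
    GenerativeParams,
    simulate_dnms_cohort,
    simulate_recall,
)
from .bold import (
    BoldParams,
    context_class,
    make_pattern_bank,
    simulate_dnms_run,
    simulate_localizer_run,
)
from .design import (
    DesignParams,
    ExperimentDesign,
    build_design,
    exp1_design_params,
    exp3_design_params,
    generate_learning_schedule,
    generate_recall_trials,
)
from .models import model1, model2, model3
from .mvpa import (
    crossval_accuracy,
    extract_trial_evidence,
    label_localizer_trs,
    score_evidence,
    split_folds_by_time,
    target_context_contrast,
    train_evidence_model,
)
from .recall import (
    ERROR_CATEGORIES,
    bootstrap_category_null,
    categorize_subject_errors,
    condition_error_test,
)
from .rt import (
    apply_exclusions,
    probe_type_contrasts,
    split_by_target_memory,
    target_memory_scores,
    zscore_log_rt,
)

__all__ = [
    "RunConfig",
    "RECOVERY_RIDGE",
    "child_seed",
    "run_exp1",
    "run_exp2",
    "evidence_from_traces",
    "decode_subject_evidence",
    "build_model_table",
    "run_exp3",
    "run_synthetic_experiment",
    "analyze_real_data",
]


#: Ridge strength used with the low-noise recovery acquisition; strong
#: regularization keeps the logistic probability readout in its linear
#: range so planted couplings are recoverable on the evidence scale.
RECOVERY_RIDGE = 50.0


def child_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    mode: str = "exp2"  # exp1 | exp2 | exp3
    seed: int = 0
    n_subjects: int = 80
    n_trials: int = 60
    n_recall_per_condition: int = 18
    params: GenerativeParams = field(default_factory=GenerativeParams)
    bold: BoldParams = field(default_factory=BoldParams)
    bootstrap_B: int = 10_000
    lam: float = 1.0
    shift_s: float = 5.0
    window_s: float = 6.0
    gap_trs: int = 1
    chance_accuracy: float = 2.0 / 3.0
    out_dir: str | None = None


# ---------------------------------------------------------------------------
# Experiment 1: free recall with distraction
# ---------------------------------------------------------------------------

def run_exp1(config: RunConfig) -> dict:
    """Simulate a free-recall cohort and run the error analyses."""
    design = build_design(exp1_design_params(), child_seed(config.seed, "design"))
    n_sub = config.n_subjects
    error_rows, total_rows = [], []
    rng = np.random.default_rng(child_seed(config.seed, "exp1-behavior"))
    for s in range(n_sub):
        sid = f"s{s:03d}"
        trials = generate_recall_trials(
            design, int(rng.integers(2**31)), n_per_condition=config.n_recall_per_condition
        )
        responses = simulate_recall(trials, design, config.params, rng)
        errors = categorize_subject_errors(trials, responses, design, subject=sid)
        error_rows.append(errors)
        counts = errors.groupby("condition").size() if len(errors) else pd.Series(dtype=int)
        for cond in ("none", "break", "full"):
            total_rows.append({"subject": sid, "condition": cond,
                               "n_errors": int(counts.get(cond, 0))})
    errors = pd.concat(error_rows, ignore_index=True)
    totals = pd.DataFrame(total_rows)
    pool_sizes = {"previous_target": 4, "same_context": 8, "other": 56}
    boot_rng = np.random.default_rng(child_seed(config.seed, "exp1-bootstrap"))
    bootstrap = {}
    for cond in ("none", "break", "full"):
        cond_err = errors[errors["condition"] == cond]
        bootstrap[cond] = {
            cat: bootstrap_category_null(cond_err, cat, pool_sizes[cat],
                                         B=config.bootstrap_B, seed=boot_rng)
            for cat in ERROR_CATEGORIES
        }
    return {
        "design": design,
        "errors": errors,
        "totals": totals,
        "bootstrap": bootstrap,
        "condition_tests": condition_error_test(totals),
    }


# ---------------------------------------------------------------------------
# Experiment 2: DNMS reaction times
# ---------------------------------------------------------------------------

def run_exp2(config: RunConfig, design_params: DesignParams | None = None) -> dict:
    """Simulate a DNMS cohort and run exclusions, zRT, and probe contrasts."""
    dp = design_params or DesignParams(
        n_sets=4, context_kinds=tuple(("scene", "none") for _ in range(4))
    )
    design = build_design(dp, child_seed(config.seed, "design"))
    schedule = generate_learning_schedule(design, child_seed(config.seed, "learning"))
    cohort = simulate_dnms_cohort(
        design, config.params, config.n_subjects,
        child_seed(config.seed, "exp2-cohort"),
        n_trials=config.n_trials, schedule=schedule,
    )
    kept, excluded_subjects, excluded = apply_exclusions(
        cohort["responses"], chance_accuracy=config.chance_accuracy
    )
    zrt = zscore_log_rt(kept)
    contrasts = probe_type_contrasts(zrt)
    mean_zrt = (
        zrt[zrt["included"] & zrt["zrt"].notna()]
        .groupby(["subject", "probe_type"])["zrt"].mean()
        .groupby("probe_type").mean()
    )
    return {
        "design": design,
        "schedule": schedule,
        "cohort": cohort,
        "kept": kept,
        "excluded_subjects": excluded_subjects,
        "excluded": excluded,
        "zrt": zrt,
        "contrasts": contrasts,
        "mean_zrt": mean_zrt,
    }


# ---------------------------------------------------------------------------
# Evidence sources for the mixed models
# ---------------------------------------------------------------------------

def evidence_from_traces(cohort: dict, design: ExperimentDesign) -> pd.DataFrame:
    """Per-trial, per-period probe-context and nonprobe-context evidence read
    directly from the latent traces (the noiseless-measurement path used by
    fast analyses and null calibrations)."""
    rows = []
    for sid, trials in cohort["trials"].items():
        trace = cohort["traces"][sid]
        ctx_idx = {c: k for k, c in enumerate(trace.context_ids)}
        for i, t in enumerate(trials):
            j = ctx_idx[design.context_of(t.probe_id)]
            row = {"subject": sid, "trial": t.index}
            for p, period in enumerate(PERIODS):
                vals = trace.intensity[i, p, :]
                row[f"ev_{period}"] = float(vals[j])
                row[f"ev_nonprobe_{period}"] = float(np.delete(vals, j).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def decode_subject_evidence(
    trials,
    trace,
    design: ExperimentDesign,
    bold_params: BoldParams,
    seed: int,
    lam: float = 1.0,
    shift_s: float = 5.0,
    window_s: float = 6.0,
    gap_trs: int = 1,
    return_accuracy: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, float]:
    """Simulate one subject's localizer + task runs, train the evidence
    model, decode the task run, and return trial-period evidence."""
    rng = np.random.default_rng(seed)
    bank = make_pattern_bank(bold_params.n_voxels, bold_params.selectivity, seed=rng)
    loc_run, loc_events = simulate_localizer_run(bank, bold_params, rng)
    labels = split_folds_by_time(
        label_localizer_trs(loc_events, loc_run.n_trs, loc_run.tr_seconds, shift_s)
    )
    lab = labels.labeled
    model = train_evidence_model(loc_run.data[lab["tr"].to_numpy()],
                                 lab["label"].to_numpy(), lam=lam)
    acc = crossval_accuracy(loc_run.data, labels, lam=lam) if return_accuracy else None
    task_run, task_events = simulate_dnms_run(trials, trace, bank, design, bold_params, rng)
    ev = score_evidence(model, task_run)
    per_period = extract_trial_evidence(
        ev, task_events, model.classes, tr_seconds=task_run.tr_seconds,
        shift_s=shift_s, window_s=window_s, gap_trs=gap_trs,
    )
    # project class evidence onto probe / target / nonprobe context scalars
    cls_of_ctx = {c.id: context_class(design, c.id) for c in design.context_sets}
    by_index = {t.index: t for t in trials}
    rows = []
    for trial_idx, g in per_period.groupby("trial"):
        t = by_index[int(trial_idx)]
        probe_cls = cls_of_ctx[design.context_of(t.probe_id)]
        target_cls = cls_of_ctx[t.context_id]
        row = {"trial": int(trial_idx)}
        for r in g.itertuples():
            rec = g.loc[r.Index]
            probe_ev = float(rec[probe_cls])
            others = [float(rec[c]) for c in model.classes if c != probe_cls]
            row[f"ev_{r.period}"] = probe_ev
            row[f"ev_nonprobe_{r.period}"] = float(np.mean(others))
            row[f"ev_target_{r.period}"] = float(rec[target_cls])
            row[f"ev_nontarget_{r.period}"] = float(
                np.mean([float(rec[c]) for c in model.classes if c != target_cls])
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return (out, acc) if return_accuracy else out


def build_model_table(
    responses: pd.DataFrame,
    evidence: pd.DataFrame,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join behavior, evidence and memory into the mixed-model input table.

    Keeps accurate, responded trials only (the models' stated estimation
    sample); ``overlap`` rides along from the responses table.
    """
    df = responses.merge(evidence, on=["subject", "trial"], how="inner")
    if scores is not None:
        df = df.merge(scores, on=["subject", "trial"], how="inner")
    df = df[df["response"].ne("none") & df["rt_ms"].notna() & df["accurate"]]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Experiment 3: DNMS + decoding + mixed models
# ---------------------------------------------------------------------------

def run_exp3(config: RunConfig, use_bold: bool = True) -> dict:
    """Full chain: design -> behavior (+BOLD) -> decode -> Models 1-3."""
    design = build_design(exp3_design_params(), child_seed(config.seed, "design"))
    schedule = generate_learning_schedule(design, child_seed(config.seed, "learning"))
    cohort = simulate_dnms_cohort(
        design, config.params, config.n_subjects,
        child_seed(config.seed, "exp3-cohort"),
        n_trials=config.n_trials, schedule=schedule,
    )
    if use_bold:
        ev_frames = []
        accs = []
        for k, (sid, trials) in enumerate(cohort["trials"].items()):
            ev = decode_subject_evidence(
                trials, cohort["traces"][sid], design, config.bold,
                seed=child_seed(config.seed, f"bold-{sid}"), lam=config.lam,
                shift_s=config.shift_s, window_s=config.window_s, gap_trs=config.gap_trs,
                return_accuracy=True,
            )
            ev, acc = ev
            ev.insert(0, "subject", sid)
            ev_frames.append(ev)
            accs.append(acc)
        evidence = pd.concat(ev_frames, ignore_index=True)
        cv_accuracy = float(np.mean(accs))
    else:
        evidence = evidence_from_traces(cohort, design)
        cv_accuracy = None
    scores = target_memory_scores(cohort["responses"], cohort["memory"], cohort["trials"])
    kept, excluded_subjects, _ = apply_exclusions(
        cohort["responses"], chance_accuracy=config.chance_accuracy
    )
    zrt = zscore_log_rt(kept)
    table = build_model_table(kept, evidence, scores)
    fits = {
        "model1": model1(table),
        "model2": {pt: model2(table, pt) for pt in ("lure", "other", "target")},
        "model2_nonprobe": {pt: model2(table, pt, evidence_source="nonprobe")
                            for pt in ("lure", "other")},
        "model3": model3(table),
    }
    # delay-period target-vs-nontarget evidence contrast
    if use_bold:
        diffs = (
            evidence.assign(diff=evidence["ev_target_delay"] - evidence["ev_nontarget_delay"])
            [["subject", "diff"]]
        )
        reinstatement_test = target_context_contrast(diffs)
    else:
        reinstatement_test = None
    memory_split = split_by_target_memory(zrt, scores)
    return {
        "design": design,
        "schedule": schedule,
        "cohort": cohort,
        "evidence": evidence,
        "scores": scores,
        "zrt": zrt,
        "table": table,
        "fits": fits,
        "cv_accuracy": cv_accuracy,
        "reinstatement_test": reinstatement_test,
        "memory_split": memory_split,
        "excluded_subjects": excluded_subjects,
    }


def run_synthetic_experiment(config: RunConfig) -> dict:
    """Dispatch on config.mode; optionally write a report bundle."""
    stage = config.mode
    try:
        if config.mode == "exp1":
            result = run_exp1(config)
        elif config.mode == "exp2":
            result = run_exp2(config)
        elif config.mode == "exp3":
            result = run_exp3(config)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"stage {stage!r} failed (config seed {config.seed})") from exc
    if config.out_dir is not None:
        _write_report(config, result)
    return result


def _fit_to_records(fit) -> list[dict]:
    return fit.params.reset_index(names="term").to_dict(orient="records")


def _write_report(config: RunConfig, result: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cwio.write_yaml(dataclasses.asdict(config), out / "config.yaml")
    cwio.write_design(result["design"], out / "design")
    summary: dict = {"mode": config.mode, "seed": config.seed}
    if config.mode == "exp1":
        cwio.write_tsv(result["errors"], out / "errors.tsv")
        cwio.write_tsv(result["totals"], out / "error_totals.tsv")
        cwio.write_tsv(result["condition_tests"], out / "condition_tests.tsv")
        summary["bootstrap"] = {
            cond: {cat: dataclasses.asdict(r) for cat, r in by_cat.items()}
            for cond, by_cat in result["bootstrap"].items()
        }
    else:
        cwio.write_tsv(result["cohort"]["responses"], out / "responses.tsv")
        cwio.write_tsv(result["cohort"]["memory"], out / "memory.tsv")
        cwio.write_tsv(result["zrt"], out / "zrt.tsv")
        if "contrasts" in result:
            cwio.write_tsv(result["contrasts"], out / "contrasts.tsv")
            summary["mean_zrt"] = result["mean_zrt"].to_dict()
        if "fits" in result:
            cwio.write_tsv(result["table"], out / "model_table.tsv")
            summary["fits"] = {
                "model1": _fit_to_records(result["fits"]["model1"]),
                "model2": {k: _fit_to_records(v) for k, v in result["fits"]["model2"].items()},
                "model3": _fit_to_records(result["fits"]["model3"]),
            }
            summary["cv_accuracy"] = result["cv_accuracy"]
            summary["reinstatement_test"] = result["reinstatement_test"]
    summary["decision_parameters"] = {
        "bootstrap_B": config.bootstrap_B, "lam": config.lam,
        "shift_s": config.shift_s, "window_s": config.window_s,
        "gap_trs": config.gap_trs, "chance_accuracy": config.chance_accuracy,
        "zrt_transform": "ln + within-subject z (ddof=1)",
        "trial_type_reference": "other", "overlap_centering": "uncentered",
        "learned_threshold": "> 0.5 of targets",
    }
    cwio.write_json(summary, out / "summary.json")


# ---------------------------------------------------------------------------
# Real-data path
# ---------------------------------------------------------------------------

def analyze_real_data(
    localizer_bold,
    localizer_events,
    task_bold,
    task_events,
    mask,
    behavior: pd.DataFrame,
    config: RunConfig,
    design: ExperimentDesign,
    discard_volumes: int = 0,
    highpass_cutoff_s: float | None = None,
) -> dict:
    """Decode evidence from NIfTI inputs and fit the RT models.

    ``behavior`` must carry subject, trial, probe_type, overlap, response,
    rt_ms, accurate.  Events TSVs follow the synthetic schema (onset,
    duration, trial_type, block, trial).
    """
    from .bold import highpass as hp
    from .io import load_masked_series, read_tsv

    for name, val in (("mask", mask), ("localizer_bold", localizer_bold),
                      ("task_bold", task_bold)):
        if val is None:
            raise ValueError(f"missing required input: {name}")
    loc_run = load_masked_series(localizer_bold, mask, discard_volumes=discard_volumes,
                                 label="localizer")
    task_run = load_masked_series(task_bold, mask, discard_volumes=discard_volumes,
                                  label="dnms")
    if highpass_cutoff_s:
        loc_run = hp(loc_run, highpass_cutoff_s)
        task_run = hp(task_run, highpass_cutoff_s)
    loc_events = localizer_events if isinstance(localizer_events, pd.DataFrame) \
        else read_tsv(localizer_events)
    tsk_events = task_events if isinstance(task_events, pd.DataFrame) \
        else read_tsv(task_events)
    required = {"onset", "duration", "trial_type", "block", "trial"}
    for nm, ev in (("localizer_events", loc_events), ("task_events", tsk_events)):
        missing = required - set(ev.columns)
        if missing:
            raise ValueError(f"{nm} is missing columns: {sorted(missing)}")
    labels = split_folds_by_time(
        label_localizer_trs(loc_events, loc_run.n_trs, loc_run.tr_seconds, config.shift_s)
    )
    lab = labels.labeled
    model = train_evidence_model(loc_run.data[lab["tr"].to_numpy()],
                                 lab["label"].to_numpy(), lam=config.lam)
    cv_acc = crossval_accuracy(loc_run.data, labels, lam=config.lam)
    ev = score_evidence(model, task_run)
    per_period = extract_trial_evidence(
        ev, tsk_events, model.classes, tr_seconds=task_run.tr_seconds,
        shift_s=config.shift_s, window_s=config.window_s, gap_trs=config.gap_trs,
    )
    return {"model": model, "cv_accuracy": cv_acc, "evidence": per_period,
            "behavior": behavior}
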