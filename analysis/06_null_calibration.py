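"""Type-I calibration of the whole significance chain under a null generator.

Zeroes every planted effect (equal recall error rates across conditions, no
probe-type RT offsets, no evidence-RT couplings) and measures how often
each test in the chain rejects at alpha = .05: the three condition t tests,
the three probe-type zRT contrasts, and the headline terms of Models 1-3
fit on latent-trace evidence.  Rates should sit near 5%.
"""

import sys

import numpy as np
import pandas as pd

from contextwm.behavior import GenerativeParams, simulate_dnms_cohort, simulate_recall
from contextwm.design import (
    build_design,
    exp1_design_params,
    exp3_design_params,
    generate_learning_schedule,
    generate_recall_trials,
)
from contextwm.models import model1, model2, model3
from contextwm.pipeline import build_model_table, evidence_from_traces
from contextwm.recall import categorize_subject_errors, condition_error_test
from contextwm.rt import (
    apply_exclusions,
    probe_type_contrasts,
    target_memory_scores,
    zscore_log_rt,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_REP = int(sys.argv[2]) if len(sys.argv) > 2 else 150


def main():
    null = GenerativeParams(
        recall_error_prob={"none": 0.08, "break": 0.08, "full": 0.08},
        beta_target_ms=0.0, beta_lure_ms=0.0, beta_other_ms=0.0,
        gamma_probe_ms=0.0, gamma_nonprobe_ms=0.0, gamma_overlap_ms=0.0,
    )
    d1 = build_design(exp1_design_params(), SEED + 101)
    d3 = build_design(exp3_design_params(), SEED + 102)
    sched = generate_learning_schedule(d3, SEED + 103)
    rng = np.random.default_rng(SEED)
    rej = {k: 0 for k in ("full_vs_break", "full_vs_none", "break_vs_none",
                          "lure_vs_other", "lure_vs_target", "target_vs_other",
                          "m1_interaction", "m2_delay", "m3_interaction")}
    n_models = 0
    for rep in range(N_REP):
        totals = []
        for s in range(15):
            trials = generate_recall_trials(d1, int(rng.integers(2**31)))
            resp = simulate_recall(trials, d1, null, rng)
            errs = categorize_subject_errors(trials, resp, d1, subject=f"s{s}")
            counts = errs.groupby("condition").size() if len(errs) else pd.Series(dtype=int)
            for cond in ("none", "break", "full"):
                totals.append({"subject": f"s{s}", "condition": cond,
                               "n_errors": int(counts.get(cond, 0))})
        ct = condition_error_test(pd.DataFrame(totals)).set_index("contrast")
        for k in ("full_vs_break", "full_vs_none", "break_vs_none"):
            rej[k] += ct.loc[k, "p"] < 0.05
        cohort = simulate_dnms_cohort(d3, null, 10, int(rng.integers(2**31)),
                                      n_trials=30, schedule=sched)
        kept, _, _ = apply_exclusions(cohort["responses"])
        pc = probe_type_contrasts(zscore_log_rt(kept)).set_index("contrast")
        for k in ("lure_vs_other", "lure_vs_target", "target_vs_other"):
            rej[k] += pc.loc[k, "p"] < 0.05
        scores = target_memory_scores(cohort["responses"], cohort["memory"],
                                      cohort["trials"])
        table = build_model_table(kept, evidence_from_traces(cohort, d3), scores)
        try:
            f1, f2, f3 = model1(table), model2(table, "lure"), model3(table)
        except (ValueError, np.linalg.LinAlgError):
            continue
        n_models += 1
        rej["m1_interaction"] += f1.p("target_memory_score:probe_type[T.lure]") < 0.05
        rej["m2_delay"] += f2.p("ev_delay") < 0.05
        rej["m3_interaction"] += f3.p("ev_delay:overlap") < 0.05

    print(f"rejection rates at alpha=.05 over {N_REP} null replicates:")
    for name, hits in rej.items():
        n = n_models if name.startswith("m") else N_REP
        print(f"  {name:>16}: {hits / n:.3f}")


if __name__ == "__main__":
    main()
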