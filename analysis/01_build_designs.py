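"""Build the behavioral and imaging experiment designs and inspect them.

Writes the serialized designs plus learning/recall/DNMS trial tables under
results/designs/, and prints structural summaries: per-word presentation
counts, per-condition trial counts, probe-type pools, and the distribution
of the probe-target overlap statistic.
"""

import collections
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from contextwm import io as cwio
from contextwm.design import (
    build_design,
    exp1_design_params,
    exp3_design_params,
    generate_dnms_trials,
    generate_learning_schedule,
    generate_recall_trials,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/designs")


def main():
    exp1 = build_design(exp1_design_params(), SEED)
    exp3 = build_design(exp3_design_params(), SEED + 1)
    cwio.write_design(exp1, OUT / "exp1")
    cwio.write_design(exp3, OUT / "exp3")

    sched = generate_learning_schedule(exp3, SEED + 2)
    counts = collections.Counter(w for t in sched for w in t.word_ids)
    print(f"exp1: {len(exp1.words)} words in {len(exp1.context_sets)} scene contexts")
    print(f"exp3: {len(exp3.words)} words; contexts "
          f"{[(c.picture_kind, c.side) for c in exp3.context_sets]}")
    print(f"learning schedule: {len(sched)} trials; presentations/word = "
          f"{sorted(set(counts.values()))}")

    recall = generate_recall_trials(exp1, SEED + 3)
    cond = collections.Counter(t.condition for t in recall)
    print(f"recall: {len(recall)} trials, per condition {dict(cond)}")

    dnms = generate_dnms_trials(exp3, SEED + 4, n_trials=60, schedule=sched)
    ptypes = collections.Counter(t.probe_type for t in dnms)
    overlaps = [t.overlap for t in dnms if t.probe_type == "lure"]
    print(f"dnms: {len(dnms)} trials, probe types {dict(ptypes)}")
    print(f"lure overlap: range {min(overlaps)}-{max(overlaps)}, "
          f"mean {np.mean(overlaps):.2f}, sd {np.std(overlaps, ddof=1):.2f}")

    rows = [{"trial": t.index, "context_id": t.context_id,
             "targets": " ".join(t.target_ids), "probe_id": t.probe_id,
             "probe_type": t.probe_type, "correct_response": t.correct_response,
             "overlap": t.overlap, "seed": SEED + 4} for t in dnms]
    cwio.write_tsv(pd.DataFrame(rows), OUT / "exp3" / "dnms_trials.tsv")
    rows = [{"trial": t.index, "context_id": t.context_id,
             "targets": " ".join(t.target_ids), "condition": t.condition,
             "seed": SEED + 3} for t in recall]
    cwio.write_tsv(pd.DataFrame(rows), OUT / "exp1" / "recall_trials.tsv")


if __name__ == "__main__":
    main()
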