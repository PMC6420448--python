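"""Decoder training and trial-period evidence extraction.

The evidence model is four *independent* L2-regularized binary logistic
units, one per trained class (face-left, face-right, scene-left,
scene-right), each trained class-vs-rest on localizer TRs.  Because the
units are independent, the four per-TR probability outputs do not sum to 1
— simultaneous evidence for several contexts is representable, which is
what a reinstatement readout requires.

All timing honors a fixed 5-s hemodynamic shift and half-open windows:
TR t carries label c iff t lies in [onset + shift, end + shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .bold import TRAINED_CLASSES, BoldRun

__all__ = [
    "LabeledTRTable",
    "EvidenceModel",
    "permutation_null_accuracy",
    "label_localizer_trs",
    "split_folds_by_time",
    "train_evidence_model",
    "crossval_accuracy",
    "score_evidence",
    "extract_trial_evidence",
    "trial_period_windows",
    "target_context_contrast",
]


@dataclass
class LabeledTRTable:
    """Per-TR labels: columns tr, label, block, fold (fold filled later)."""

    table: pd.DataFrame

    @property
    def labeled(self) -> pd.DataFrame:
        return self.table[self.table["label"].notna()]


def label_localizer_trs(
    events: pd.DataFrame,
    n_trs: int,
    tr_seconds: float = 1.0,
    shift_seconds: float = 5.0,
    classes: tuple[str, ...] = TRAINED_CLASSES,
) -> LabeledTRTable:
    """Label each TR with the class of the (shifted) miniblock covering it.

    Only the four trained classes receive labels; object/scrambled blocks and
    interblock intervals stay unlabeled.  Overlapping shifted windows are a
    design error and raise.
    """
    labels = np.full(n_trs, None, dtype=object)
    blocks = np.full(n_trs, -1, dtype=int)
    for row in events.itertuples():
        if row.trial_type not in classes:
            continue
        lo = int(np.ceil((row.onset + shift_seconds) / tr_seconds - 1e-9))
        hi = int(np.ceil((row.onset + row.duration + shift_seconds) / tr_seconds - 1e-9))
        hi = min(hi, n_trs)
        if np.any(labels[lo:hi] != None):  # noqa: E711 - object array comparison
            raise ValueError("shifted miniblock windows overlap")
        labels[lo:hi] = row.trial_type
        blocks[lo:hi] = int(row.block)
    df = pd.DataFrame({"tr": np.arange(n_trs), "label": labels, "block": blocks})
    df["fold"] = -1
    return LabeledTRTable(df)


def split_folds_by_time(table: LabeledTRTable, k: int = 4) -> LabeledTRTable:
    """Assign labeled TRs to k contiguous temporal folds, splitting only at
    miniblock boundaries so no block straddles folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    df = table.table.copy()
    lab = df[df["label"].notna()]
    block_order = lab.groupby("block")["tr"].min().sort_values().index.to_numpy()
    if len(block_order) < k:
        raise ValueError("fewer labeled blocks than folds")
    fold_of_block = {
        int(b): int(i * k // len(block_order)) for i, b in enumerate(block_order)
    }
    df.loc[lab.index, "fold"] = [fold_of_block[int(b)] for b in lab["block"]]
    return LabeledTRTable(df)


def permutation_null_accuracy(
    X: np.ndarray,
    table: LabeledTRTable,
    rng,
    lam: float = 1.0,
    classes: tuple[str, ...] = TRAINED_CLASSES,
) -> float:
    """One permutation draw of the chance-level cross-validated accuracy.

    Labels are permuted at the TR level *within the training data* of each
    fold and the held-out fold is scored against its true labels.  Scrambling
    training labels per TR leaves the units nothing to learn — or to
    anti-learn — so the null accuracy is centered on the analytic chance
    level (25% for four classes); permuting whole miniblocks instead leaves
    the true class signal anti-associated with the shuffled labels and
    biases the null below chance.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lab = table.labeled
    if (lab["fold"] < 0).any():
        raise ValueError("assign folds before permuting (split_folds_by_time)")
    X = np.asarray(X, dtype=float)
    accs = []
    for fold in sorted(lab["fold"].unique()):
        tr = lab[lab["fold"] != fold]
        te = lab[lab["fold"] == fold]
        train_labels = rng.permutation(tr["label"].to_numpy())
        tr_idx = tr["tr"].to_numpy()
        sub = _balance_classes(train_labels)
        tr_idx, train_labels = tr_idx[sub], train_labels[sub]
        present = tuple(c for c in classes if c in set(train_labels.tolist()))
        model = train_evidence_model(X[tr_idx], train_labels, lam=lam, classes=present)
        ev = score_evidence(model, X[te["tr"].to_numpy()])
        pred = np.asarray(model.classes, dtype=object)[ev.argmax(axis=1)]
        accs.append(float(np.mean(pred == te["label"].to_numpy())))
    return float(np.mean(accs))


@dataclass
class EvidenceModel:
    classes: tuple[str, ...]
    units: dict  # class -> fitted LogisticRegression
    mean: np.ndarray
    sd: np.ndarray
    lam: float

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.mean):
            raise ValueError("feature dimensionality does not match training")
        return (X - self.mean) / self.sd


def train_evidence_model(
    X: np.ndarray,
    labels: np.ndarray,
    lam: float = 1.0,
    classes: tuple[str, ...] = TRAINED_CLASSES,
) -> EvidenceModel:
    """Fit one class-vs-rest L2 logistic unit per class on standardized
    features.  ``lam`` is the ridge penalty (sklearn C = 1/lam)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    present = set(labels.tolist())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes absent from training data: {missing}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd
    units = {}
    for c in classes:
        clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=2000)
        clf.fit(Xs, (labels == c).astype(int))
        units[c] = clf
    return EvidenceModel(classes=tuple(classes), units=units, mean=mean, sd=sd, lam=lam)


def score_evidence(model: EvidenceModel, run_or_X) -> np.ndarray:
    """Per-TR class evidence: (T, n_classes) probabilities in [0, 1]."""
    X = run_or_X.data if isinstance(run_or_X, BoldRun) else np.asarray(run_or_X, float)
    Xs = model._standardize(X)
    cols = [model.units[c].predict_proba(Xs)[:, 1] for c in model.classes]
    return np.column_stack(cols)


def _balance_classes(labels: np.ndarray) -> np.ndarray:
    """Indices of an evenly spaced subsample equalizing class counts."""
    counts = {c: int(np.sum(labels == c)) for c in set(labels.tolist())}
    n_min = min(counts.values())
    keep: list[int] = []
    for c in counts:
        idx = np.flatnonzero(labels == c)
        sel = np.linspace(0, len(idx) - 1, n_min).round().astype(int)
        keep.extend(idx[sel].tolist())
    return np.asarray(sorted(keep))


def crossval_accuracy(
    X: np.ndarray,
    table: LabeledTRTable,
    k: int = 4,
    lam: float = 1.0,
    classes: tuple[str, ...] = TRAINED_CLASSES,
    balance_training: bool = True,
) -> float:
    """Leave-one-fold-out accuracy: argmax over the four unit outputs.

    Training sets are class-balanced by deterministic subsampling (fold-wise
    class imbalance would otherwise bias the argmax readout against classes
    over-represented in the held-out fold — permutation nulls would then sit
    below the analytic 25% chance level).
    """
    df = table.table
    lab = df[df["label"].notna()]
    if (lab["fold"] < 0).any():
        table = split_folds_by_time(table, k=k)
        lab = table.table[table.table["label"].notna()]
    X = np.asarray(X, dtype=float)
    accs = []
    for fold in sorted(lab["fold"].unique()):
        tr_idx = lab.loc[lab["fold"] != fold, "tr"].to_numpy()
        te_idx = lab.loc[lab["fold"] == fold, "tr"].to_numpy()
        train_labels = lab.loc[lab["fold"] != fold, "label"].to_numpy()
        if balance_training:
            sub = _balance_classes(train_labels)
            tr_idx, train_labels = tr_idx[sub], train_labels[sub]
        # a class may be entirely held out; train on those present — its
        # held-out TRs are then necessarily misclassified
        present = tuple(c for c in classes if c in set(train_labels.tolist()))
        model = train_evidence_model(X[tr_idx], train_labels, lam=lam, classes=present)
        ev = score_evidence(model, X[te_idx])
        pred = np.asarray(model.classes, dtype=object)[ev.argmax(axis=1)]
        accs.append(float(np.mean(pred == lab.loc[lab["fold"] == fold, "label"].to_numpy())))
    return float(np.mean(accs))


def trial_period_windows(
    trial_onset_s: float,
    tr_seconds: float = 1.0,
    shift_s: float = 5.0,
    window_s: float = 6.0,
    gap_trs: int = 1,
    target_s: float = 2.0,
    delay_s: float = 18.0,
) -> dict[str, list[int]]:
    """TR windows for the three trial periods under the conflict rule.

    Raw window for a period with onset o is [o + shift, o + shift + window).
    TRs claimed by an earlier period's raw window are dropped from later
    windows; each non-first window then drops its ``gap_trs`` leading TRs to
    buffer hemodynamic bleed-over.
    """
    onsets = {
        "target_presentation": trial_onset_s,
        "delay": trial_onset_s + target_s,
        "probe_presentation": trial_onset_s + target_s + delay_s,
    }
    claimed: set[int] = set()
    windows: dict[str, list[int]] = {}
    for i, (period, o) in enumerate(onsets.items()):
        lo = int(np.ceil((o + shift_s) / tr_seconds - 1e-9))
        hi = int(np.ceil((o + shift_s + window_s) / tr_seconds - 1e-9))
        raw = list(range(lo, hi))
        surviving = [t for t in raw if t not in claimed]
        if i > 0:
            surviving = surviving[gap_trs:]
        if not surviving:
            raise ValueError(f"no TRs left for period {period!r} after conflict resolution")
        windows[period] = surviving
        claimed.update(raw)
    return windows


def extract_trial_evidence(
    evidence: np.ndarray,
    events: pd.DataFrame,
    model_classes: tuple[str, ...],
    tr_seconds: float = 1.0,
    shift_s: float = 5.0,
    window_s: float = 6.0,
    gap_trs: int = 1,
) -> pd.DataFrame:
    """Average per-TR evidence over each trial period's window.

    ``events`` is the task event table (rows per trial x period with columns
    onset, duration, trial_type in the three period names, trial).  Returns
    one row per trial x period with one column per class.
    """
    ev = np.asarray(evidence, dtype=float)
    rows = []
    per_trial = events[events["trial_type"] == "target_presentation"]
    durs = {r.trial_type: r.duration for r in events.itertuples()}
    for r in per_trial.itertuples():
        wins = trial_period_windows(
            r.onset, tr_seconds=tr_seconds, shift_s=shift_s, window_s=window_s,
            gap_trs=gap_trs, target_s=durs["target_presentation"], delay_s=durs["delay"],
        )
        for period, trs in wins.items():
            trs = [t for t in trs if t < ev.shape[0]]
            if not trs:
                raise ValueError("evidence trace does not cover the trial windows")
            mean_ev = ev[trs].mean(axis=0)
            row = {"trial": int(r.trial), "period": period, "n_trs": len(trs)}
            row.update({c: float(v) for c, v in zip(model_classes, mean_ev)})
            rows.append(row)
    return pd.DataFrame(rows)


def target_context_contrast(per_subject_diffs: pd.DataFrame) -> dict:
    """Group test of target-context minus mean nontarget-context evidence.

    ``per_subject_diffs`` has columns ``subject`` and ``diff`` (per-subject
    mean difference).  Returns t, df = n_subjects - 1, two-sided p.
    """
    d = per_subject_diffs.groupby("subject")["diff"].mean()
    if len(d) < 2:
        raise ValueError("need >= 2 subjects")
    t, p = stats.ttest_1samp(d, 0.0)
    return {"t": float(t), "df": int(len(d) - 1), "p": float(p),
            "mean_diff": float(d.mean()), "n_subjects": int(len(d))}
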