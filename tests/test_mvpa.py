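"""Decoder: TR labeling, temporal folds, evidence units, window extraction."""

import numpy as np
import pandas as pd
import pytest

from contextwm.bold import (
    TRAINED_CLASSES,
    BoldParams,
    make_pattern_bank,
    simulate_localizer_run,
)
from contextwm.mvpa import (
    crossval_accuracy,
    extract_trial_evidence,
    label_localizer_trs,
    score_evidence,
    split_folds_by_time,
    target_context_contrast,
    train_evidence_model,
    trial_period_windows,
)


@pytest.fixture(scope="module")
def localizer():
    p = BoldParams()
    bank = make_pattern_bank(p.n_voxels, p.selectivity, 0)
    run, events = simulate_localizer_run(bank, p, 0)
    return run, events


class TestLabeling:
    def test_shifted_block_window_arithmetic(self):
        events = pd.DataFrame([{"onset": 100.0, "duration": 20.0,
                                "trial_type": "face-left", "block": 0, "trial": 0}])
        table = label_localizer_trs(events, n_trs=200, tr_seconds=1.0, shift_seconds=5.0)
        labeled = table.labeled
        assert labeled["tr"].tolist() == list(range(105, 125))
        assert (labeled["label"] == "face-left").all()

    def test_block_onset_plus_shift_labeled(self, localizer):
        run, events = localizer
        table = label_localizer_trs(events, run.n_trs)
        lab = table.table.set_index("tr")["label"]
        for r in events.itertuples():
            if r.trial_type in TRAINED_CLASSES:
                assert lab[int(r.onset + 5)] == r.trial_type

    def test_interblock_unlabeled(self, localizer):
        run, events = localizer
        table = label_localizer_trs(events, run.n_trs)
        lab = table.table.set_index("tr")["label"]
        for r in events.itertuples():
            # one TR before the shifted window opens is between blocks
            assert lab[int(r.onset + 4)] is None or int(r.onset) == 12

    def test_object_scrambled_unlabeled(self, localizer):
        run, events = localizer
        table = label_localizer_trs(events, run.n_trs)
        assert set(table.labeled["label"].unique()) <= set(TRAINED_CLASSES)

    def test_overlapping_windows_error(self):
        events = pd.DataFrame([
            {"onset": 10.0, "duration": 20.0, "trial_type": "face-left", "block": 0, "trial": 0},
            {"onset": 25.0, "duration": 20.0, "trial_type": "face-right", "block": 1, "trial": 1},
        ])
        with pytest.raises(ValueError, match="overlap"):
            label_localizer_trs(events, n_trs=100)


class TestFolds:
    def test_four_folds_six_blocks_each(self, localizer):
        run, events = localizer
        table = split_folds_by_time(label_localizer_trs(events, run.n_trs))
        lab = table.labeled
        per_fold_blocks = lab.groupby("fold")["block"].nunique()
        # 12 trained-class blocks over 4 folds -> 3 each
        assert (per_fold_blocks == 3).all()
        # no block straddles folds
        assert (lab.groupby("block")["fold"].nunique() == 1).all()

    def test_folds_temporally_ordered(self, localizer):
        run, events = localizer
        lab = split_folds_by_time(label_localizer_trs(events, run.n_trs)).labeled
        fold_seq = lab.sort_values("tr")["fold"].to_numpy()
        assert (np.diff(fold_seq) >= 0).all()

    def test_fewer_blocks_than_folds(self):
        events = pd.DataFrame([{"onset": 10.0, "duration": 20.0,
                                "trial_type": "face-left", "block": 0, "trial": 0}])
        table = label_localizer_trs(events, n_trs=60)
        with pytest.raises(ValueError, match="fewer"):
            split_folds_by_time(table, k=4)


class TestEvidenceModel:
    @staticmethod
    def _toy(n=40, rng=None):
        rng = rng or np.random.default_rng(0)
        corners = [(-6, -6), (-6, 6), (6, -6), (6, 6)]
        X, y = [], []
        for c, mu in zip(TRAINED_CLASSES, corners):
            X.append(np.asarray(mu) + 0.3 * rng.normal(size=(n, 2)))
            y += [c] * n
        return np.vstack(X), np.asarray(y, dtype=object)

    def test_separable_toy_confident(self):
        X, y = self._toy()
        m = train_evidence_model(X, y, lam=1.0)
        ev = score_evidence(m, X)
        own = ev[np.arange(len(y)), [m.classes.index(c) for c in y]]
        assert (own > 0.9).mean() > 0.95

    def test_outputs_unit_interval_not_simplex(self):
        X, y = self._toy()
        m = train_evidence_model(X, y, lam=1.0)
        ev = score_evidence(m, X)
        assert ev.min() >= 0 and ev.max() <= 1
        assert not np.allclose(ev.sum(axis=1), 1.0)

    def test_huge_ridge_gives_base_rate(self):
        X, y = self._toy()
        m = train_evidence_model(X, y, lam=1e8)
        ev = score_evidence(m, X)
        assert np.allclose(ev, 0.25, atol=0.01)  # each class is 1/4 of TRs

    def test_missing_class_error(self):
        X, y = self._toy()
        keep = y != "face-left"
        with pytest.raises(ValueError, match="absent"):
            train_evidence_model(X[keep], y[keep])

    def test_duplicate_rows_identical_evidence(self):
        X, y = self._toy()
        m = train_evidence_model(X, y)
        ev = score_evidence(m, np.vstack([X[:1], X[:1]]))
        assert np.array_equal(ev[0], ev[1])

    def test_dim_mismatch_error(self):
        X, y = self._toy()
        m = train_evidence_model(X, y)
        with pytest.raises(ValueError, match="dimensionality"):
            score_evidence(m, np.zeros((3, 5)))


class TestCrossval:
    def test_high_snr_accuracy(self):
        p = BoldParams(selectivity=5.0, noise_sd=0.1)
        bank = make_pattern_bank(p.n_voxels, p.selectivity, 1)
        run, events = simulate_localizer_run(bank, p, 1)
        table = split_folds_by_time(label_localizer_trs(events, run.n_trs))
        assert crossval_accuracy(run.data, table) >= 0.95

    def test_permuted_labels_near_chance(self, localizer):
        from contextwm.mvpa import permutation_null_accuracy

        run, events = localizer
        rng = np.random.default_rng(0)
        table = split_folds_by_time(label_localizer_trs(events, run.n_trs))
        accs = [permutation_null_accuracy(run.data, table, rng) for _ in range(10)]
        assert abs(np.mean(accs) - 0.25) < 0.04


class TestWindows:
    def test_default_window_arithmetic(self):
        wins = trial_period_windows(0.0)
        assert wins["target_presentation"] == [5, 6, 7, 8, 9, 10]
        # delay raw {7..12} loses {7..10} to the target window, then 1 leading TR
        assert wins["delay"] == [12]
        # probe raw {25..30} has no conflict, drops 1 leading TR
        assert wins["probe_presentation"] == [26, 27, 28, 29, 30]

    def test_windows_disjoint_brute_force(self):
        for onset in (0.0, 13.0, 57.0):
            wins = trial_period_windows(onset)
            all_trs = [t for w in wins.values() for t in w]
            assert len(all_trs) == len(set(all_trs))

    def test_constant_trace_equal_evidence(self):
        ev = np.full((120, 4), 0.37)
        events = pd.DataFrame([
            {"onset": 10.0, "duration": 2.0, "trial_type": "target_presentation",
             "block": 0, "trial": 0},
            {"onset": 12.0, "duration": 18.0, "trial_type": "delay", "block": 0, "trial": 0},
            {"onset": 30.0, "duration": 4.0, "trial_type": "probe_presentation",
             "block": 0, "trial": 0},
        ])
        out = extract_trial_evidence(ev, events, TRAINED_CLASSES)
        assert np.allclose(out[list(TRAINED_CLASSES)].to_numpy(), 0.37)

    def test_empty_window_error(self):
        with pytest.raises(ValueError, match="no TRs"):
            trial_period_windows(0.0, window_s=4.0, target_s=0.5, gap_trs=5)


class TestGroupContrast:
    def test_df_and_null(self, rng):
        df = pd.DataFrame({"subject": np.repeat([f"s{i}" for i in range(36)], 5),
                           "diff": rng.normal(0, 1, size=180)})
        out = target_context_contrast(df)
        assert out["df"] == 35
        assert out["p"] > 0.001  # null cohort should not be wildly significant

    def test_planted_difference_detected(self, rng):
        df = pd.DataFrame({"subject": np.repeat([f"s{i}" for i in range(20)], 5),
                           "diff": rng.normal(0.3, 0.2, size=100)})
        out = target_context_contrast(df)
        assert out["p"] < 0.001 and out["mean_diff"] > 0
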