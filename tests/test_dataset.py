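"""Epoch-sample extraction, task labelling, undersampling and folds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tacdecode import dataset as ds
from tacdecode import paradigm as pg
from tacdecode.synth import Volume4D


def make_volume(events, subject=1, session=1, shape=(4, 4, 4), tr=3.0,
                n_trs=240, fill="time"):
    """4D volume whose value at every voxel equals the TR index (or a
    constant), so window averages are analytically checkable."""
    if fill == "time":
        data = np.broadcast_to(np.arange(n_trs, dtype=np.float32),
                               shape + (n_trs,)).copy()
    else:
        data = np.full(shape + (n_trs,), float(fill), dtype=np.float32)
    return Volume4D(data=data, tr_s=tr, affine=np.eye(4), subject=subject,
                    session=session)


@pytest.fixture()
def responded_events():
    events = pg.generate_paradigm(pg.ParadigmConfig(n_sessions=1, seed=0), 1)
    events["q1_response"] = [1.0, 2.0] * 7 + [1.0]
    return events


class TestEpochExtraction:
    def test_window_is_five_trs_shifted_by_delay(self, responded_events):
        vol = make_volume(responded_events)
        x, meta = ds.extract_epoch_samples(vol, responded_events,
                                           delay_trs=2, zscore=False)
        # epoch 1 of trial 1 starts at 0 s -> TRs [2, 7) -> mean TR index 4
        first = x[0]
        assert first.flat[0] == pytest.approx(np.arange(2, 7).mean())
        # epoch 2 of trial 1 starts at 18 s -> TRs [8, 13)
        second = x[1]
        assert second.flat[0] == pytest.approx(np.arange(8, 13).mean())

    def test_fifteen_responded_trials_give_thirty_samples(self,
                                                          responded_events):
        vol = make_volume(responded_events)
        x, meta = ds.extract_epoch_samples(vol, responded_events)
        assert x.shape[0] == 30
        assert len(meta) == 30

    def test_nonresponded_trials_are_dropped(self, responded_events):
        responded_events.loc[responded_events.index[:3], "q1_response"] = np.nan
        vol = make_volume(responded_events)
        x, _ = ds.extract_epoch_samples(vol, responded_events)
        assert x.shape[0] == 24

    def test_constant_series_zero_after_zscoring(self, responded_events):
        vol = make_volume(responded_events, fill=7.5)
        raw, _ = ds.extract_epoch_samples(vol, responded_events, zscore=False)
        assert (raw == 7.5).all()
        z, _ = ds.extract_epoch_samples(vol, responded_events, zscore=True)
        assert (z == 0.0).all()

    def test_window_past_scan_end_names_the_trial(self, responded_events):
        vol = make_volume(responded_events, n_trs=236)
        with pytest.raises(ValueError, match="trial 15"):
            ds.extract_epoch_samples(vol, responded_events)

    def test_extraction_commutes_with_trial_order(self, responded_events):
        vol = make_volume(responded_events)
        x1, m1 = ds.extract_epoch_samples(vol, responded_events, zscore=False)
        shuffled = responded_events.sample(frac=1.0, random_state=4)
        x2, m2 = ds.extract_epoch_samples(vol, shuffled, zscore=False)
        key = ["trial", "epoch"]
        order1 = m1.sort_values(key).index
        order2 = m2.sort_values(key).index
        np.testing.assert_array_equal(x1[order1], x2[order2])


@pytest.fixture(scope="module")
def cohort_epochs(cohort_events):
    meta = ds.epoch_index(cohort_events)
    samples = np.zeros((len(meta), 1, 1, 1), dtype=np.float32)
    return samples, meta


class TestTaskLabels:

    def test_stimulus_task_sizes_match_cohort_table(self, cohort_epochs):
        samples, meta = cohort_epochs
        s = ds.assign_task_labels(samples, meta, "aristotle_vs_reverse")
        assert s.class_counts == (594, 596)      # Reverse=0, Aristotle=1
        s = ds.assign_task_labels(samples, meta, "reverse_vs_async")
        assert s.class_counts == (590, 594)
        s = ds.assign_task_labels(samples, meta, "aristotle_vs_async")
        assert s.class_counts == (590, 596)

    def test_perception_task_sizes_match_cohort_table(self, cohort_epochs):
        samples, meta = cohort_epochs
        s = ds.assign_task_labels(samples, meta,
                                  "aristotle_illusion_vs_reverse_illusion")
        assert s.class_counts == (212, 544)
        s = ds.assign_task_labels(samples, meta,
                                  "reverse_illusion_vs_no_reverse_illusion")
        assert s.class_counts == (382, 212)

    def test_excluded_imbalanced_task_still_constructible(self, cohort_epochs):
        samples, meta = cohort_epochs
        s = ds.assign_task_labels(samples, meta,
                                  "aristotle_illusion_vs_no_aristotle_illusion")
        assert s.class_counts == (52, 544)

    def test_unknown_task_rejected(self, cohort_epochs):
        samples, meta = cohort_epochs
        with pytest.raises(ValueError, match="unknown task"):
            ds.assign_task_labels(samples, meta, "apples_vs_oranges")

    def test_both_epochs_share_the_trial_label(self, cohort_epochs):
        samples, meta = cohort_epochs
        s = ds.assign_task_labels(samples, meta, "aristotle_vs_reverse")
        per_trial = (s.meta.assign(label=s.labels)
                     .groupby(["subject", "session", "trial"])["label"]
                     .nunique())
        assert (per_trial == 1).all()

    def test_all_nonresponse_gives_empty_and_errors(self):
        events = pg.generate_paradigm(pg.ParadigmConfig(n_sessions=1), 1)
        meta = ds.epoch_index(events)      # all trials unresponded
        assert len(meta) == 0
        with pytest.raises(ValueError):
            ds.assign_task_labels(np.zeros((0, 1, 1, 1)), meta,
                                  "aristotle_vs_reverse")


class TestUndersampling:
    def _set(self, n0, n1):
        n = n0 + n1
        meta = pd.DataFrame({"subject": 1, "session": 1,
                             "trial": np.arange(n) // 2 + 1,
                             "condition": "x", "q1_response": 1,
                             "epoch": np.arange(n) % 2 + 1})
        return ds.LabeledSampleSet(
            samples=np.arange(n, dtype=np.float32).reshape(n, 1, 1, 1),
            labels=np.array([0] * n0 + [1] * n1), meta=meta, task="t")

    def test_majority_reduced_to_minority_count(self):
        out = ds.undersample_majority(self._set(544, 212), seed=0)
        assert out.class_counts == (212, 212)

    def test_already_balanced_unchanged(self):
        s = self._set(10, 10)
        out = ds.undersample_majority(s, seed=0)
        np.testing.assert_array_equal(out.samples, s.samples)

    def test_sampling_without_replacement_and_deterministic(self):
        s = self._set(30, 10)
        a = ds.undersample_majority(s, seed=3)
        b = ds.undersample_majority(s, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        kept = a.samples[a.labels == 0].ravel()
        assert len(np.unique(kept)) == len(kept)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ds.undersample_majority(self._set(5, 0), seed=0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n0=st.integers(1, 40), n1=st.integers(1, 40),
           seed=st.integers(0, 10))
    def test_balance_property(self, n0, n1, seed):
        """For any class sizes the result is balanced at the minority
        count, is a subset of the input, and keeps minority members."""
        s = self._set(n0, n1)
        out = ds.undersample_majority(s, seed=seed)
        assert out.class_counts == (min(n0, n1), min(n0, n1))
        assert set(out.samples.ravel()) <= set(s.samples.ravel())
        minority = int(n1 < n0) if n0 != n1 else None
        if minority is not None:
            kept = set(out.samples[out.labels == minority].ravel())
            full = set(s.samples[s.labels == minority].ravel())
            assert kept == full


class TestFolds:
    def _set(self, n_trials, label_rule=None):
        rows = []
        for t in range(1, n_trials + 1):
            for epoch in (1, 2):
                rows.append({"subject": 1, "session": 1, "trial": t,
                             "condition": "x", "q1_response": 1,
                             "epoch": epoch})
        meta = pd.DataFrame(rows)
        labels = np.array([(t - 1) % 2 if label_rule is None
                           else label_rule(t)
                           for t in meta["trial"]])
        return ds.LabeledSampleSet(
            samples=np.zeros((len(meta), 1, 1, 1), dtype=np.float32),
            labels=labels, meta=meta, task="t")

    def test_ten_trials_five_folds(self):
        s = self._set(10)
        spec = ds.make_folds(s, k=5, seed=0)
        for train_idx, val_idx in spec.folds:
            assert len(val_idx) == 4           # 2 trials x 2 epochs
            assert len(train_idx) == 16

    def test_trials_never_split_across_train_and_val(self):
        s = self._set(13)
        spec = ds.make_folds(s, k=5, seed=1)
        for train_idx, val_idx in spec.folds:
            t_train = set(map(tuple, s.meta.iloc[train_idx][
                ["subject", "session", "trial"]].to_numpy()))
            t_val = set(map(tuple, s.meta.iloc[val_idx][
                ["subject", "session", "trial"]].to_numpy()))
            assert not (t_train & t_val)

    def test_validation_folds_cover_all_trials_once(self):
        s = self._set(11)
        spec = ds.make_folds(s, k=5, seed=2)
        seen = []
        for _, val_idx in spec.folds:
            seen += [tuple(r) for r in s.meta.iloc[val_idx][
                ["subject", "session", "trial"]].drop_duplicates().to_numpy()]
        assert len(seen) == 11
        assert len(set(seen)) == 11

    def test_fewer_trials_than_k_rejected(self):
        s = self._set(6, label_rule=lambda t: int(t > 3))
        with pytest.raises(ValueError, match="fewer than k"):
            ds.make_folds(s, k=5, seed=0)


class TestLabelShuffle:
    def test_marginals_and_pairing_preserved(self):
        rows = []
        for t in range(1, 21):
            for epoch in (1, 2):
                rows.append({"subject": 1, "session": 1, "trial": t,
                             "condition": "x", "q1_response": 1,
                             "epoch": epoch})
        meta = pd.DataFrame(rows)
        labels = np.repeat(np.arange(20) % 2, 2)
        s = ds.LabeledSampleSet(np.zeros((40, 1, 1, 1), dtype=np.float32),
                                labels, meta, "t")
        sh = ds.shuffle_labels(s, seed=0)
        assert sh.class_counts == s.class_counts
        per_trial = (sh.meta.assign(label=sh.labels)
                     .groupby("trial")["label"].nunique())
        assert (per_trial == 1).all()
        assert not np.array_equal(sh.labels, s.labels)
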