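"""From 4D volumes + events to labelled 3D samples, folds, and class balance.

Each responded trial contributes two samples, one per 15-s stimulation
epoch: the voxelwise mean of the in-window volumes, shifted by a
hemodynamic delay, then z-scored voxelwise within the session.  Five binary
tasks are defined, three stimulus-based (which stimulus was applied) and
two perception-based (what the participant reported feeling).  Fold
assignment is grouped at the trial level so the two epochs of a trial never
straddle the train/validation split, and class balance is restored by
undersampling the majority class in the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import Volume4D

#: task name -> (class-0 selector, class-1 selector); a selector is
#: (condition, required Q1 or None).  Label 1 is the illusion-occurrence
#: class where one exists (it is the "positive" class for precision/recall).
TASKS = {
    "aristotle_vs_reverse": (("Reverse", None), ("Aristotle", None)),
    "reverse_vs_async": (("Asynchronous", None), ("Reverse", None)),
    "aristotle_vs_async": (("Asynchronous", None), ("Aristotle", None)),
    "aristotle_illusion_vs_reverse_illusion": (("Reverse", 1), ("Aristotle", 2)),
    "reverse_illusion_vs_no_reverse_illusion": (("Reverse", 2), ("Reverse", 1)),
    # generated for completeness; excluded from default training for its
    # severe class imbalance (52 vs 544 epochs at the study's rates)
    "aristotle_illusion_vs_no_aristotle_illusion": (("Aristotle", 1),
                                                    ("Aristotle", 2)),
}

META_COLUMNS = ["subject", "session", "trial", "condition", "q1_response",
                "epoch"]


def epoch_index(events: pd.DataFrame) -> pd.DataFrame:
    """One row per stimulation epoch of every *responded* trial."""
    responded = events[events["q1_response"].notna()]
    rows = []
    for _, r in responded.iterrows():
        for epoch, onset in ((1, r["epoch1_onset_s"]), (2, r["epoch2_onset_s"])):
            rows.append({
                "subject": r["subject"], "session": r["session"],
                "trial": r["trial"], "condition": r["condition"],
                "q1_response": int(r["q1_response"]), "epoch": epoch,
                "onset_s": onset, "duration_s": r["epoch_duration_s"],
            })
    return pd.DataFrame(rows, columns=META_COLUMNS + ["onset_s", "duration_s"])


def extract_epoch_samples(vol: Volume4D, events: pd.DataFrame,
                          delay_trs: int = 2, zscore: bool = True):
    """Average the in-window volumes of each stimulation epoch into one
    3D sample per epoch.

    The window is ``[onset + delay, onset + delay + duration)`` in TRs; the
    +2 TR (6 s) default delay matches the canonical HRF peak.  Samples are
    z-scored voxelwise across the session's samples (constant voxels map to
    zero).  Returns ``(samples, meta)``: a float32 array (n, x, y, z) and a
    DataFrame aligned with it.
    """
    sub = events[(events["subject"] == vol.subject)
                 & (events["session"] == vol.session)]
    epochs = epoch_index(sub)
    n_t = vol.n_trs
    samples = []
    for _, e in epochs.iterrows():
        a = int(round(e["onset_s"] / vol.tr_s)) + delay_trs
        b = a + int(round(e["duration_s"] / vol.tr_s))
        if b > n_t or a < 0:
            raise ValueError(
                f"epoch window [{a}, {b}) TRs of subject {vol.subject} "
                f"session {vol.session} trial {int(e['trial'])} exceeds the "
                f"scan ({n_t} TRs)")
        samples.append(vol.data[..., a:b].mean(axis=3))
    if not samples:
        return (np.empty((0,) + vol.data.shape[:3], dtype=np.float32),
                epochs[META_COLUMNS])
    x = np.stack(samples).astype(np.float32)
    if zscore:
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        x = np.where(sd > 1e-8, (x - mu) / np.where(sd > 1e-8, sd, 1.0), 0.0)
        x = x.astype(np.float32)
    return x, epochs[META_COLUMNS].reset_index(drop=True)


@dataclass
class LabeledSampleSet:
    """3D samples with binary labels and trial-level group keys."""

    samples: np.ndarray        # (n, x, y, z) float32
    labels: np.ndarray         # (n,) int, in {0, 1}
    meta: pd.DataFrame         # aligned rows: subject/session/trial/...
    task: str

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def class_counts(self) -> tuple:
        return (int((self.labels == 0).sum()), int((self.labels == 1).sum()))

    def trial_keys(self) -> pd.DataFrame:
        return self.meta[["subject", "session", "trial"]].drop_duplicates()

    def subset(self, idx) -> "LabeledSampleSet":
        idx = np.asarray(idx)
        return LabeledSampleSet(self.samples[idx], self.labels[idx],
                                self.meta.iloc[idx].reset_index(drop=True),
                                self.task)


def assign_task_labels(samples: np.ndarray, meta: pd.DataFrame,
                       task: str) -> LabeledSampleSet:
    """Select the samples belonging to a binary task and label them.

    Stimulus tasks select by condition alone; perception tasks additionally
    require the matching Q1 response.  Non-responded trials never appear
    (``epoch_index`` already drops them).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; known: {sorted(TASKS)}")
    sel0, sel1 = TASKS[task]
    labels = np.full(len(meta), -1, dtype=int)
    for lab, (cond, q1) in ((0, sel0), (1, sel1)):
        m = (meta["condition"] == cond).to_numpy()
        if q1 is not None:
            m &= (meta["q1_response"] == q1).to_numpy()
        labels[m] = lab
    keep = labels >= 0
    if not keep.any():
        raise ValueError(f"task {task!r}: no matching samples")
    return LabeledSampleSet(samples[keep], labels[keep],
                            meta[keep].reset_index(drop=True), task)


def undersample_majority(s: LabeledSampleSet, seed: int = 0) -> LabeledSampleSet:
    """Randomly drop majority-class samples (without replacement) until the
    classes are equal.  Apply to training portions only."""
    n0, n1 = s.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be nonempty")
    if n0 == n1:
        return s
    rng = np.random.default_rng(seed)
    minority = int(n1 < n0)
    n_keep = min(n0, n1)
    maj_idx = np.flatnonzero(s.labels == 1 - minority)
    min_idx = np.flatnonzero(s.labels == minority)
    kept = rng.choice(maj_idx, size=n_keep, replace=False)
    idx = np.sort(np.concatenate([kept, min_idx]))
    return s.subset(idx)


@dataclass
class FoldSpec:
    """Trial-grouped k-fold split: per fold, sample index lists."""

    k: int
    folds: list                # list of (train_idx, val_idx) arrays
    seed: int

    @property
    def ratio(self) -> tuple:
        return (self.k - 1, 1)


def make_folds(s: LabeledSampleSet, k: int = 5, seed: int = 0) -> FoldSpec:
    """Grouped k-fold at the trial level.

    Trials are shuffled with the seed and dealt into k chunks (earlier
    chunks take the remainder); fold i validates on chunk i and trains on
    the rest, so no trial's two epochs ever split across train/val.
    """
    trials = s.trial_keys().reset_index(drop=True)
    # require at least k trials per class for a meaningful CV
    trial_label = (s.meta.groupby(["subject", "session", "trial"])
                   .first().reset_index())
    lab_per_trial = (s.meta.assign(label=s.labels)
                     .groupby(["subject", "session", "trial"])["label"]
                     .first())
    for lab in (0, 1):
        if (lab_per_trial == lab).sum() < k:
            raise ValueError(
                f"class {lab} has fewer than k={k} trials; cannot fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    sizes = np.full(k, len(trials) // k)
    sizes[: len(trials) % k] += 1
    chunks = np.split(order, np.cumsum(sizes)[:-1])

    key = s.meta["subject"].astype(str) + "/" + \
        s.meta["session"].astype(str) + "/" + s.meta["trial"].astype(str)
    trial_key = trials["subject"].astype(str) + "/" + \
        trials["session"].astype(str) + "/" + trials["trial"].astype(str)
    folds = []
    for c in chunks:
        val_trials = set(trial_key.iloc[c])
        val_mask = key.isin(val_trials).to_numpy()
        folds.append((np.flatnonzero(~val_mask), np.flatnonzero(val_mask)))
    return FoldSpec(k=k, folds=folds, seed=seed)


def shuffle_labels(s: LabeledSampleSet, seed: int = 0) -> LabeledSampleSet:
    """Permute labels at the trial level (both epochs keep a common label).

    Used for null-calibration runs: the marginal label distribution is
    preserved while any label-signal association is destroyed.
    """
    lab_per_trial = (s.meta.assign(label=s.labels)
                     .groupby(["subject", "session", "trial"])["label"]
                     .first())
    rng = np.random.default_rng(seed)
    permuted = pd.Series(rng.permutation(lab_per_trial.to_numpy()),
                         index=lab_per_trial.index)
    key = list(zip(s.meta["subject"], s.meta["session"], s.meta["trial"]))
    new_labels = permuted.loc[key].to_numpy()
    return LabeledSampleSet(s.samples, new_labels.astype(int), s.meta, s.task)
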