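"""Synthetic parcellation atlas and block-design BOLD simulation.

The study's fMRI data are not deposited, so this module generates stand-in
volumes in which class-discriminative BOLD signal is planted in known atlas
regions.  The atlas is a seeded Voronoi partition of an ellipsoidal "brain"
mask; voxel time series are

    baseline + sum_effects amplitude * (epoch boxcar (x) HRF)   in effect ROIs
             + AR(1)-filtered Gaussian noise                    everywhere.

Perception-linked effects condition on each trial's simulated Q1 response,
so label-correlated signal exists only where an effect plants it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .paradigm import ParadigmConfig


@dataclass
class Parcellation:
    """Integer-labelled ROI atlas: 0 = background, labels 1..K."""

    labels: np.ndarray                 # 3D int array
    roi_names: dict                    # label -> name
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def roi_sizes(self) -> dict:
        lab, cnt = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def to_nifti(self, path, names_tsv=None) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        nib.save(img, str(path))
        if names_tsv is not None:
            pd.DataFrame(
                {"label": list(self.roi_names),
                 "name": list(self.roi_names.values())}
            ).to_csv(names_tsv, sep="\t", index=False)

    @classmethod
    def from_nifti(cls, path, names_tsv=None) -> "Parcellation":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(int)
        if names_tsv is not None:
            df = pd.read_csv(names_tsv, sep="\t")
            names = dict(zip(df["label"], df["name"]))
        else:
            names = {int(k): f"ROI_{int(k):03d}"
                     for k in np.unique(labels) if k > 0}
        return cls(labels=labels, roi_names=names, affine=img.affine)


def generate_atlas(grid_shape=(32, 32, 32), n_rois: int = 40,
                   seed: int = 0, min_roi_voxels: int = 8) -> Parcellation:
    """Partition an ellipsoidal brain mask into ``n_rois`` compact regions.

    Seed voxels are drawn uniformly inside the mask and every mask voxel is
    assigned to its nearest seed (Voronoi growth).  A few Lloyd iterations
    (seeds moved to their cell centroids, cells reassigned) even out the
    region volumes, mimicking the roughly comparable sizes of anatomical
    parcellations and avoiding degenerate sliver regions.  Seeds are
    redrawn (up to 20 attempts) until every region has at least
    ``min_roi_voxels`` voxels.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    coords = np.stack(np.meshgrid(*[np.arange(g) for g in grid_shape],
                                  indexing="ij"), axis=-1).astype(float)
    center = (np.asarray(grid_shape) - 1) / 2.0
    semi = 0.45 * np.asarray(grid_shape)
    mask = (((coords - center) / semi) ** 2).sum(-1) <= 1.0
    mask_idx = np.argwhere(mask)
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if n_rois * min_roi_voxels > len(mask_idx):
        raise ValueError(
            f"n_rois={n_rois} needs {n_rois * min_roi_voxels} voxels, "
            f"mask has {len(mask_idx)}")
    rng = np.random.default_rng(seed)
    fmask = mask_idx.astype(np.float64)
    for _ in range(20):
        seeds = fmask[rng.choice(len(mask_idx), n_rois, replace=False)]
        for _lloyd in range(10):
            d2 = ((fmask[:, None, :] - seeds[None, :, :]) ** 2).sum(-1)
            assign = d2.argmin(axis=1)
            new_seeds = np.array([
                fmask[assign == k].mean(axis=0) if (assign == k).any()
                else seeds[k] for k in range(n_rois)])
            if np.allclose(new_seeds, seeds):
                break
            seeds = new_seeds
        sizes = np.bincount(assign, minlength=n_rois)
        if sizes.min() >= min_roi_voxels:
            break
    else:
        raise ValueError("could not place ROIs with the requested minimum size")
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(mask_idx.T)] = assign + 1
    names = {k: f"ROI_{k:03d}" for k in range(1, n_rois + 1)}
    return Parcellation(labels=labels, roi_names=names)


def double_gamma_hrf(tr_s: float = 3.0, duration_s: float = 32.0,
                     peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Shape parameters follow the standard convention (response peak 6 s,
    undershoot peak 16 s, peak-to-undershoot ratio 6, dispersions 1 s).
    Normalized so the continuous response peaks at 1.
    """
    from scipy.stats import gamma

    def h(t):
        # gamma pdf with unit scale peaks at shape - 1, so shape = peak + 1
        return (gamma.pdf(t, peak_s + 1.0, scale=1.0)
                - gamma.pdf(t, undershoot_s + 1.0, scale=1.0) / ratio)

    fine = np.arange(0, duration_s, 0.01)
    scale = h(fine).max()
    t = np.arange(0, duration_s, tr_s)
    return (h(t) / scale).astype(np.float64)


@dataclass(frozen=True)
class Effect:
    """One planted BOLD effect: which trials it applies to and where.

    ``condition`` / ``q1`` restrict the trials (None = no restriction);
    ``amplitude`` is in units of the noise SD relative to baseline.
    """

    rois: tuple
    amplitude: float
    condition: str | None = None
    q1: int | None = None

    def matches(self, trial_row) -> bool:
        if self.condition is not None and trial_row["condition"] != self.condition:
            return False
        if self.q1 is not None:
            if not np.isfinite(trial_row["q1_response"]):
                return False
            if int(trial_row["q1_response"]) != self.q1:
                return False
        return True


@dataclass(frozen=True)
class EffectSpec:
    """Collection of planted effects plus the HRF used to express them."""

    effects: tuple = ()
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0

    def hrf(self, tr_s: float) -> np.ndarray:
        return double_gamma_hrf(tr_s=tr_s, peak_s=self.hrf_peak_s,
                                undershoot_s=self.hrf_undershoot_s,
                                ratio=self.hrf_ratio)

    def validate(self, atlas: Parcellation) -> None:
        known = set(atlas.roi_names)
        for eff in self.effects:
            missing = set(eff.rois) - known
            if missing:
                raise ValueError(f"effect references missing ROI(s) {missing}")


def discriminative_effects(planted_rois, class_a=("Aristotle", 2),
                           class_b=("Reverse", 1), amp_a: float = 2.5,
                           amp_b: float = 0.8) -> EffectSpec:
    """Two-class effect spec: both classes activate the same ROIs with
    different amplitudes, so the planted ROIs carry the discriminative
    signal for a perception-based task."""
    ca, qa = class_a
    cb, qb = class_b
    return EffectSpec(effects=(
        Effect(rois=tuple(planted_rois), amplitude=amp_a, condition=ca, q1=qa),
        Effect(rois=tuple(planted_rois), amplitude=amp_b, condition=cb, q1=qb),
    ))


@dataclass(frozen=True)
class NoiseSpec:
    """Temporal noise model: white Gaussian innovations through an AR(1)
    filter, plus a constant baseline.  ``subject_jitter_sd`` multiplies each
    subject's effect amplitudes by ``1 + N(0, sd)``."""

    white_sd: float = 1.0
    ar1: float = 0.3
    baseline: float = 100.0
    subject_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.subject_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")


@dataclass
class Volume4D:
    """One session's 4D BOLD array (x, y, z, t) with acquisition metadata."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    subject: int
    session: int

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header["pixdim"][4] = self.tr_s
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, subject=0, session=0, tr_s=None) -> "Volume4D":
        img = nib.load(str(path))
        tr = float(img.header["pixdim"][4]) if tr_s is None else tr_s
        return cls(data=np.asarray(img.dataobj, dtype=np.float32), tr_s=tr,
                   affine=img.affine, subject=subject, session=session)


def epoch_regressor(onsets_s, duration_s, n_trs, tr_s, hrf) -> np.ndarray:
    """Boxcar time course of the given epochs convolved with the HRF,
    truncated to the scan length."""
    neural = np.zeros(n_trs)
    for onset in onsets_s:
        a = int(round(onset / tr_s))
        b = int(round((onset + duration_s) / tr_s))
        neural[a:min(b, n_trs)] = 1.0
    return np.convolve(neural, hrf)[:n_trs]


def simulate_session(events: pd.DataFrame, subject: int, session: int,
                     atlas: Parcellation, effects: EffectSpec,
                     noise: NoiseSpec, config: ParadigmConfig,
                     seed: int = 0) -> Volume4D:
    """Simulate one subject-session 4D BOLD volume.

    All randomness derives from ``(seed, subject, session)`` so individual
    sessions are independently reproducible.  Subject-level amplitude jitter
    derives from ``(seed, subject)`` only, so it is shared across sessions.
    """
    effects.validate(atlas)
    sel = events[(events["subject"] == subject) & (events["session"] == session)]
    if len(sel) == 0:
        raise ValueError(f"no events for subject {subject} session {session}")
    n_trs = config.n_trs_per_session
    end = sel["epoch2_onset_s"].max() + sel["epoch_duration_s"].max()
    if end > n_trs * config.tr_s + 1e-9:
        raise ValueError("event timing exceeds the scan length")
    hrf = effects.hrf(config.tr_s)

    subj_rng = np.random.default_rng([seed, subject])
    jitter = 1.0 + noise.subject_jitter_sd * subj_rng.standard_normal(
        max(len(effects.effects), 1))

    shape = atlas.shape
    data = np.full(shape + (n_trs,), noise.baseline, dtype=np.float32)
    for k, eff in enumerate(effects.effects):
        onsets = []
        for _, row in sel.iterrows():
            if eff.matches(row):
                onsets += [row["epoch1_onset_s"], row["epoch2_onset_s"]]
        if not onsets:
            continue
        reg = epoch_regressor(onsets, config.stim_duration_s, n_trs,
                              config.tr_s, hrf)
        roi_mask = np.isin(atlas.labels, list(eff.rois))
        data[roi_mask] += (eff.amplitude * jitter[k] * reg).astype(np.float32)

    if noise.white_sd > 0:
        rng = np.random.default_rng([seed, subject, session])
        innov = rng.standard_normal((int(np.prod(shape)), n_trs)).astype(np.float32)
        innov *= noise.white_sd
        if noise.ar1 > 0:
            # stationary AR(1): x_t = phi x_{t-1} + e_t, unit-SD innovations
            innov = lfilter([1.0], [1.0, -noise.ar1], innov, axis=1)
        data += innov.reshape(shape + (n_trs,)).astype(np.float32)
    return Volume4D(data=data, tr_s=config.tr_s, affine=atlas.affine,
                    subject=subject, session=session)


def simulate_cohort(events: pd.DataFrame, atlas: Parcellation,
                    effects: EffectSpec, noise: NoiseSpec,
                    config: ParadigmConfig, seed: int = 0
                    ) -> Iterator[Volume4D]:
    """Yield one Volume4D per (subject, session) present in ``events``."""
    keys = events[["subject", "session"]].drop_duplicates().sort_values(
        ["subject", "session"])
    for _, (subject, session) in keys.iterrows():
        yield simulate_session(events, int(subject), int(session), atlas,
                               effects, noise, config, seed=seed)
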