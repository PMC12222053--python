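"""Shared fixtures: tiny study configurations that exercise the full
pipeline at second-scale cost, and the behavioral-table transcription."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tacdecode import paradigm as pg

#: trial-level response counts reproducing the study's cohort behavioral
#: table exactly (epoch counts halved: 596 = 2 x 298 responded trials etc.)
TABLE_COUNTS = {
    "Aristotle": {1: 26, 2: 272, None: 2},
    "Reverse": {1: 106, 2: 191, None: 3},
    "Asynchronous": {1: 24, 2: 271, None: 5},
}


@pytest.fixture(scope="session")
def cohort_events():
    """30-subject, 2-session event table with exact transcribed responses."""
    cfg = pg.ParadigmConfig(seed=7)
    events = pg.generate_paradigm(cfg, n_subjects=30)
    return pg.assign_responses_from_counts(events, TABLE_COUNTS)


@pytest.fixture(scope="session")
def tiny_study():
    """A small, strongly separable synthetic study: 4 subjects, 12^3 grid,
    8 ROIs with signal planted in two of them, trained 2-fold.

    Session-scoped: several tests share the trained models and maps.
    """
    from types import SimpleNamespace

    from tacdecode import dataset as ds, synth, train as tr
    from tacdecode.sfcn import SFCNConfig

    pcfg = pg.ParadigmConfig(n_sessions=1, seed=11)
    events = pg.generate_paradigm(pcfg, n_subjects=6)
    events = pg.simulate_behavior(events, pg.BehaviorModel(seed=12))
    atlas = synth.generate_atlas((12, 12, 12), n_rois=8, seed=13)
    planted = (2, 5)
    effects = synth.discriminative_effects(planted, amp_a=5.0, amp_b=0.5)
    noise = synth.NoiseSpec(white_sd=0.4, ar1=0.2)
    samples, metas = [], []
    for vol in synth.simulate_cohort(events, atlas, effects, noise, pcfg,
                                     seed=14):
        x, meta = ds.extract_epoch_samples(vol, events)
        samples.append(x)
        metas.append(meta)
    x = np.concatenate(samples)
    meta = pd.concat(metas, ignore_index=True)
    lset = ds.assign_task_labels(x, meta,
                                 "aristotle_illusion_vs_reverse_illusion")
    folds = ds.make_folds(lset, k=2, seed=15)
    # no pooling: on the 12-voxel grid the saliency layer keeps full
    # resolution and a 3-voxel receptive field, so maps can localize
    mcfg = SFCNConfig(block_channels=(6, 8), pool_blocks=(False, False),
                      seed=16)
    tcfg = tr.TrainConfig(task=lset.task, lr=1e-3, weight_decay=0.4,
                          batch_size=8, epochs=24, seed=17)
    cv = tr.cross_validate(lset, folds, tcfg, mcfg)
    return SimpleNamespace(events=events, atlas=atlas, planted=planted,
                           effects=effects, noise=noise, paradigm=pcfg,
                           sample_set=lset, folds=folds, cv=cv,
                           model_config=mcfg, train_config=tcfg)
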