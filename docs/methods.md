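# Methods

`tacdecode` re-creates, end to end, a perception-decoding analysis of
block-design tactile fMRI: a synthetic study generator, a lightweight 3D
convolutional classifier (SFCN family), Grad-CAM saliency mapping, and a
grand-mean ROI statistic that recovers the regions driving the classifier.
Because no real recordings from the tactile-illusion study are publicly
available, every quantitative result this package produces is computed on
synthetic data whose design mirrors the study; the synthetic generator is
therefore first-class, tested code, and its assumptions are spelled out
below.

## Experimental design being emulated

Crossing the index and middle fingers and touching a single ball between
them evokes the percept of two objects (the Aristotle illusion); touching
two balls on the outer sides of the crossed fingers evokes one object (the
Reverse illusion).  The emulated experiment presents three stimulus
conditions — Aristotle, Reverse, and Asynchronous (a veridical two-object
control) — in trials of fixed structure: 15 s stimulation, a 3-s
"one or two?" question (Q1), another 15 s of the same stimulus, a 6-s
perceived-distance question (Q2, four buttons), and 9 s of rest.  A trial
cycle is therefore 15+3+15+6+9 = 48 s; 15 trials (5 per condition, order
randomized) fill a 720-s session, and each of the 30 simulated participants
completes two sessions (1,440 s) at TR = 3 s.

Behavior is simulated at the trial level.  A trial is an *illusion trial*
when the reported count matches the illusory percept (Q1 = 2 under
Aristotle; Q1 = 1 under Reverse or Asynchronous).  Default illusion
probabilities are the cohort-level response frequencies of the study's
behavioral table — 544/596 (Aristotle), 212/594 (Reverse), 48/590
(Asynchronous) — with non-response probabilities 2/300, 3/300 and 5/300 per
trial.  Those counts are epoch-level in the source table; they divide
evenly by two, which is why the generator treats them as trial counts times
two epochs.  The illusion rate excludes non-responses from the denominator.
Q2 distance distributions are free parameters; only their ordering
(Aristotle > Asynchronous > Reverse in the mean) is meaningful, the
categorical probabilities themselves are conventions.

## Synthetic brain and BOLD model

The atlas is a seeded Voronoi partition of an ellipsoidal brain mask
(semi-axes 0.45 x grid), refined by ten Lloyd iterations so region volumes
are comparable — degenerate sliver regions otherwise sit entirely inside a
neighbouring region's saliency halo and confound the ROI statistics.  The
default desk-scale atlas is 40 ROIs on a 32^3 grid; any NIfTI label volume
can be substituted for real-atlas work.

Voxel time series are

    baseline + sum_e amplitude_e * jitter_subject * (boxcar_e (x) HRF) + AR(1) noise,

where each effect `e` selects trials by condition and/or simulated Q1
response and adds its regressor only inside its designated ROIs.  The HRF
is the canonical double-gamma (peak 6 s, undershoot 16 s, peak:undershoot
6:1), normalized to unit peak and sampled at the TR.  Noise is white
Gaussian innovation (SD 1.0) through an AR(1) filter (coefficient 0.3) on a
baseline of 100; per-subject amplitude jitter is multiplicative with SD
0.1.  Label-linked signal exists nowhere except the planted ROIs, which is
what makes planted-ROI recovery a meaningful end-to-end check.

Effect amplitudes are free parameters: the study reports no activation
magnitudes.  The desk-scale defaults (1.3 for the Aristotle-illusion
class, 1.0 for the Reverse-illusion class, in units of the noise SD) were
calibrated once, under a training budget at which every fold converges,
so that the scaled-down classifier lands in the study's own accuracy
regime (roughly 0.7–0.9 validation accuracy) rather than saturating at
1.0; a saturated task is both unrealistic and statistically degenerate,
because every subject's saliency map then shares near-identical
structure.  The calibration target is the accuracy regime, never the
downstream ROI statistics.

## Dataset construction

Each responded trial contributes two samples, one per stimulation epoch:
the voxelwise mean of the five volumes in the window
[onset + 6 s, onset + 21 s) — the +2 TR shift matches the canonical HRF
peak.  Samples are z-scored voxelwise within each session.  Five binary
tasks are defined; three stimulus-based (Aristotle vs Reverse, Reverse vs
Asynchronous, Aristotle vs Asynchronous) and two perception-based
(Aristotle-illusion vs Reverse-illusion; Reverse-illusion occurrence vs
absence).  Trials with no Q1 response are excluded everywhere.  The
occurrence-vs-absence-of-Aristotle-illusion contrast is constructible but
not trained by default: at the study's response rates it is hopelessly
imbalanced (52 vs 544 epochs).

Cross-validation is 5-fold and grouped at the trial level, so the two
epochs of a trial are never split across training and validation (an 8:2
split per fold).  Class imbalance is corrected by randomly undersampling
the training majority class; validation sets are never resampled.

## Classifier

The SFCN-family classifier is a stack of blocks, each a 3^3 convolution +
batch norm + ReLU, most followed by 2x max pooling, with a final 1^3
convolution block, then global average pooling, dropout and a fully
connected layer producing two class scores.  The full-scale configuration
(32, 64, 128, 256, 256, 64 channels, five poolings) matches the published
SFCN design for large MRI grids (~2.9 M parameters at 2 classes).  The
desk-scale default is deliberately shallower: 3 blocks (8, 16, 16) with a
single pooling, so on a 32^3 grid the saliency layer keeps 16^3 resolution
and an 8-voxel receptive field — about one ROI diameter.  Deeper,
more-pooled variants classify equally well here but smear Grad-CAM
attribution across neighbouring ROIs, which defeats the point of the
analysis at this grid size.

The network, its backpropagation, and the optimizers are implemented
directly in numpy (with numba-accelerated convolution kernels and a pure
numpy fallback kept in exact agreement by tests); float32 throughout.
Max-pool gradient ties go to the first maximum.  Training minimizes
softmax cross-entropy with an AdamW-style optimizer — decoupled weight
decay applied to weight matrices but not to norm/bias parameters.  The
printed per-task optima (e.g. learning rate 3e-4, weight decay 0.4, batch
32 for the illusion-vs-illusion task) are kept as the per-task defaults;
the desk-scale pipeline overrides the learning rate to 1e-3 because those
optima were tuned for the full-scale study and the synthetic task does not
leave the one-class plateau within a small epoch budget at 3e-4.  Training
runs 16 epochs by default with the best-validation-accuracy checkpoint
kept; ties are broken toward the later epoch, since among equally accurate
checkpoints the most-trained one has the best-formed features for saliency.
Whether the reference analysis used best-epoch or final-epoch metrics is
unknown; best-epoch is reported.  The desk-scale epoch budget is 24:
training exhibits a long one-class plateau (loss falls for several epochs
while the model still predicts a single class) before separation snaps
in, and shorter budgets leave some folds on the plateau, which corrupts
both the metrics and the saliency maps.

## Grad-CAM and ROI statistics

For every validation sample, saliency is L = ReLU(sum_k alpha_k A_k) with
alpha_k the spatial mean of the gradient of the *true-label* pre-softmax
score with respect to channel k of the last convolutional block's
activation (a predicted-class mode is available).  Maps are upsampled
trilinearly (corner-aligned) to the input grid and averaged pixel-wise —
no per-map normalization, which would break plain averaging; normalization
is offered only for visualization.  Per-subject maps pool that subject's
validation samples across all folds.

Per subject and ROI, the mean saliency inside the label defines a
subjects x ROIs matrix; the grand mean is the average over all its cells
and is treated as a fixed reference constant (exactly as the source
procedure describes — a statistical simplification, since the grand mean is
itself estimated).  Each ROI's subject values minus the grand mean enter a
two-sided one-sample Wilcoxon signed-rank test (exact null distribution up
to n = 25 when the nonzero |differences| are untied, normal approximation
otherwise; zeros discarded).  P-values are corrected across ROIs by
Benjamini-Hochberg.  A *discovery* additionally requires the ROI mean to
lie above the grand mean: the question asked of the data is which regions
show *elevated* saliency, and a two-sided q < alpha alone would also flag
regions with consistently depressed saliency (e.g. near-empty maps), which
is not a salient region by any reading.  Both flags are reported in the
output table.

### Known limitation: neighbour bleed under shared models

The saliency halo — receptive field plus upsampling — has a spatial scale
of a few voxels.  ROIs adjacent to a truly salient region therefore
receive a small but *systematic* share of its saliency.  Because all
subjects are scored by the same five fold models, that bleed is consistent
across subjects, and a rank test against a fixed grand mean flags any
consistent elevation regardless of magnitude.  Empirically, on the
desk-scale planted study the procedure recovers every planted ROI at the
top of the saliency ranking, reports zero discoveries on label-shuffled
null data, and additionally flags roughly four immediate Voronoi
neighbours of the planted ROIs at several-fold lower saliency — the
bleed is a few-voxel-deep, deterministic, and therefore maximally
"consistent" to a signed-rank test.  The discovery list should be read
together with the `mean_saliency` column, which separates the driver
regions from their halo cleanly; with exchangeable synthetic subjects no
CNN of useful depth can shrink the halo below one ROI diameter, so the
neighbour discoveries are a property of the grand-mean procedure itself,
inherited by design.  Real cohorts add anatomical and physiological
between-subject variability that the generator does not model, which
relaxes this anticonservativeness but also lowers power; passing tests on
synthetic data demonstrate correct mechanics, not field performance.

## Null calibration

The null condition used for calibration checks keeps the full generative
structure but makes the two perception classes share an identical
amplitude and then permutes trial labels, so volumes carry activation yet
no label information.  Under this null the classifier's validation
accuracy stays within binomial error of 0.5 (the best-checkpoint selection
inflates the expectation slightly above 0.5, which the acceptance band
accounts for), and the ROI procedure's discovery fraction is required to
stay at or below the FDR level.

## Problem sizes and run times

The desk-scale study (12 subjects x 2 sessions x 15 trials, 32^3 grid, 40
ROIs, 5 folds, 24 epochs) runs in about ten minutes on a single CPU core;
the null replicates use 8 subjects, 2 folds and 8 epochs.  The full-scale
configuration (120 ROIs, MNI-like grids, 6-block SFCN) is exposed through
the same config surface for users with real data and more compute.

## Numerical conventions

Seeds fan out from one global seed through a stable per-stage hash, so
every stage is independently reproducible and bit-identical across reruns.
Atlas generation retries seed draws (up to 20) until every ROI has >= 8
voxels.  Voxelwise z-scoring maps constant voxels to zero.  Degenerate
inputs fail loudly: empty validation sets, empty classes, unknown tasks or
layers, windows past the scan end, and effects referencing missing ROIs
all raise with specific messages.
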