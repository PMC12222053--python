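"""Grad-CAM saliency for the 3D classifier.

The saliency map of a sample for class c is

    L = ReLU( sum_k alpha_k A_k ),    alpha_k = spatial-mean dy_c / dA_k

where A_k are the channel activations of the last convolutional block and
y_c is the pre-softmax class score.  Maps are computed at feature
resolution, upsampled trilinearly to the input grid, and averaged
pixel-wise across validation samples (no per-map normalization, so the
average of maps equals the map of averages of the weighted sums only up to
the ReLU — the arithmetic mean here is taken over the final maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .sfcn import SFCN


@dataclass
class GradCAMResult:
    """Everything the Grad-CAM expression touches, for one sample."""

    feature_maps: np.ndarray      # A_k: (C, d, h, w)
    weights: np.ndarray           # alpha_k: (C,)
    target_class: int             # c in y_c
    score: float                  # y_c (pre-softmax)
    map: np.ndarray               # L: (d, h, w), nonnegative
    upsampled: np.ndarray | None  # L at input resolution


def gradcam(model: SFCN, sample: np.ndarray, target_class: int,
            layer: str | None = None,
            upsample_to: tuple | None = None) -> GradCAMResult:
    """Compute the Grad-CAM map of one 3D sample.

    ``sample`` is a bare (d, h, w) volume; the gradient is taken of the
    requested pre-softmax class score.  ``layer`` defaults to the model's
    last convolutional block activation; an unknown name raises ``KeyError``
    listing the available layers.
    """
    x = np.ascontiguousarray(sample[None, None], dtype=np.float32)
    logits, act = model.forward_with_activation(x, layer=layer, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.zero_grads()
    dact = model.backward_to_activation(dlogits, layer=layer)
    a = act[0]                                  # (C, d, h, w)
    alpha = dact[0].mean(axis=(1, 2, 3))        # global-pooled gradient
    cam = np.maximum((alpha[:, None, None, None] * a).sum(axis=0), 0.0)
    up = None
    if upsample_to is not None:
        up = upsample(cam, upsample_to)
    return GradCAMResult(feature_maps=a, weights=alpha,
                         target_class=int(target_class),
                         score=float(logits[0, target_class]),
                         map=cam.astype(np.float32), upsampled=up)


def gradcam_batch(model: SFCN, samples: np.ndarray, target_classes,
                  layer: str | None = None,
                  upsample_to: tuple | None = None) -> list:
    """Grad-CAM maps for a batch of (n, d, h, w) samples at once.

    Equivalent to calling :func:`gradcam` per sample (the class-score
    gradient of one sample does not touch another sample's activations),
    but amortizes the forward/backward passes.  Returns the list of maps.
    """
    x = np.ascontiguousarray(samples[:, None], dtype=np.float32)
    logits, act = model.forward_with_activation(x, layer=layer, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[np.arange(len(x)), np.asarray(target_classes, dtype=int)] = 1.0
    model.zero_grads()
    dact = model.backward_to_activation(dlogits, layer=layer)
    alpha = dact.mean(axis=(2, 3, 4))                      # (n, C)
    cams = np.maximum((alpha[:, :, None, None, None] * act).sum(axis=1), 0.0)
    if upsample_to is None:
        return [c.astype(np.float32) for c in cams]
    return [upsample(c, upsample_to) for c in cams]


def upsample(vol: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear (corner-aligned) upsampling of a 3D map.

    Identity when the shapes match; a size-1 source axis broadcasts as a
    constant.  Linear interpolation preserves nonnegativity.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < s for t, s in zip(target_shape, vol.shape)):
        raise ValueError(f"target {target_shape} smaller than map {vol.shape}")
    if any(t < 1 for t in target_shape):
        raise ValueError("degenerate target shape")
    if target_shape == vol.shape:
        return vol.copy()
    axes = []
    for s, t in zip(vol.shape, target_shape):
        if t == 1 or s == 1:
            axes.append(np.zeros(t))
        else:
            axes.append(np.linspace(0.0, s - 1.0, t))
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    out = map_coordinates(vol.astype(np.float64), coords, order=1,
                          mode="nearest")
    return out.astype(np.float32)


def average_maps(maps) -> np.ndarray:
    """Voxelwise arithmetic mean of aligned 3D maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps must share a common shape")
    return np.mean(np.stack(maps), axis=0).astype(np.float32)


def subject_mean_maps(maps, subject_ids) -> dict:
    """Per-subject pixel-wise mean over that subject's maps (validation
    samples pooled across folds)."""
    maps = list(maps)
    subject_ids = list(subject_ids)
    if len(maps) != len(subject_ids):
        raise ValueError("maps and subject_ids must align")
    out = {}
    for subject in sorted(set(subject_ids)):
        sel = [m for m, s in zip(maps, subject_ids) if s == subject]
        out[subject] = average_maps(sel)
    return out


def validation_saliency(cv_result, sample_set, layer: str | None = None,
                        target: str = "true"):
    """Grad-CAM maps for every validation sample of a cross-validation run.

    ``target``: "true" differentiates the sample's true-label score (the
    default), "pred" the predicted-class score.  Returns
    ``(maps, subject_ids)`` with maps at input resolution.
    """
    if target not in ("true", "pred"):
        raise ValueError("target must be 'true' or 'pred'")
    grid = sample_set.samples.shape[1:]
    maps, subjects = [], []
    for model, val_idx in zip(cv_result.models, cv_result.fold_val_indices):
        val = sample_set.subset(val_idx)
        if target == "pred":
            classes = model.predict(
                np.ascontiguousarray(val.samples[:, None], dtype=np.float32))
        else:
            classes = val.labels
        for i in range(0, len(val), 16):
            maps.extend(gradcam_batch(model, val.samples[i:i + 16],
                                      classes[i:i + 16], layer=layer,
                                      upsample_to=grid))
        subjects.extend(int(s) for s in val.meta["subject"])
    return maps, subjects
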