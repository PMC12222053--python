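"""Static figure export: orthogonal saliency slices and subject scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def save_orthogonal_slices(map3d: np.ndarray, path, title: str = "",
                           cmap: str = "hot") -> None:
    """Mid-volume axial/coronal/sagittal slices of a 3D map as one PNG."""
    x, y, z = (s // 2 for s in map3d.shape)
    views = [
        (map3d[x, :, :].T, "sagittal"),
        (map3d[:, y, :].T, "coronal"),
        (map3d[:, :, z].T, "axial"),
    ]
    vmax = float(map3d.max()) or 1.0
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, (sl, name) in zip(axes, views):
        im = ax.imshow(sl, origin="lower", cmap=cmap, vmin=0, vmax=vmax)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.colorbar(im, ax=axes, fraction=0.025)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def save_subject_scatter(summary, path, title: str = "") -> None:
    """Subject-wise saliency per discovered ROI with group mean +/- SE and
    the grand mean as a dashed reference line."""
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(summary.summary)), 3.5))
    if summary.empty:
        ax.text(0.5, 0.5, "no ROIs passed the threshold",
                ha="center", va="center")
    else:
        labels = list(summary.summary["label"])
        for i, lab in enumerate(labels):
            vals = summary.per_roi[summary.per_roi["label"] == lab]["value"]
            ax.scatter(np.full(len(vals), i), vals, color="0.6", s=12,
                       zorder=2)
        means = summary.summary["mean"]
        ses = summary.summary["se"].fillna(0.0)
        ax.errorbar(range(len(labels)), means, yerr=ses, fmt="o", color="red",
                    ecolor="black", capsize=3, zorder=3)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(summary.summary["name"], rotation=45, ha="right",
                           fontsize=8)
    ax.axhline(summary.grand_mean, ls="--", color="tab:blue", lw=1,
               label="grand mean")
    ax.set_ylabel("ROI mean saliency")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
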