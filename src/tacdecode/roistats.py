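"""Atlas-ROI statistics on saliency maps.

Per subject, the mean saliency inside each atlas region is computed; the
grand mean is the average over all (subject, ROI) cells.  Each ROI's
subject values are compared to the grand mean with a one-sample Wilcoxon
signed-rank test (exact null distribution up to n = 25 without rank ties,
normal approximation beyond; zero differences are discarded, Wilcoxon's
convention), and p-values are corrected across ROIs with the
Benjamini-Hochberg step-up procedure.  An ROI is reported as a discovery
("elevated") when q < alpha AND its mean lies above the grand mean; the
two-sided q < alpha flag is kept separately, since a region with
consistently *depressed* saliency is not a salient region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import Parcellation


def roi_means(map3d: np.ndarray, atlas: Parcellation) -> pd.Series:
    """Mean map value within each atlas label > 0 (background excluded)."""
    if map3d.shape != atlas.shape:
        raise ValueError(
            f"map grid {map3d.shape} does not match atlas {atlas.shape}")
    labels = atlas.labels.ravel()
    vals = map3d.astype(np.float64).ravel()
    n_lab = max(atlas.roi_names) + 1
    sums = np.bincount(labels, weights=vals, minlength=n_lab)
    counts = np.bincount(labels, minlength=n_lab)
    keys = sorted(atlas.roi_names)
    means = [sums[k] / counts[k] if counts[k] else np.nan for k in keys]
    return pd.Series(means, index=pd.Index(keys, name="label"),
                     name="mean_saliency")


def subject_roi_matrix(subject_maps: dict, atlas: Parcellation) -> pd.DataFrame:
    """Subjects x ROIs matrix of per-subject ROI mean saliency."""
    rows = {s: roi_means(m, atlas) for s, m in subject_maps.items()}
    mat = pd.DataFrame(rows).T
    mat.index.name = "subject"
    return mat.sort_index()


def grand_mean(matrix: pd.DataFrame) -> float:
    """Scalar mean over every (subject, ROI) entry."""
    if matrix.size == 0:
        raise ValueError("empty subject x ROI matrix")
    return float(np.asarray(matrix, dtype=float).mean())


def wilcoxon_signed_rank(diffs: np.ndarray, alternative: str = "two-sided"):
    """One-sample Wilcoxon signed-rank test of ``diffs`` against zero.

    Returns ``(statistic, p, n_effective)``; zeros are discarded first.
    Exact distribution when n_effective <= 25 and the nonzero |diffs| are
    untied, otherwise the normal approximation.  All diffs zero -> p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return np.nan, 1.0, 0
    ranks_tied = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                         method=method)
    return float(res.statistic), float(res.pvalue), n


@dataclass
class ROIStatsTable:
    """Per-ROI statistics plus the scalar grand mean used as reference."""

    table: pd.DataFrame
    grand_mean: float
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        """Two-sided q < alpha rows."""
        return self.table[self.table["significant"]]

    @property
    def elevated(self) -> pd.DataFrame:
        """Discoveries: q < alpha and ROI mean above the grand mean."""
        return self.table[self.table["elevated"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def test_rois(matrix: pd.DataFrame, grand: float | None = None,
              alpha: float = 0.05, alternative: str = "two-sided",
              roi_names: dict | None = None) -> ROIStatsTable:
    """Wilcoxon signed-rank of each ROI's subject means against the grand
    mean, with Benjamini-Hochberg FDR across ROIs.

    The grand mean is treated as a fixed reference constant (it is not
    re-estimated per test).  ROIs whose differences are identically zero
    are untestable: p = 1, flagged.
    """
    if grand is None:
        grand = grand_mean(matrix)
    rows = []
    for label in matrix.columns:
        vals = matrix[label].to_numpy(dtype=float)
        stat, p, n_eff = wilcoxon_signed_rank(vals - grand, alternative)
        rows.append({
            "label": label,
            "name": (roi_names or {}).get(label, f"ROI_{int(label):03d}"),
            "mean_saliency": float(vals.mean()),
            "n_effective": n_eff,
            "statistic": stat,
            "p": p,
            "untestable": n_eff == 0,
        })
    table = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(table["p"].to_numpy(), alpha=alpha,
                                    method="fdr_bh")
    table["q"] = q
    table["significant"] = reject
    table["elevated"] = reject & (table["mean_saliency"] > grand)
    return ROIStatsTable(table=table, grand_mean=float(grand), alpha=alpha)


@dataclass
class SubjectSaliencySummary:
    """Per-significant-ROI subject values with group mean +/- SE, plus each
    subject's whole-matrix mean (the narrow-distribution check)."""

    per_roi: pd.DataFrame         # label, name, subject, value
    summary: pd.DataFrame         # label, name, mean, se, n
    subject_means: pd.Series      # subject -> mean over all ROIs
    grand_mean: float
    empty: bool = False


def subject_saliency_summary(matrix: pd.DataFrame, stats_table: ROIStatsTable,
                             which: str = "elevated"
                             ) -> SubjectSaliencySummary:
    """Subject-wise saliency values for each discovered ROI.

    SE = SD / sqrt(n) with ddof 1; reported as NaN for a single subject.
    An empty discovery set returns an empty summary with ``empty=True``.
    """
    sel = getattr(stats_table, which)
    subject_means = matrix.mean(axis=1)
    subject_means.name = "subject_mean_saliency"
    if len(sel) == 0:
        return SubjectSaliencySummary(
            per_roi=pd.DataFrame(columns=["label", "name", "subject", "value"]),
            summary=pd.DataFrame(columns=["label", "name", "mean", "se", "n"]),
            subject_means=subject_means,
            grand_mean=stats_table.grand_mean, empty=True)
    per_rows, sum_rows = [], []
    for _, row in sel.iterrows():
        label = row["label"]
        vals = matrix[label]
        for subject, v in vals.items():
            per_rows.append({"label": label, "name": row["name"],
                             "subject": subject, "value": float(v)})
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        sum_rows.append({"label": label, "name": row["name"],
                         "mean": float(vals.mean()), "se": se, "n": n})
    return SubjectSaliencySummary(per_roi=pd.DataFrame(per_rows),
                                  summary=pd.DataFrame(sum_rows),
                                  subject_means=subject_means,
                                  grand_mean=stats_table.grand_mean)
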