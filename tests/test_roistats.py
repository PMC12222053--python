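"""ROI saliency statistics: means, grand mean, Wilcoxon vs grand mean,
Benjamini-Hochberg correction and subject summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from tacdecode import roistats as rs
from tacdecode.synth import Parcellation


def tiny_atlas(labels):
    labels = np.asarray(labels)
    names = {int(k): f"ROI_{int(k):03d}" for k in np.unique(labels) if k > 0}
    return Parcellation(labels=labels, roi_names=names)


class TestROIMeans:
    def test_uniform_map_gives_constant_means(self):
        atlas = tiny_atlas(np.array([[[0, 1], [1, 2]], [[2, 2], [3, 3]]]))
        means = rs.roi_means(np.full(atlas.shape, 3.25), atlas)
        assert (means == 3.25).all()

    def test_indicator_map_isolates_one_roi(self):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[0] = 1
        labels[1] = 3
        labels[2] = 2
        atlas = tiny_atlas(labels)
        m = (labels == 3).astype(float)
        means = rs.roi_means(m, atlas)
        assert means[3] == 1.0
        assert means[1] == 0.0 and means[2] == 0.0

    def test_checkerboard_two_voxel_roi(self):
        labels = np.zeros((2, 1, 1), dtype=int)
        labels[:, 0, 0] = 4
        atlas = tiny_atlas(labels)
        m = np.array([0.0, 2.0]).reshape(2, 1, 1)
        assert rs.roi_means(m, atlas)[4] == 1.0

    def test_grid_mismatch_rejected(self):
        atlas = tiny_atlas(np.ones((2, 2, 2), dtype=int))
        with pytest.raises(ValueError, match="match"):
            rs.roi_means(np.zeros((3, 3, 3)), atlas)


class TestGrandMean:
    def test_small_matrix(self):
        m = pd.DataFrame([[1.0, 3.0], [5.0, 7.0]])
        assert rs.grand_mean(m) == 4.0

    def test_constant_matrix(self):
        m = pd.DataFrame(np.full((4, 6), 2.2))
        assert rs.grand_mean(m) == pytest.approx(2.2)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((5, 7)))
        shuffled = m.sample(frac=1, random_state=1)[
            rng.permutation(m.columns)]
        assert rs.grand_mean(m) == pytest.approx(rs.grand_mean(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.grand_mean(pd.DataFrame())


def exhaustive_wilcoxon_two_sided(diffs):
    """Exact two-sided one-sample Wilcoxon signed-rank p by enumerating all
    sign assignments of the ranked |differences| (zeros discarded)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if min(w, total - w) <= w_obs + 1e-12:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_all_above_grand_mean_exact_p(self):
        # n = 8 strictly positive differences: two-sided p = 2 / 2^8
        diffs = np.arange(1, 9, dtype=float)
        _, p, n_eff = rs.wilcoxon_signed_rank(diffs)
        assert n_eff == 8
        assert p == pytest.approx(2 / 256)

    def test_identical_to_grand_mean_untestable(self):
        _, p, n_eff = rs.wilcoxon_signed_rank(np.zeros(10))
        assert p == 1.0 and n_eff == 0

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng([n, seed])
        diffs = rng.standard_normal(n)
        _, p, _ = rs.wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(exhaustive_wilcoxon_two_sided(diffs),
                                  abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6),
                    min_size=4, max_size=9, unique_by=abs))
    def test_exact_p_property_over_random_differences(self, diffs):
        """For untied nonzero differences the exact p always equals the
        enumeration oracle and lies in (0, 1]."""
        _, p, n_eff = rs.wilcoxon_signed_rank(np.array(diffs))
        assert n_eff == len(diffs)
        assert 0 < p <= 1
        assert p == pytest.approx(exhaustive_wilcoxon_two_sided(diffs),
                                  abs=1e-12)

    def test_zeros_discarded_before_ranking(self):
        diffs = np.array([0.0, 0.0, 1.0, 2.0, -0.5])
        _, p, n_eff = rs.wilcoxon_signed_rank(diffs)
        assert n_eff == 3
        assert p == pytest.approx(exhaustive_wilcoxon_two_sided(diffs))


class TestFDR:
    def test_hand_computed_bh_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.8],
                                   atol=1e-12)

    def test_test_rois_reproduces_bh_on_its_pvalues(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.standard_normal((10, 6)),
                           columns=range(1, 7))
        table = rs.test_rois(mat).table
        _, q, _, _ = multipletests(table["p"].to_numpy(), alpha=0.05,
                                   method="fdr_bh")
        np.testing.assert_allclose(table["q"], q, atol=1e-12)
        assert ((table["q"] >= 0) & (table["q"] <= 1)).all()


class TestROITable:
    def test_elevated_requires_mean_above_grand(self):
        rng = np.random.default_rng(0)
        # ROI 1 far above the grand mean, ROI 2 far below, ROI 3 null
        mat = pd.DataFrame({
            1: 5.0 + 0.1 * rng.standard_normal(12),
            2: -5.0 + 0.1 * rng.standard_normal(12),
            3: 0.3 * rng.standard_normal(12),
        })
        out = rs.test_rois(mat)
        table = out.table.set_index("label")
        assert table.loc[1, "significant"] and table.loc[1, "elevated"]
        assert table.loc[2, "significant"] and not table.loc[2, "elevated"]

    def test_fixed_grand_mean_reference(self):
        mat = pd.DataFrame({1: [1.0, 2, 3, 4, 5, 6, 7, 8]})
        out = rs.test_rois(mat, grand=0.0)
        assert out.table["p"].iloc[0] == pytest.approx(2 / 256)

    def test_null_calibration_under_exchangeable_noise(self):
        # 50 replicate null matrices: on average no more than 5% of ROIs
        # may come out elevated-significant at FDR 0.05
        n_sig = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            mat = pd.DataFrame(rng.standard_normal((12, 40)),
                               columns=range(1, 41))
            n_sig.append(len(rs.test_rois(mat).elevated))
        assert np.mean(n_sig) <= 0.05 * 40


class TestSubjectSummary:
    def _stats_for(self, mat, grand=None):
        return rs.test_rois(mat, grand=grand)

    def test_mean_and_standard_error(self):
        # values {1, 2, 3} repeated: mean 2, SE = SD/sqrt(n)
        vals = [1.0, 2.0, 3.0] * 3
        mat = pd.DataFrame({1: vals})
        out = self._stats_for(mat, grand=0.0)
        summary = rs.subject_saliency_summary(mat, out, which="significant")
        row = summary.summary.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(np.std(vals, ddof=1) / 3.0)

    def test_single_subject_se_not_available(self):
        mat = pd.DataFrame({1: [4.0]})
        table = rs.ROIStatsTable(
            table=pd.DataFrame({"label": [1], "name": ["ROI_001"],
                                "mean_saliency": [4.0], "n_effective": [1],
                                "statistic": [0.0], "p": [0.01],
                                "untestable": [False], "q": [0.01],
                                "significant": [True], "elevated": [True]}),
            grand_mean=0.0, alpha=0.05)
        summary = rs.subject_saliency_summary(mat, table)
        assert np.isnan(summary.summary["se"].iloc[0])

    def test_constant_values_zero_se(self):
        mat = pd.DataFrame({1: [2.0] * 6})
        out = self._stats_for(mat, grand=0.0)
        summary = rs.subject_saliency_summary(mat, out, which="significant")
        assert summary.summary["se"].iloc[0] == 0.0

    def test_empty_discovery_set(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.standard_normal((8, 5)),
                           columns=range(1, 6))
        out = rs.test_rois(mat)
        summary = rs.subject_saliency_summary(mat, out)
        if len(out.elevated) == 0:
            assert summary.empty
        assert len(summary.subject_means) == 8
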