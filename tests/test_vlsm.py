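"""Voxel-wise t-maps, Benjamini–Hochberg FDR and 3D clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lesym
from lesym.cohort import AnalysisMask, analysis_mask, prevalence_map
from lesym.grid import VoxelGrid
from lesym.vlsm import TMap, bh_fdr, label_clusters, voxelwise_t

from conftest import bh_oracle, flood_fill_labels, make_cohort


def _single_voxel_cohort(lesioned_flags):
    """Cohort whose only voxel of interest is (0,0,0)."""
    n = len(lesioned_flags)
    wml = np.zeros((n, 2, 2, 2), dtype=np.uint8)
    wml[np.asarray(lesioned_flags, dtype=bool), 0, 0, 0] = 1
    return make_cohort(wml)


def _mask_for(cohort, min_patients=1):
    return analysis_mask(prevalence_map(cohort, "wml"), min_patients)


def _tmap_from_p(p_values):
    """Minimal TMap carrying arbitrary p-values (for FDR-only tests)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    grid = VoxelGrid(shape=(m, 1, 1), voxel_size_mm=(1.0, 1.0, 1.0))
    mask = AnalysisMask(mask=np.ones((m, 1, 1), bool), min_patients=1, grid=grid)
    t = -stats.norm.ppf(p)  # any monotone decreasing transform of p
    return TMap(
        t=t.reshape(m, 1, 1), p=p.reshape(m, 1, 1),
        df=np.full((m, 1, 1), 10.0), valid=np.ones((m, 1, 1), bool),
        mask=mask, lesion_class="wml", alternative="greater",
    )


class TestVoxelwiseT:
    def test_identical_group_means_give_t_zero(self):
        cohort = _single_voxel_cohort([1, 1, 0, 0])
        y = pd.Series([1.0, 2.0, 1.0, 2.0], index=cohort.patient_ids)
        tmap = voxelwise_t(cohort, y, _mask_for(cohort, 2))
        assert tmap.t[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_reference_example_pooled_t(self):
        # intact residuals {1,2,3}, lesioned {-1,0,1}: pooled SD 1,
        # t = (2 - 0)/(1*sqrt(2/3)) = +2.449, df = 4
        cohort = _single_voxel_cohort([0, 0, 0, 1, 1, 1])
        y = pd.Series([1.0, 2.0, 3.0, -1.0, 0.0, 1.0], index=cohort.patient_ids)
        tmap = voxelwise_t(cohort, y, _mask_for(cohort, 3))
        assert tmap.t[0, 0, 0] == pytest.approx(np.sqrt(6), abs=1e-9)
        assert tmap.df[0, 0, 0] == 4
        assert tmap.p[0, 0, 0] == pytest.approx(stats.t.sf(np.sqrt(6), 4), abs=1e-12)

    def test_sign_convention_lesioned_worse_gives_positive_t(self):
        cohort = _single_voxel_cohort([1, 1, 1, 0, 0, 0])
        y = pd.Series([-2.0, -1.0, -1.5, 1.0, 2.0, 1.5], index=cohort.patient_ids)
        tmap = voxelwise_t(cohort, y, _mask_for(cohort, 3))
        assert tmap.t[0, 0, 0] > 0

    def test_every_voxel_matches_scipy_oracle(self, tiny_bundle):
        _, cohort, cov, sub, _ = tiny_bundle
        resid = lesym.residualize(lesym.composite_scores(sub), cov)["executive"]
        mask = _mask_for(cohort, 5)
        tmap = voxelwise_t(cohort, resid, mask, alternative="greater")
        y = resid.reindex(list(cohort.patient_ids)).values
        les = cohort.lesion_matrix("wml")
        for flat_idx in np.flatnonzero(mask.mask.ravel()):
            idx = np.unravel_index(flat_idx, cohort.grid.shape)
            sel = les[:, flat_idx]
            ref = stats.ttest_ind(y[~sel], y[sel], equal_var=True, alternative="greater")
            assert tmap.t[idx] == pytest.approx(ref.statistic, abs=1e-10)
            assert tmap.p[idx] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_welch_variant_matches_scipy(self):
        cohort = _single_voxel_cohort([1, 1, 1, 0, 0, 0, 0])
        y = pd.Series([0.0, -3.0, -1.0, 1.0, 2.0, 0.5, 1.5], index=cohort.patient_ids)
        tmap = voxelwise_t(cohort, y, _mask_for(cohort, 3), welch=True)
        sel = np.array([1, 1, 1, 0, 0, 0, 0], dtype=bool)
        ref = stats.ttest_ind(y.values[~sel], y.values[sel], equal_var=False,
                              alternative="greater")
        assert tmap.t[0, 0, 0] == pytest.approx(ref.statistic, abs=1e-10)
        assert tmap.p[0, 0, 0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_joint_patient_permutation_leaves_tmap_unchanged(self, tiny_bundle):
        _, cohort, cov, sub, _ = tiny_bundle
        resid = lesym.residualize(lesym.composite_scores(sub), cov)["executive"]
        mask = _mask_for(cohort, 5)
        tmap = voxelwise_t(cohort, resid, mask)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cohort.n_patients)
        cohort_p = lesym.LesionCohort(
            grid=cohort.grid,
            patient_ids=tuple(cohort.patient_ids[i] for i in perm),
            maps={c: cohort.maps[c][perm] for c in ("wml", "ll")},
        )
        tmap_p = voxelwise_t(cohort_p, resid, mask)
        np.testing.assert_allclose(tmap.t, tmap_p.t, atol=1e-12, equal_nan=True)

    def test_zero_variance_voxel_dropped_with_warning(self):
        cohort = _single_voxel_cohort([1, 1, 0, 0])
        y = pd.Series([1.0, 1.0, 1.0, 1.0], index=cohort.patient_ids)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            tmap = voxelwise_t(cohort, y, _mask_for(cohort, 2))
        assert not tmap.valid[0, 0, 0]
        assert tmap.n_dropped_zero_variance == 1

    def test_missing_residual_rejected(self):
        cohort = _single_voxel_cohort([1, 1, 0, 0])
        y = pd.Series([1.0, 2.0, 3.0], index=cohort.patient_ids[:3])
        with pytest.raises(ValueError, match="missing"):
            voxelwise_t(cohort, y, _mask_for(cohort, 2))


class TestBHFDR:
    def test_textbook_example_two_rejections(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.27, 0.60]
        res = bh_fdr(_tmap_from_p(p), q=0.05)
        assert res.n_significant == 2
        assert res.p_cutoff == pytest.approx(0.008)

    def test_uniformly_small_p_all_rejected(self):
        res = bh_fdr(_tmap_from_p(np.full(100, 0.001)), q=0.05)
        assert res.n_significant == 100

    def test_no_rejection_branch(self):
        p = np.linspace(0.5, 0.9, 20)
        res = bh_fdr(_tmap_from_p(p), q=0.05)
        assert res.n_significant == 0
        assert res.p_cutoff is None and res.t_cutoff is None
        assert not res.sig_mask.any()

    def test_t_cutoff_is_minimum_significant_t(self):
        rng = np.random.default_rng(0)
        p = rng.beta(0.3, 3.0, size=500)
        tmap = _tmap_from_p(p)
        res = bh_fdr(tmap, q=0.05)
        if res.n_significant:
            assert res.t_cutoff == pytest.approx(np.min(tmap.t[res.sig_mask]))
            # significance is exactly a t-threshold rule (one-sided map)
            np.testing.assert_array_equal(
                res.sig_mask, tmap.valid & (tmap.t >= res.t_cutoff)
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 2000))
        p = rng.beta(0.5, rng.uniform(0.5, 5.0), size=m)
        res = bh_fdr(_tmap_from_p(p), q=0.05)
        expect = bh_oracle(p, 0.05)
        got = res.sig_mask.ravel()
        np.testing.assert_array_equal(got, expect)
        sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(got, sm_reject)

    def test_empty_map_rejected(self):
        tmap = _tmap_from_p([0.5])
        tmap.valid[:] = False
        with pytest.raises(ValueError, match="empty"):
            bh_fdr(tmap, q=0.05)


class TestClusters:
    def test_single_isolated_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        res = label_clusters(mask)
        assert res.sizes == {1: 1}

    def test_corner_touching_voxels_by_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True  # share only a corner
        assert label_clusters(mask, 26).n_clusters == 1
        assert label_clusters(mask, 18).n_clusters == 2
        assert label_clusters(mask, 6).n_clusters == 2

    def test_edge_touching_voxels_by_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[1, 2, 2] = True  # share an edge
        assert label_clusters(mask, 26).n_clusters == 1
        assert label_clusters(mask, 18).n_clusters == 1
        assert label_clusters(mask, 6).n_clusters == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(10):
            mask = rng.random((16, 16, 16)) < 0.08
            res = label_clusters(mask, connectivity)
            mine = {
                frozenset(map(tuple, np.argwhere(res.labels == lab)))
                for lab in res.sizes
            }
            oracle = set(flood_fill_labels(mask, connectivity))
            assert mine == oracle

    def test_sizes_partition_the_mask(self):
        rng = np.random.default_rng(9)
        mask = rng.random((12, 12, 12)) < 0.1
        res = label_clusters(mask)
        assert sum(res.sizes.values()) == int(mask.sum())

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_clusters(np.zeros((3, 3, 3), bool), connectivity=8)
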