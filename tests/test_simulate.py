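"""Synthetic cohort generator: determinism, rates, geometry, ground truth."""
import numpy as np
import pytest

import lesym
from lesym.simulate import (
    EffectParams,
    LesionEffect,
    LLParams,
    SimulationConfig,
    TractSpec,
    WMLFieldParams,
    default_config,
    ground_truth,
    make_synthetic_atlas,
    replicate_config,
    simulate_cognition,
    simulate_cohort,
    simulate_lesions,
)


class TestAtlas:
    def test_cuboid_core_has_peak_probability_and_far_field_zero(self):
        spec = TractSpec("roi", (8.0, 8.0, 4.0), (2, 2, 1), peak=1.0, decay_vox=0.8)
        cfg = default_config(n_patients=2, grid_shape=(16, 16, 8), tract_specs=(spec,),
                             effects=EffectParams(lesion_effects=()),
                             ll=LLParams(tract_weights={}, background_weight=1.0))
        atlas = make_synthetic_atlas(cfg)
        vol = atlas.probabilities["roi"]
        core = vol[spec.core_slices((16, 16, 8))]
        assert np.all(core == 1.0)
        assert vol[0, 0, 0] < 1e-6  # far corner decays to ~0

    def test_two_default_tracts_thresholded_masks_are_disjoint(self):
        cfg = replicate_config(seed=0, n_patients=2)
        atlas = make_synthetic_atlas(cfg)
        masks = lesym.binarize_atlas(atlas, 0.1)
        assert not np.any(masks["tract_a"] & masks["tract_b"])

    def test_atlas_is_deterministic(self):
        cfg = replicate_config(seed=3, n_patients=2)
        a1 = make_synthetic_atlas(cfg)
        a2 = make_synthetic_atlas(cfg)
        for name in a1.names:
            np.testing.assert_array_equal(a1.probabilities[name], a2.probabilities[name])

    def test_tract_outside_grid_rejected_naming_tract(self):
        spec = TractSpec("way_out", (15.0, 8.0, 4.0), (4, 2, 1))
        with pytest.raises(ValueError, match="way_out"):
            default_config(n_patients=2, grid_shape=(16, 16, 8), tract_specs=(spec,),
                           effects=EffectParams(lesion_effects=()),
                           ll=LLParams(tract_weights={}))


class TestLesions:
    def test_zero_rates_give_all_zero_maps(self):
        cfg = replicate_config(seed=1, n_patients=5, grid_shape=(12, 12, 8),
                               wml=WMLFieldParams(base_prob=0.0),
                               ll=LLParams(rate=0.0, tract_weights={}))
        cohort = simulate_lesions(cfg)
        assert cohort.maps["wml"].sum() == 0
        assert cohort.maps["ll"].sum() == 0

    def test_same_seed_identical_different_seed_differs(self):
        cfg1 = replicate_config(seed=5, n_patients=8, grid_shape=(12, 12, 8))
        cfg2 = replicate_config(seed=5, n_patients=8, grid_shape=(12, 12, 8))
        cfg3 = replicate_config(seed=6, n_patients=8, grid_shape=(12, 12, 8))
        c1, c2, c3 = map(simulate_lesions, (cfg1, cfg2, cfg3))
        np.testing.assert_array_equal(c1.maps["wml"], c2.maps["wml"])
        np.testing.assert_array_equal(c1.maps["ll"], c2.maps["ll"])
        assert not np.array_equal(c1.maps["wml"], c3.maps["wml"])

    def test_homogeneous_rate_recovered_within_binomial_error(self):
        # Homogeneous p=0.02, n=500: per-voxel empirical frequency within
        # 3 binomial SDs at >= 99% of voxels (the smooth field preserves
        # the marginal rate exactly; only sampling noise remains).
        p, n = 0.02, 500
        cfg = replicate_config(
            seed=42, n_patients=n, grid_shape=(16, 16, 8),
            wml=WMLFieldParams(base_prob=p, smoothness_vox=1.5, burden_sigma=0.0,
                               prevalence_profile="uniform"),
            ll=LLParams(rate=0.0, tract_weights={}),
        )
        cohort = simulate_lesions(cfg)
        freq = cohort.maps["wml"].mean(axis=0)
        sd = np.sqrt(p * (1 - p) / n)
        within = np.abs(freq - p) <= 3 * sd
        assert within.mean() >= 0.99

    def test_lacunes_are_small_spheres_of_expected_size(self):
        cfg = replicate_config(seed=9, n_patients=40, grid_shape=(16, 16, 8),
                               wml=WMLFieldParams(base_prob=0.0),
                               ll=LLParams(rate=1.0, extra_mean=0.0, radius_vox=2.0,
                                           tract_weights={}, background_weight=1.0))
        cohort = simulate_lesions(cfg)
        ball = ((np.arange(-2, 3)[:, None, None] ** 2
                 + np.arange(-2, 3)[None, :, None] ** 2
                 + np.arange(-2, 3)[None, None, :] ** 2) <= 4).sum()
        per_patient = cohort.maps["ll"].reshape(40, -1).sum(axis=1)
        assert np.all(per_patient >= 1)
        assert np.all(per_patient <= ball)  # one sphere, possibly clipped

    def test_ll_radius_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            replicate_config(seed=0, n_patients=2, grid_shape=(6, 6, 4),
                             ll=LLParams(radius_vox=3.0, tract_weights={}))

    def test_burden_wml_correlation_couples_ll_presence_to_burden(self):
        base = dict(n_patients=400, grid_shape=(12, 12, 8))
        cfg = replicate_config(seed=21, **base,
                               ll=LLParams(rate=0.3, wml_correlation=0.9,
                                           tract_weights={}, background_weight=1.0))
        cohort = simulate_lesions(cfg)
        totals = cohort.total_volumes()
        has_ll = totals["ll_present"].astype(bool)
        assert totals.loc[has_ll, "wml_total_ml"].mean() > totals.loc[~has_ll, "wml_total_ml"].mean()


class TestCognition:
    def test_noiseless_single_subtest_recovers_latent_exactly(self):
        spec = lesym.simulate.SubtestSpec("probe", "executive", higher_better=False,
                                          loading=1.0, noise_sd=0.0, mean=10.0, sd=2.0)
        cfg = replicate_config(seed=13, n_patients=25, grid_shape=(12, 12, 8),
                               subtests=(spec,))
        atlas, cohort, cov, sub, _ = simulate_cohort(cfg)
        # lower-better with loading 1: raw = mean - sd * latent
        latent = (10.0 - sub["probe"]) / 2.0
        comp = lesym.composite_scores(sub, scheme=cfg.subtest_scheme())
        z = (latent - latent.mean()) / latent.std(ddof=1)
        np.testing.assert_allclose(comp["executive"], z, atol=1e-10)

    def test_mismatched_cohort_size_rejected(self, tiny_config, tiny_bundle):
        atlas, cohort, *_ = tiny_bundle
        bad = replicate_config(seed=7, n_patients=tiny_config.n_patients + 1,
                               grid_shape=tiny_config.grid_shape)
        with pytest.raises(ValueError, match="cohort size"):
            simulate_cognition(bad, cohort, atlas)

    def test_cognition_deterministic_given_config(self, tiny_config, tiny_bundle):
        atlas, cohort, cov1, sub1, _ = tiny_bundle
        cov2, sub2 = simulate_cognition(tiny_config, cohort, atlas)
        np.testing.assert_array_equal(cov1.values, cov2.values)
        np.testing.assert_array_equal(sub1.values, sub2.values)


class TestGroundTruth:
    def test_planted_coefficients_echoed_exactly(self):
        eff = EffectParams(lesion_effects=(LesionEffect("executive", "tract_a", "ll", -3.0),))
        cfg = replicate_config(seed=0, n_patients=2, effects=eff)
        truth = ground_truth(cfg)
        assert truth.effect("executive", "tract_a", "ll") == -3.0
        assert truth.effect("executive", "tract_b", "ll") == 0.0
        assert truth.noise_sd == eff.noise_sd

    def test_no_tracts_gives_empty_effects(self):
        cfg = SimulationConfig(n_patients=2, grid_shape=(8, 8, 8), tract_specs=(),
                               effects=EffectParams(lesion_effects=()),
                               ll=LLParams(tract_weights={}))
        assert ground_truth(cfg).lesion_effects == ()

    def test_ground_truth_survives_config_serialisation(self, tmp_path, tiny_config):
        path = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(path)
        restored = SimulationConfig.from_yaml(path)
        assert restored == tiny_config
        assert ground_truth(restored) == ground_truth(tiny_config)
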