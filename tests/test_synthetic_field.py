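"""Synthetic trial generator: design, trait formulas, rendering, point clouds."""

import numpy as np
import pandas as pd
import pytest

from maizefuse import reference
from maizefuse import synthetic_field as sf


class TestDesign:
    def test_counts_and_alternating_treatment(self):
        plots = sf.generate_design(2, 3, seed=7)
        assert len(plots) == 6
        treatments = [p.treatment for p in plots]
        assert treatments.count(sf.LOW_N) == 3
        assert treatments.count(sf.HIGH_N) == 3
        by_block = {p.block_id: p.treatment for p in plots}
        assert by_block["B00"] == sf.LOW_N and by_block["B01"] == sf.HIGH_N

    def test_single_plot_has_valid_polygon(self):
        (plot,) = sf.generate_design(1, 1, seed=0)
        assert plot.polygon.area > 0
        assert plot.polygon.bounds[2] - plot.polygon.bounds[0] == pytest.approx(
            reference.PLOT_WIDTH_M
        )

    def test_polygons_pairwise_disjoint(self):
        plots = sf.generate_design(3, 4, seed=3)
        for i, a in enumerate(plots):
            for b in plots[i + 1 :]:
                assert a.polygon.intersection(b.polygon).area == 0.0

    def test_deterministic_per_seed(self):
        a = sf.generate_design(3, 5, seed=42)
        b = sf.generate_design(3, 5, seed=42)
        assert [(p.plot_id, p.genotype_id, p.polygon.bounds) for p in a] == [
            (p.plot_id, p.genotype_id, p.polygon.bounds) for p in b
        ]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_design(0, 3, seed=0)
        with pytest.raises(ValueError):
            sf.generate_design(2, -1, seed=0)


class TestDerivePhenotypes:
    def test_equal_biomass_gives_third_harvest_index(self):
        rec = sf.derive_phenotypes(100, 100, 100, 1.0, 8.0, 5, 0.0004)
        assert rec.harvest_index == pytest.approx(1 / 3)

    def test_jones_factor_protein_to_nitrogen(self):
        # protein of 6.25% means exactly 1% of grain biomass is nitrogen
        rec = sf.derive_phenotypes(0.0, 0.0, 100.0, 0.0, 6.25, 1, 0.0001)
        grain_n_fraction = rec.grain_n / rec.dry_grain_yield
        assert grain_n_fraction == pytest.approx(0.01)

    def test_hand_worked_example(self):
        # stalk 500 g, cob 100 g, grain 400 g, stalk N 1%, protein 9.375%,
        # 5 plants, 0.0004 ha -- all values derived by hand from the formulas
        rec = sf.derive_phenotypes(500, 100, 400, 1.0, 9.375, 5, 0.0004)
        assert rec.dry_grain_yield == pytest.approx(5000.0)
        assert rec.dry_stalk_biomass == pytest.approx(6250.0)
        assert rec.cob_biomass == pytest.approx(1250.0)
        assert rec.harvest_index == pytest.approx(0.4)
        assert rec.grain_n == pytest.approx(75.0)       # (9.375/625)*400*5/0.0004/1000
        assert rec.total_plant_n == pytest.approx(137.5)  # + 1%*500 scaled
        assert rec.grain_nute == pytest.approx(400.0 / 11.0)

    def test_error_on_zero_area_and_zero_biomass(self):
        with pytest.raises(ValueError):
            sf.derive_phenotypes(1, 1, 1, 1, 8, 5, 0.0)
        with pytest.raises(ValueError):
            sf.derive_phenotypes(0, 0, 0, 1, 8, 5, 0.0004)

    def test_invariants_on_random_positive_inputs(self, rng):
        for _ in range(200):
            stalk, cob, grain = rng.uniform(10, 500, 3)
            rec = sf.derive_phenotypes(
                stalk, cob, grain, rng.uniform(0.1, 2), rng.uniform(4, 14),
                int(rng.integers(1, 40)), 0.0004,
            )
            assert 0 < rec.harvest_index < 1
            assert rec.grain_n <= rec.total_plant_n
            assert min(rec.dry_stalk_biomass, rec.cob_biomass, rec.dry_grain_yield) >= 0


class TestTraitPopulation:
    def test_zero_effect_removes_bimodality(self):
        design = sf.generate_design(10, 30, seed=1)
        spec = sf.EffectSpec(effect_scale=0.0)
        traits = sf.sample_trait_population(design, spec, seed=1)
        by_t = traits.groupby("treatment")["dry_grain_yield"].mean()
        pooled_sd = traits["dry_grain_yield"].std()
        assert abs(by_t[sf.HIGH_N] - by_t[sf.LOW_N]) < 0.5 * pooled_sd

    def test_treatment_effect_separates_means(self):
        design = sf.generate_design(10, 30, seed=1)
        traits = sf.sample_trait_population(design, seed=1)
        for trait in ("dry_grain_yield", "grain_n", "total_plant_n"):
            g = traits.groupby("treatment")[trait]
            gap = g.mean()[sf.HIGH_N] - g.mean()[sf.LOW_N]
            within = g.std().mean()
            assert gap > 2 * within, trait  # clearly bimodal pooled distribution

    def test_biomass_traits_positively_correlated(self):
        design = sf.generate_design(10, 30, seed=2)
        traits = sf.sample_trait_population(design, seed=2)
        corr = traits[["dry_stalk_biomass", "cob_biomass", "dry_grain_yield"]].corr()
        assert (corr.to_numpy() > 0.3).all()

    def test_grain_density_narrow_and_left_skewed(self):
        design = sf.generate_design(13, 29, seed=3)  # ~ full trial size
        traits = sf.sample_trait_population(design, seed=3)
        gd = traits["grain_density"]
        cv = 100 * gd.std() / gd.mean()
        assert 1.0 < cv < 6.0            # cv on the order of 3%
        assert gd.skew() < -0.5          # left-skewed
        cv_yield = 100 * traits.dry_grain_yield.std() / traits.dry_grain_yield.mean()
        cv_hi = 100 * traits.harvest_index.std() / traits.harvest_index.mean()
        assert cv_yield > cv_hi

    def test_deterministic_per_seed(self):
        design = sf.generate_design(2, 5, seed=4)
        a = sf.sample_trait_population(design, seed=9)
        b = sf.sample_trait_population(design, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_correlation_matrix_rejected(self):
        design = sf.generate_design(1, 2, seed=0)
        bad = sf.EffectSpec()
        bad.corr = np.full((5, 5), 0.99)
        bad.corr[0, 1] = -0.99  # asymmetric
        with pytest.raises(ValueError):
            sf.sample_trait_population(design, bad, seed=0)


class TestRenderScene:
    def test_noiseless_plot_mean_nir_equals_planted_function(self, noiseless_scene):
        design, phenotypes, scene, spec = noiseless_scene
        nir_band = int(np.argmin(np.abs(scene.wavelengths - 900)))
        for plot in design:
            rs, cs = scene.plot_pixel_window(plot)
            mask = scene.truth_mask[rs, cs]
            mean_nir = scene.hyperspectral[rs, cs, nir_band][mask].mean()
            planted = np.clip(
                spec.nir_base
                + spec.nir_gain * phenotypes.loc[plot.plot_id, spec.signal_trait],
                0.05, 0.95,
            )
            assert mean_nir == pytest.approx(planted, abs=1e-6)

    def test_zero_shadow_and_soil_mask_covers_interior(self):
        design = sf.generate_design(1, 2, 5, plot_length=0.96, plot_width=0.30)
        phenotypes = sf.sample_trait_population(design, seed=5)
        spec = sf.RenderSpec(n_bands=8, soil_fraction=0.0, shadow_fraction=0.0,
                             border_px=0)
        scene = sf.render_scene(design, phenotypes, spec, seed=5)
        for plot in design:
            rs, cs = scene.plot_pixel_window(plot)
            assert scene.truth_mask[rs, cs].all()

    def test_rendered_scene_validates_and_is_deterministic(self, small_scene):
        design, phenotypes, scene = small_scene
        scene.validate()
        again = sf.render_scene(
            design, phenotypes, sf.RenderSpec(n_bands=12, noise_sd=0.01), seed=11
        )
        np.testing.assert_array_equal(scene.hyperspectral, again.hyperspectral)
        np.testing.assert_array_equal(scene.height, again.height)

    def test_canopy_height_tracks_stalk_biomass(self, small_scene):
        design, phenotypes, scene = small_scene
        means, stalks = [], []
        for plot in design:
            rs, cs = scene.plot_pixel_window(plot)
            mask = scene.truth_mask[rs, cs]
            means.append(scene.height[rs, cs][mask].mean())
            stalks.append(phenotypes.loc[plot.plot_id, "dry_stalk_biomass"])
        assert np.corrcoef(means, stalks)[0, 1] > 0.99


class TestPointCloud:
    def test_density_within_ten_percent(self, small_scene):
        _, _, scene = small_scene
        pc = sf.generate_pointcloud(scene, density=1600, seed=8)
        area = (
            scene.height.shape[0] * scene.gsd * scene.height.shape[1] * scene.gsd
        )
        realized = len(pc) / area
        assert abs(realized - 1600) < 160

    def test_flat_bare_ground_all_ground_constant_z(self):
        design = sf.generate_design(1, 2, 5, plot_length=0.96, plot_width=0.30)
        phenotypes = sf.sample_trait_population(design, seed=5)
        spec = sf.RenderSpec(n_bands=8, soil_fraction=1.0, shadow_fraction=0.0,
                             border_px=0)
        scene = sf.render_scene(design, phenotypes, spec, seed=5)
        scene.height[:] = 0.0
        scene.truth_mask[:] = False
        pc = sf.generate_pointcloud(scene, density=800, seed=8, z_noise_sd=0.0)
        assert pc["ground"].all()
        assert np.allclose(pc["z"], 0.0)

    def test_canopy_z_matches_planted_height(self, small_scene):
        _, _, scene = small_scene
        pc = sf.generate_pointcloud(scene, density=1600, seed=9, z_noise_sd=0.0)
        canopy = pc.loc[~pc["ground"]]
        planted_max = scene.height.max()
        assert np.percentile(canopy["z"], 90) == pytest.approx(planted_max, abs=0.3)
        # canopy returns are brighter than ground returns, as planted
        assert canopy["intensity"].mean() > pc.loc[pc["ground"], "intensity"].mean()
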