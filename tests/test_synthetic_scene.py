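import math

import numpy as np
import pytest

from plaquelapse import dendrite_morph as dm
from plaquelapse import synthetic_scene as sc


class TestSceneConfig:
    def test_default_count_matches_density_times_volume(self):
        # 515 mm^-3 over a 0.508 x 0.508 x 0.300 mm^3 field -> 39.9 -> 40
        assert sc.expected_plaque_count(sc.SceneConfig()) == 40

    @pytest.mark.parametrize(
        "overrides",
        [
            {"pixels_per_axis": 32},
            {"z_depth_um": -1.0},
            {"core_intensity": 0.0},
            {"min_plaque_radius_um": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            sc.SceneConfig(**overrides)


def _small_cfg(**overrides):
    base = dict(
        field_size_um=(127.0, 127.0),
        pixels_per_axis=128,
        z_depth_um=60.0,
        plaque_density_per_mm3=2000.0,  # ~2 plaques in this small field
        plaque_radius_median_um=8.0,
        plaque_radius_sigma=0.1,
        rng_seed=5,
    )
    base.update(overrides)
    return sc.SceneConfig(**base)


class TestMakeScene:
    def test_empty_scene_is_pure_background_noise(self):
        cfg = _small_cfg(plaque_density_per_mm3=0.0)
        stacks, gt = sc.make_scene(cfg, n_sessions=1)
        assert gt.n_plaques == 0
        assert stacks[0].voxels.max() < cfg.background_level + 10

    def test_count_and_truth_bookkeeping(self):
        cfg = _small_cfg()
        stacks, gt = sc.make_scene(cfg, n_sessions=3, growth_factors=(1.1, 1.0))
        assert gt.n_plaques == sc.expected_plaque_count(cfg)
        assert gt.radii_by_session_um.shape == (3, gt.n_plaques)
        np.testing.assert_allclose(
            gt.radii_by_session_um[1], gt.radii_by_session_um[0] * 1.1
        )
        np.testing.assert_allclose(
            gt.radii_by_session_um[2], gt.radii_by_session_um[1]
        )
        assert gt.session_days == [13, 20, 27]

    def test_fixed_seed_bit_identical_different_seed_not(self):
        cfg = _small_cfg()
        a1, gta = sc.make_scene(cfg, 2)
        a2, _ = sc.make_scene(cfg, 2)
        b, gtb = sc.make_scene(_small_cfg(rng_seed=6), 2)
        for s1, s2 in zip(a1, a2):
            np.testing.assert_array_equal(s1.voxels, s2.voxels)
        assert not np.array_equal(gta.centers_um, gtb.centers_um)

    def test_identity_growth_noise_free_sessions_identical(self):
        cfg = _small_cfg(
            noise_gaussian_sd=0.0, noise_signal_scale=0.0, quantize=False
        )
        _, gt = sc.make_scene(cfg, 2, growth_factors=(1.0,))
        s1 = sc.render_noise_free(gt, 0, cfg)
        s2 = sc.render_noise_free(gt, 1, cfg)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_placement_respects_margins_and_overlap(self):
        cfg = _small_cfg(plaque_density_per_mm3=6000.0, rng_seed=2)
        _, gt = sc.make_scene(cfg, 1)
        r = gt.radii_by_session_um[0]
        for i, (y, x, z) in enumerate(gt.centers_um):
            m = 2 * r[i]
            assert m <= y <= cfg.field_size_um[0] - m
            assert m <= x <= cfg.field_size_um[1] - m
            assert r[i] <= z <= cfg.z_depth_um - r[i]
        for i in range(gt.n_plaques):
            for j in range(i + 1, gt.n_plaques):
                d = np.linalg.norm(gt.centers_um[i] - gt.centers_um[j])
                assert d >= r[i] + r[j] - cfg.overlap_tolerance_um - 1e-9

    def test_growth_factor_count_is_validated(self):
        with pytest.raises(ValueError, match="growth factors"):
            sc.make_scene(_small_cfg(), 3, growth_factors=(1.1,))

    def test_too_small_field_fails_explicitly(self):
        cfg = _small_cfg(
            field_size_um=(63.5, 63.5),
            pixels_per_axis=64,
            plaque_radius_median_um=20.0,
            plaque_density_per_mm3=5000.0,
        )
        with pytest.raises((ValueError, RuntimeError), match="too small|overlap"):
            sc.make_scene(cfg, 1)


class TestRenderNoiseFree:
    def test_uniform_background_without_plaques(self, quiet_scene_config):
        cfg = quiet_scene_config(background_level=7.0)
        _, gt = sc.make_scene(cfg, 1)
        stack = sc.render_noise_free(gt, 0, cfg)
        np.testing.assert_array_equal(stack.voxels, 7.0)

    def test_central_slice_area_matches_pi_r_squared(self, single_sphere):
        cfg, gt, stack = single_sphere
        sl = stack.voxels[40]
        above = int((sl > cfg.core_intensity / 2).sum())
        expected = math.pi * 10.0**2 / stack.pixel_size_um**2
        perimeter = 2 * math.pi * 10.0 / stack.pixel_size_um
        assert abs(above - expected) <= 2 * perimeter

    def test_growth_scales_central_slice_area_by_g_squared(self, quiet_scene_config):
        cfg = quiet_scene_config()
        g = 1.062
        gt = sc.SceneGroundTruth(
            centers_um=np.array([[63.5, 63.5, 40.0]]),
            radii_by_session_um=[[10.0], [10.0 * g]],
            halo_amplitude=0.0,
            halo_decay_by_session_um=[[2.0], [2.0 * g]],
            session_days=[13, 20],
            jitter_px=np.zeros((2, 2), dtype=int),
            rng_seed=1,
        )
        areas = []
        for session in (0, 1):
            sl = sc.render_noise_free(gt, session, cfg).voxels[40]
            areas.append(int((sl > cfg.core_intensity / 2).sum()))
        ratio = areas[1] / areas[0]
        assert g**2 * 0.95 <= ratio <= g**2 * 1.05

    def test_center_slice_attains_roi_maximum(self, single_sphere):
        _, _, stack = single_sphere
        roi = stack.voxels[:, 54:74, 54:74].mean(axis=(1, 2))
        assert int(np.argmax(roi)) == 40


class TestDendriteScene:
    def test_uniform_cylinder_fwhm_everywhere(self):
        cfg = sc.DendriteSceneConfig(
            vertices_um=[[10.0, 5.0], [10.0, 205.0]],
            diameter_breakpoints=((0.0, 0.9),),
        )
        trace, img = sc.make_dendrite_scene(cfg, 0.2)
        for s in (20.0, 100.0, 180.0):
            d, _ = dm.shaft_diameter(img, trace, [s], 0.2)
            assert d[0] == pytest.approx(0.9, abs=0.2)

    def test_spine_annotation_counts_preserved(self):
        prox = tuple(np.linspace(1.0, 99.0, 36))
        dist = tuple(np.linspace(101.0, 199.0, 29))
        cfg = sc.DendriteSceneConfig(
            vertices_um=[[10.0, 5.0], [10.0, 205.0]],
            spine_arclengths_um=prox + dist,
        )
        trace, _ = sc.make_dendrite_scene(cfg, 0.2)
        spines = np.array(trace.spine_arclengths_um)
        assert ((spines >= 0) & (spines < 100)).sum() == 36
        assert ((spines >= 100) & (spines <= 200)).sum() == 29

    def test_diameter_step_recovered_from_render(self):
        cfg = sc.DendriteSceneConfig(
            vertices_um=[[10.0, 5.0], [10.0, 205.0]],
            diameter_breakpoints=((0.0, 0.9), (110.0, 0.8)),
            plaque_interval_um=(90.0, 110.0),
        )
        trace, img = sc.make_dendrite_scene(cfg, 0.2)
        _, before = dm.shaft_diameter(img, trace, np.arange(20.0, 80.0, 1.0), 0.2)
        _, after = dm.shaft_diameter(img, trace, np.arange(120.0, 180.0, 1.0), 0.2)
        assert before == pytest.approx(0.9, abs=0.05)
        assert after == pytest.approx(0.8, abs=0.05)

    def test_unmeasurably_thin_shaft_rejected(self):
        cfg = sc.DendriteSceneConfig(
            vertices_um=[[10.0, 5.0], [10.0, 105.0]],
            diameter_breakpoints=((0.0, 0.3),),
        )
        with pytest.raises(ValueError, match="measured"):
            sc.make_dendrite_scene(cfg, 0.2)


class TestArtifacts:
    def test_scene_written_as_uint16_tiffs_with_manifest(self, tmp_path):
        cfg = _small_cfg()
        stacks, gt = sc.make_scene(cfg, 2)
        paths = sc.write_scene(stacks, gt, tmp_path)
        assert len(paths) == 2
        assert (tmp_path / "ground_truth.json").exists()
        from plaquelapse import stack_io

        back = stack_io.read_stack(paths[0], pixel_size_um=cfg.pixel_size_um)
        assert back.voxels.shape == stacks[0].voxels.shape

    def test_dendrite_annotation_csv(self, tmp_path):
        cfg = sc.DendriteSceneConfig(
            vertices_um=[[10.0, 5.0], [10.0, 105.0]],
            spine_arclengths_um=(5.0, 50.0),
        )
        out = tmp_path / "ann.csv"
        sc.write_dendrite_annotations(cfg, out)
        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) == {"arclength_um", "is_spine", "diameter_um"}
        assert int(df.is_spine.sum()) == 2
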