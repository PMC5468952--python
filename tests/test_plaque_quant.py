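import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from plaquelapse import plaque_quant as pq
from plaquelapse import synthetic_scene as sc
from plaquelapse.stack_io import ImageStack


# ---------------------------------------------------------------------------
# independent oracle: flood fill over strictly-above-threshold pixels,
# followed by hole filling via a border flood of the complement
# ---------------------------------------------------------------------------

def flood_fill_oracle(frame, threshold, seed, reach=3.0):
    binary = frame > threshold
    h, w = frame.shape
    sy, sx = seed
    if not binary[sy, sx]:
        best = None
        for y in range(h):
            for x in range(w):
                if binary[y, x]:
                    d = math.hypot(y - sy, x - sx)
                    if d <= reach and (best is None or d < best[0]):
                        best = (d, y, x)
        if best is None:
            return np.zeros_like(binary)
        sy, sx = best[1], best[2]
    mask = np.zeros_like(binary)
    q = deque([(sy, sx)])
    mask[sy, sx] = True
    while q:
        y, x = q.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not mask[ny, nx]:
                    mask[ny, nx] = True
                    q.append((ny, nx))
    # fill holes: anything not reachable from the border through the complement
    outside = np.zeros_like(binary)
    q = deque()
    for y in range(h):
        for x in (0, w - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                q.append((y, x))
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                q.append((ny, nx))
    return ~outside


class TestBackground:
    @pytest.mark.parametrize(
        "frame, mu, sigma",
        [
            (np.full((10, 10), 5.0), 5.0, 0.0),
            (np.concatenate([np.zeros(10), np.full(90, 100.0)]).reshape(10, 10), 0.0, 0.0),
            (
                np.concatenate([np.arange(10.0), np.full(90, 100.0)]).reshape(10, 10),
                4.5,
                math.sqrt(8.25),
            ),
        ],
    )
    def test_lowest_decile_statistics(self, frame, mu, sigma):
        bg = pq.estimate_background(frame)
        assert bg.mu_bg == pytest.approx(mu)
        assert bg.sigma_bg == pytest.approx(sigma)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            pq.estimate_background(np.zeros((3, 3)))

    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=12),
            elements=st.floats(0, 1000),
        )
    )
    def test_background_mean_never_exceeds_frame_mean(self, frame):
        if frame.size < 10:
            return
        assert pq.estimate_background(frame).mu_bg <= frame.mean() + 1e-9


class TestThreshold:
    @pytest.mark.parametrize(
        "mu, sigma, expected",
        [(0.0, 2.0, 6.0), (4.5, math.sqrt(8.25), 4.5 + 3 * math.sqrt(8.25)), (7.0, 0.0, 7.0)],
    )
    def test_mu_plus_three_sigma(self, mu, sigma, expected):
        assert pq.border_threshold(pq.BackgroundStats(mu, sigma)) == pytest.approx(expected)


class TestSegmentation:
    def test_disk_mask_matches_flood_fill_oracle(self):
        yy, xx = np.ogrid[:40, :40]
        frame = np.where((yy - 20) ** 2 + (xx - 20) ** 2 <= 100, 100.0, 0.0)
        mask = pq.segment_plaque(frame, 6.0, (20, 20))
        np.testing.assert_array_equal(mask, flood_fill_oracle(frame, 6.0, (20, 20)))

    def test_threshold_at_frame_value_gives_empty_mask(self):
        frame = np.full((20, 20), 7.0)
        assert not pq.segment_plaque(frame, 7.0, (10, 10)).any()

    def test_seed_selects_only_its_component(self):
        yy, xx = np.ogrid[:40, :40]
        a = (yy - 10) ** 2 + (xx - 10) ** 2 <= 25
        b = (yy - 30) ** 2 + (xx - 30) ** 2 <= 25
        frame = np.where(a | b, 50.0, 0.0)
        mask = pq.segment_plaque(frame, 6.0, (10, 10))
        assert mask[a].all() and not mask[b].any()

    def test_interior_holes_are_filled(self):
        yy, xx = np.ogrid[:40, :40]
        r2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (r2 <= 144) & (r2 >= 36)
        frame = np.where(ring, 50.0, 0.0)
        mask = pq.segment_plaque(frame, 6.0, (20, 8))
        assert mask[20, 20]  # the hole inside the ring belongs to the plaque

    def test_matches_oracle_on_random_textured_frames(self):
        rng = np.random.default_rng(99)
        for _ in range(12):
            frame = rng.random((48, 48)) * 10
            for _ in range(rng.integers(1, 4)):
                cy, cx = rng.integers(8, 40, 2)
                yy, xx = np.ogrid[:48, :48]
                frame += np.where(
                    (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.integers(9, 64), 60.0, 0.0
                )
            thr = float(rng.uniform(5, 30))
            seed = tuple(rng.integers(4, 44, 2))
            got = pq.segment_plaque(frame, thr, seed)
            np.testing.assert_array_equal(got, flood_fill_oracle(frame, thr, seed))

    def test_raising_threshold_never_enlarges_the_mask(self):
        rng = np.random.default_rng(7)
        frame = rng.random((48, 48)) * 20
        yy, xx = np.ogrid[:48, :48]
        frame += np.where((yy - 24) ** 2 + (xx - 24) ** 2 <= 80, 60.0, 0.0)
        areas = [
            pq.segment_plaque(frame, thr, (24, 24)).sum() for thr in (5, 10, 20, 40)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestCenterFrame:
    def test_tied_maxima_take_lowest_z(self):
        vox = np.zeros((4, 8, 8))
        vox[1] = 9.0
        vox[2] = 9.0
        vox[3] = 3.0
        vox[0] = 1.0
        assert pq.select_center_frame(vox, (0, 8, 0, 8)) == 1

    def test_noise_free_sphere_center(self, single_sphere):
        _, _, stack = single_sphere
        assert pq.select_center_frame(stack.voxels, (54, 74, 54, 74)) == 40

    def test_noisy_sphere_center_within_one_frame(self):
        cfg = sc.SceneConfig(
            field_size_um=(127.0, 127.0),
            pixels_per_axis=128,
            z_depth_um=300.0,
            plaque_density_per_mm3=0.0,
            rng_seed=3,
        )
        gt = sc.SceneGroundTruth(
            centers_um=np.array([[63.5, 63.5, 150.0]]),
            radii_by_session_um=[[10.0]],
            halo_amplitude=cfg.halo_amplitude,
            halo_decay_by_session_um=[[cfg.halo_decay_um]],
            session_days=[13],
            jitter_px=np.zeros((1, 2), dtype=int),
            rng_seed=3,
        )
        clean = sc.render_noise_free(gt, 0, cfg)
        rng = np.random.default_rng(3)
        noisy = ImageStack(
            np.clip(np.rint(clean.voxels + rng.normal(0, 0.3, clean.voxels.shape)), 0, None),
            pixel_size_um=cfg.pixel_size_um,
        )
        center = pq.select_center_frame(noisy.voxels, (54, 74, 54, 74))
        assert abs(center - 150) <= 1


class TestMeasurePlaque:
    def test_sphere_size_matches_analytic_slice_areas(self, single_sphere):
        _, _, stack = single_sphere
        obs = pq.measure_plaque(stack, (63.5, 63.5, 40.0))
        analytic = np.mean([math.pi * (100 - d * d) for d in (0, 1, -1, 2, -2)])
        assert obs.size_um2 == pytest.approx(analytic, rel=0.05)
        assert not obs.clipped
        assert obs.center_frame == 40

    def test_plaque_at_stack_start_is_clipped_with_four_frames(self, quiet_scene_config):
        cfg = quiet_scene_config(z_depth_um=30.0)
        gt = sc.SceneGroundTruth(
            centers_um=np.array([[63.5, 63.5, 1.0]]),
            radii_by_session_um=[[6.0]],
            halo_amplitude=0.0,
            halo_decay_by_session_um=[[2.0]],
            session_days=[13],
            jitter_px=np.zeros((1, 2), dtype=int),
            rng_seed=1,
        )
        stack = sc.render_noise_free(gt, 0, cfg)
        obs = pq.measure_plaque(stack, (63.5, 63.5, 1.0))
        assert obs.clipped
        assert len(obs.frame_masks) == 4  # frames -1..3 clipped to 0..3

    def test_measurement_is_deterministic(self, single_sphere):
        _, _, stack = single_sphere
        a = pq.measure_plaque(stack, (63.5, 63.5, 40.0))
        b = pq.measure_plaque(stack, (63.5, 63.5, 40.0))
        assert a.size_um2 == b.size_um2
        for ma, mb in zip(a.frame_masks, b.frame_masks):
            np.testing.assert_array_equal(ma, mb)

    def test_empty_center_frame_rejects_observation(self, quiet_scene_config):
        cfg = quiet_scene_config(background_level=5.0)
        _, gt = sc.make_scene(cfg, 1)
        stack = sc.render_noise_free(gt, 0, cfg)  # no plaques at density 0
        with pytest.raises(pq.EmptyMaskError):
            pq.measure_plaque(stack, (63.5, 63.5, 40.0))

    def test_growth_recovered_as_area_ratio(self, quiet_scene_config):
        cfg = quiet_scene_config()
        g = 1.1
        gt = sc.SceneGroundTruth(
            centers_um=np.array([[63.5, 63.5, 40.0]]),
            radii_by_session_um=[[8.0], [8.0 * g]],
            halo_amplitude=0.0,
            halo_decay_by_session_um=[[2.0], [2.0 * g]],
            session_days=[13, 20],
            jitter_px=np.zeros((2, 2), dtype=int),
            rng_seed=1,
        )
        sizes = [
            pq.measure_plaque(sc.render_noise_free(gt, s, cfg), (63.5, 63.5, 40.0)).size_um2
            for s in (0, 1)
        ]
        ratio = sizes[1] / sizes[0]
        assert g**2 - 0.05 <= ratio <= g**2 + 0.05


class TestDetection:
    def test_blank_stack_yields_no_seeds(self):
        cfg = sc.SceneConfig(
            field_size_um=(127.0, 127.0),
            pixels_per_axis=128,
            z_depth_um=60.0,
            plaque_density_per_mm3=0.0,
            rng_seed=11,
        )
        stacks, _ = sc.make_scene(cfg, 1)
        assert pq.detect_plaques(stacks[0]) == []

    def test_recall_and_no_spurious_on_default_density_scene(self):
        cfg = sc.SceneConfig(
            field_size_um=(381.0, 381.0),
            pixels_per_axis=384,
            z_depth_um=150.0,
            rng_seed=21,
        )
        stacks, gt = sc.make_scene(cfg, 1)
        seeds = pq.detect_plaques(stacks[0])
        centers = gt.centers_um
        dists = np.array(
            [np.linalg.norm(centers - np.asarray(s), axis=1).min() for s in seeds]
        )
        assert (dists < 5.0).all()  # no spurious seeds
        recalled = sum(
            1
            for c in centers
            if min(np.linalg.norm(np.asarray(s) - c) for s in seeds) < 5.0
        )
        assert recalled >= 0.9 * gt.n_plaques

    def test_close_pair_suppressed_to_one_seed(self, quiet_scene_config):
        cfg = quiet_scene_config(
            noise_gaussian_sd=0.2, quantize=True, background_level=3.0
        )
        gt = sc.SceneGroundTruth(
            centers_um=np.array([[60.0, 60.0, 30.0], [60.0, 66.0, 30.0]]),
            radii_by_session_um=[[5.0, 5.0]],
            halo_amplitude=0.0,
            halo_decay_by_session_um=[[2.0, 2.0]],
            session_days=[13],
            jitter_px=np.zeros((1, 2), dtype=int),
            rng_seed=1,
        )
        stack = sc.render_noise_free(gt, 0, cfg)
        seeds = pq.detect_plaques(stack, min_distance_um=10.0)
        assert len(seeds) == 1
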