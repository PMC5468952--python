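import numpy as np
import pytest
from hypothesis import settings

from plaquelapse import synthetic_scene as sc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def quiet_scene_config():
    """Small noise-free, halo-free configuration for geometry oracles."""
    def make(**overrides):
        base = dict(
            field_size_um=(127.0, 127.0),
            pixels_per_axis=128,
            z_depth_um=80.0,
            z_step_um=1.0,
            plaque_density_per_mm3=0.0,
            halo_amplitude=0.0,
            noise_gaussian_sd=0.0,
            noise_signal_scale=0.0,
            quantize=False,
            rng_seed=1,
        )
        base.update(overrides)
        return sc.SceneConfig(**base)

    return make


@pytest.fixture(scope="session")
def single_sphere():
    """Noise-free stack holding one centred 10 um sphere, plus its truth."""
    cfg = sc.SceneConfig(
        field_size_um=(127.0, 127.0),
        pixels_per_axis=128,
        z_depth_um=80.0,
        plaque_density_per_mm3=0.0,
        halo_amplitude=0.0,
        noise_gaussian_sd=0.0,
        noise_signal_scale=0.0,
        quantize=False,
        rng_seed=1,
    )
    gt = sc.SceneGroundTruth(
        centers_um=np.array([[63.5, 63.5, 40.0]]),
        radii_by_session_um=[[10.0]],
        halo_amplitude=0.0,
        halo_decay_by_session_um=[[2.0]],
        session_days=[13],
        jitter_px=np.zeros((1, 2), dtype=int),
        rng_seed=1,
    )
    return cfg, gt, sc.render_noise_free(gt, 0, cfg)


@pytest.fixture(scope="session")
def acceptance_field_configs():
    """The five 254 um fields (15 plaques each) used for growth recovery."""
    volume_mm3 = 0.254 * 0.254 * 0.300
    return [
        sc.SceneConfig(
            field_size_um=(254.0, 254.0),
            pixels_per_axis=256,
            plaque_density_per_mm3=15.0 / volume_mm3,
            rng_seed=seed,
        )
        for seed in range(100, 105)
    ]
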