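"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from fruitsense.scene_sim import SceneConfig, default_signatures, generate_scene


def noiseless_config(high_res=(205, 256), **overrides):
    """Scaled-down scene with zero reflectance and depth noise."""
    over = dict(
        signatures=default_signatures(noise_sd=0.0),
        depth_noise_sd_m=0.0,
        **overrides,
    )
    return SceneConfig.scaled(high_res=high_res, **over)


@pytest.fixture(scope="session")
def tiny_noiseless_scene():
    """A 205x256 noiseless scene: (config, frame, tof, truth)."""
    cfg = noiseless_config(n_fruits=6)
    frame, tof, truth = generate_scene(cfg, seed=11)
    return cfg, frame, tof, truth


@pytest.fixture(scope="session")
def tiny_noisy_scene():
    """A 205x256 scene at the generator's default noise levels."""
    cfg = SceneConfig.scaled(high_res=(205, 256), n_fruits=6)
    frame, tof, truth = generate_scene(cfg, seed=12)
    return cfg, frame, tof, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
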