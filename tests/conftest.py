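import dataclasses

import numpy as np
import pytest

from gfseg import canopy_sim as cs
from gfseg import render as rn


def clean_camera(resolution: int = 256) -> rn.CameraConfig:
    """Nadir close-range camera giving ~1.4-2.8 mm/pixel so leaves span
    several pixels: the 'clean' evaluation configuration."""
    return rn.CameraConfig(height=1.0, fov=40.0, inclination=0.0, resolution=resolution)


def clean_light() -> rn.LightConfig:
    """Sunny but shadow-free, diffuse-heavy illumination."""
    return rn.LightConfig(condition="sunny", diffuse_fraction=0.45, shadows=False)


def small_params(crop: str = "wheat", seed: int = 0, **overrides) -> cs.CanopyParams:
    base = cs.CanopyParams(
        crop=crop, growth_stage=2, n_stages=2, plant_density=25.0,
        row_spacing=0.15, plant_jitter=0.01, tillers_per_plant=2,
        leaves_per_tiller=3, leaf_length=0.18, leaf_max_width=0.014,
        leaf_inclination=55.0, leaf_curvature=1.0, plant_height=0.4,
        seed=seed,
    )
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def small_scene():
    return cs.build_canopy(small_params(), plot_extent=(0.8, 0.8))


@pytest.fixture(scope="session")
def clean_sample(small_scene):
    return rn.render_sample(small_scene, clean_camera(), clean_light(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
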