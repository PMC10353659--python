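"""Preset study protocols: fixed generator + camera configurations.

Two reference protocols are bundled so that bulk dataset generation and
baseline evaluation are reproducible by name rather than by ad-hoc
parameter choices:

``bulk_render_stream``
    The paper-scale dataset protocol: Latin-hypercube points replicated
    over growth stages, rendered at 1,024 x 1,024 with the reference
    camera (1.5 m height, 85 deg horizontal FOV, 45 deg inclination).
    Uses the sparse low-fidelity parameter space so thousands of scenes
    render on one CPU.

``clean_sample_stream``
    The clean evaluation protocol for the classical baseline: nadir
    close-range camera (~1.4 mm/pixel at 512 px) over the full-density
    space, sunny but shadow-free illumination, alternating rice/wheat.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import canopy_sim as cs
from . import render as rn

__all__ = ["bulk_render_stream", "clean_sample_stream", "BULK_CAMERA", "CLEAN_LIGHT"]

BULK_CAMERA = rn.CameraConfig(height=1.5, fov=85.0, inclination=45.0, resolution=1024)
CLEAN_LIGHT = rn.LightConfig(condition="sunny", diffuse_fraction=0.45, shadows=False)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def bulk_render_stream(n_points: int, n_stages: int, seed: int,
                       crop: str = "wheat",
                       camera: rn.CameraConfig = BULK_CAMERA,
                       plot_extent: tuple[float, float] = (0.6, 0.6),
                       ) -> Iterator[rn.RenderedSample]:
    """Yield renders of ``n_points`` LHS points x ``n_stages`` stages,
    one at a time (streaming keeps memory flat for thousands of scenes)."""
    space = cs.low_fidelity_space(crop, n_stages)
    light = rn.LightConfig(condition="sunny", diffuse_fraction=0.35, shadows=False)
    points = cs.sample_parameter_space(space, n_points, seed)
    for p in cs.expand_stages(points):
        scene = cs.build_canopy(p, plot_extent=plot_extent)
        yield rn.render_sample(scene, camera, light, seed=p.seed + p.growth_stage, params=p)


def clean_sample_stream(n: int, seed: int, resolution: int = 512,
                        ) -> Iterator[rn.RenderedSample]:
    """Yield ``n`` clean evaluation samples, alternating rice and wheat
    across the full-density parameter space and cycling growth stages."""
    camera = rn.CameraConfig(height=1.0, fov=40.0, inclination=0.0, resolution=resolution)
    per_crop = -(-n // 2)
    n_pts = -(-per_crop // 4)
    specs = []
    for i, crop in enumerate(("rice", "wheat")):
        space = cs.default_space(crop, n_stages=4)
        pts = cs.sample_parameter_space(space, n_pts, int(_sub_seeds(seed, 2)[i]))
        specs.append(cs.expand_stages(pts))
    interleaved = [s for pair in zip(*specs) for s in pair][:n]
    for p in interleaved:
        scene = cs.build_canopy(p, plot_extent=(0.7, 0.7))
        yield rn.render_sample(scene, camera, CLEAN_LIGHT, seed=p.seed, params=p)
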