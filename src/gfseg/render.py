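"""Pinhole projection and deterministic rasterized rendering.

A :class:`Scene` is projected through a pinhole camera and shaded under a
two-condition (sunny/cloudy) illumination model to produce an 8-bit sRGB
image together with a pixel-perfect green-vegetation mask.  The mask is
decided per pixel by majority vote over a 4x4 subpixel coverage grid
(ties go to background), from the same geometry pass as the RGB image, so
image and label are aligned by construction and the label never depends
on illumination.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import _raster
from .canopy_sim import CanopyParams, Scene

__all__ = [
    "CameraConfig",
    "LightConfig",
    "RenderedSample",
    "project",
    "render_sample",
    "ground_sample_distance",
    "write_sample",
    "read_sample",
]

#: subpixel supersampling factor per axis for mask coverage
SUPERSAMPLE = 4
_NEAR = 1e-3
_SHADOW_RES = 1024


@dataclass(frozen=True)
class CameraConfig:
    """Pinhole camera above the background plane.

    ``fov`` is the horizontal field of view; ``inclination`` is measured
    from nadir (0 = looking straight down); images are square.
    """

    height: float = 1.5
    fov: float = 85.0
    inclination: float = 45.0
    resolution: int = 1024
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.fov < 180:
            raise ValueError("fov must lie in (0, 180) degrees")
        if not 0 <= self.inclination <= 90:
            raise ValueError("inclination must lie in [0, 90] degrees")
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16")
        if self.height <= 0:
            raise ValueError("camera height must be > 0")

    # camera basis: x right, y image-down, z forward
    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        i = math.radians(self.inclination)
        a = math.radians(self.azimuth)
        fwd = np.array([math.sin(i) * math.sin(a), math.sin(i) * math.cos(a), -math.cos(i)])
        right = np.array([math.cos(a), -math.sin(a), 0.0])
        down = np.cross(fwd, right)
        pos = np.array([0.0, 0.0, self.height])
        return pos, right, down, fwd

    @property
    def focal_px(self) -> float:
        return (self.resolution / 2) / math.tan(math.radians(self.fov) / 2)


@dataclass(frozen=True)
class LightConfig:
    """Illumination: direct sun + diffuse sky.

    Sunny conditions are direct-dominated (diffuse_fraction < 0.5, hard
    shadows optional); cloudy conditions are diffuse-dominated
    (diffuse_fraction >= 0.8, no hard shadows).
    """

    condition: str = "sunny"
    sun_elevation: float = 55.0
    sun_azimuth: float = 135.0
    diffuse_fraction: float = 0.3
    shadows: bool = True

    def __post_init__(self) -> None:
        if self.condition not in ("sunny", "cloudy"):
            raise ValueError("condition must be 'sunny' or 'cloudy'")
        if self.condition == "sunny" and not self.diffuse_fraction < 0.5:
            raise ValueError("sunny requires diffuse_fraction < 0.5")
        if self.condition == "cloudy" and not self.diffuse_fraction >= 0.8:
            raise ValueError("cloudy requires diffuse_fraction >= 0.8")
        if not 0 <= self.diffuse_fraction <= 1:
            raise ValueError("diffuse_fraction must lie in [0, 1]")

    def sun_dir(self) -> np.ndarray:
        e = math.radians(self.sun_elevation)
        a = math.radians(self.sun_azimuth)
        return np.array([math.cos(e) * math.sin(a), math.cos(e) * math.cos(a), math.sin(e)])


@dataclass
class RenderedSample:
    """RGB image + aligned binary green mask + provenance metadata."""

    rgb: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True = green vegetation
    meta: dict

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask dimensions must match")


def project(point, camera: CameraConfig):
    """Project one world point; returns (u, v) continuous pixel
    coordinates (top-left origin) or None if the point is behind the
    camera plane.  Raises on the camera origin itself."""
    pos, right, down, fwd = camera.basis()
    p = np.asarray(point, dtype=float) - pos
    if np.allclose(p, 0.0):
        raise ValueError("cannot project the camera origin")
    z = float(p @ fwd)
    if z <= 0:
        return None
    c = camera.resolution / 2
    u = c + camera.focal_px * float(p @ right) / z
    v = c + camera.focal_px * float(p @ down) / z
    return (u, v)


def ground_sample_distance(camera: CameraConfig) -> float:
    """Ground footprint of one pixel at the image center [mm/pixel]."""
    if camera.inclination >= 90:
        raise ValueError("grazing geometry: inclination must be < 90 degrees")
    slant = camera.height / math.cos(math.radians(camera.inclination))
    swath = 2 * slant * math.tan(math.radians(camera.fov) / 2)
    return 1000.0 * swath / camera.resolution


def _project_triangles(scene: Scene, camera: CameraConfig) -> np.ndarray:
    """Vertex projection to subsample screen units; NaN-flags triangles
    with any vertex at or behind the near plane."""
    pos, right, down, fwd = camera.basis()
    verts = scene.triangles.reshape(-1, 3) - pos
    zc = verts @ fwd
    xc = verts @ right
    yc = verts @ down
    res2 = camera.resolution / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (res2 + camera.focal_px * xc / zc) * SUPERSAMPLE
        v = (res2 + camera.focal_px * yc / zc) * SUPERSAMPLE
        iz = 1.0 / zc
    out = np.stack([u, v, iz], axis=1).reshape(-1, 3, 3)
    bad = (zc.reshape(-1, 3) <= _NEAR).any(axis=1)
    out[bad, 0, 0] = np.nan
    return out


def _triangle_normals(tris: np.ndarray) -> np.ndarray:
    a = tris[:, 1] - tris[:, 0]
    b = tris[:, 2] - tris[:, 0]
    n = np.cross(a, b)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def _linear_to_srgb(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return np.where(x <= 0.0031308, 12.92 * x, 1.055 * np.power(x, 1 / 2.4) - 0.055)


def render_sample(
    scene: Scene,
    camera: CameraConfig,
    light: LightConfig,
    seed: int,
    params: CanopyParams | None = None,
) -> RenderedSample:
    """Rasterize ``scene`` to an RGB image and its green-vegetation mask.

    Deterministic for fixed inputs and seed.  The seed drives per-facet
    leaf-color variation and the background texture phase only; geometry
    and therefore the mask are seed- and light-independent.
    """
    res = camera.resolution
    ss_res = res * SUPERSAMPLE
    tri_id = np.full((ss_res, ss_res), -1, dtype=np.int32)
    invz = np.zeros((ss_res, ss_res), dtype=np.float64)

    n_tri = scene.n_triangles
    rng = np.random.default_rng(seed)
    if n_tri:
        screen = _project_triangles(scene, camera)
        _raster.rasterize(screen, ss_res, ss_res, tri_id, invz)
        normals = _triangle_normals(scene.triangles)
        facet_jitter = rng.uniform(0.85, 1.15, size=(n_tri, 1))
        colors = np.clip(scene.leaf_colors * facet_jitter, 0.0, 1.0)
        world_tris = scene.triangles
    else:
        normals = np.zeros((1, 3))
        colors = np.zeros((1, 3))
        world_tris = np.zeros((1, 3, 3))

    sun = light.sun_dir()
    use_shadow = bool(light.condition == "sunny" and light.shadows and n_tri)

    # orthographic sun-view shadow map over the scene bounding box
    if use_shadow:
        up = np.array([0.0, 0.0, 1.0])
        if abs(sun[2]) > 0.99:
            up = np.array([0.0, 1.0, 0.0])
        s1 = np.cross(sun, up)
        s1 /= np.linalg.norm(s1)
        s2 = np.cross(sun, s1)
        pts = scene.triangles.reshape(-1, 3)
        c1 = pts @ s1
        c2 = pts @ s2
        pad = 0.02
        org1, org2 = c1.min() - pad, c2.min() - pad
        span = max(c1.max() - org1, c2.max() - org2) + pad
        scale = _SHADOW_RES / span
        smap = np.full((_SHADOW_RES, _SHADOW_RES), -1e30, dtype=np.float64)
        _raster.shadow_map(world_tris, s1, s2, sun, org1, org2, scale, _SHADOW_RES, smap)
    else:
        s1 = np.array([1.0, 0.0, 0.0])
        s2 = np.array([0.0, 1.0, 0.0])
        org1 = org2 = 0.0
        scale = 1.0
        smap = np.zeros((1, 1), dtype=np.float64)

    bg = scene.background
    pos, right, down, fwd = camera.basis()
    rgb_lin = np.empty((res, res, 3), dtype=np.float64)
    green_count = np.zeros((res, res), dtype=np.int32)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    _raster.shade(
        tri_id, invz, SUPERSAMPLE, res, pos, right, down, fwd, camera.focal_px,
        normals, colors, sun, light.diffuse_fraction, use_shadow,
        s1, s2, org1, org2, scale, _SHADOW_RES if use_shadow else 1, smap,
        bg.kind == "water", np.asarray(bg.albedo, dtype=np.float64), bg.mottle,
        bg.gray_level, bg.specular_strength, noise_seed,
        rgb_lin, green_count,
    )

    rgb = (_linear_to_srgb(rgb_lin) * 255.0 + 0.5).astype(np.uint8)
    # majority of the 16 subsamples; exact tie -> background
    mask = green_count > (SUPERSAMPLE * SUPERSAMPLE) // 2

    meta = {
        "camera": dataclasses.asdict(camera),
        "light": dataclasses.asdict(light),
        "seed": int(seed),
        "gsd_mm_per_pixel": ground_sample_distance(camera),
        "green_pixel_count": int(mask.sum()),
        "params": params.to_dict() if params is not None else None,
    }
    return RenderedSample(rgb=rgb, mask=mask, meta=meta)


def write_sample(sample: RenderedSample, out_dir, sample_id: str) -> dict:
    """Write ``<id>_rgb.png``, ``<id>_mask.png`` (0/255) and
    ``<id>_meta.json``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rgb_path = out / f"{sample_id}_rgb.png"
    mask_path = out / f"{sample_id}_mask.png"
    meta_path = out / f"{sample_id}_meta.json"
    Image.fromarray(sample.rgb).save(rgb_path)
    Image.fromarray((sample.mask.astype(np.uint8) * 255)).save(mask_path)
    with open(meta_path, "w") as fh:
        json.dump(sample.meta, fh, indent=1)
    return {"rgb": str(rgb_path), "mask": str(mask_path), "meta": str(meta_path)}


def read_sample(out_dir, sample_id: str) -> RenderedSample:
    out = Path(out_dir)
    rgb = np.asarray(Image.open(out / f"{sample_id}_rgb.png").convert("RGB"))
    mask = np.asarray(Image.open(out / f"{sample_id}_mask.png").convert("L")) > 0
    with open(out / f"{sample_id}_meta.json") as fh:
        meta = json.load(fh)
    return RenderedSample(rgb=rgb, mask=mask, meta=meta)
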