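"""Parametric canopy scene generation.

Defines a documented, extensible simulation parameter space for rice and
wheat canopies, samples it by Latin-hypercube sampling, and builds 3D
scenes (triangle meshes of green organs over a soil or water background).

The canopy model is deliberately parametric rather than physiological: a
plant is a set of tillers, each carrying leaves realized as drooping
arc-midrib strips whose inclination and curvature are direct controls.
World units are meters; angles are degrees; z=0 is the background plane.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Dim",
    "ParameterSpace",
    "CanopyParams",
    "Background",
    "Scene",
    "default_space",
    "sample_parameter_space",
    "expand_stages",
    "build_canopy",
    "leaf_surface",
]

GREEN_VEGETATION = "green_vegetation"

#: fraction of leaf length at which the width profile peaks
_WIDTH_PEAK = 0.3
#: midrib segments per leaf (>= 8 required for the area contract)
_N_SEGMENTS = 16


@dataclass(frozen=True)
class Dim:
    """One sampled dimension of the parameter space."""

    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" or "log"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"dim {self.name!r}: require low < high, got [{self.low}, {self.high}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"dim {self.name!r}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"dim {self.name!r}: log scale requires low > 0")


@dataclass(frozen=True)
class ParameterSpace:
    """A box-shaped canopy parameter space for one crop.

    Each :class:`Dim` name must correspond to a numeric field of
    :class:`CanopyParams`.  ``n_stages`` is the number of discrete growth
    stages each sampled point is replicated over downstream.
    """

    dims: tuple[Dim, ...]
    crop: str
    n_stages: int = 4

    def __post_init__(self) -> None:
        if self.crop not in ("rice", "wheat"):
            raise ValueError(f"crop must be 'rice' or 'wheat', got {self.crop!r}")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        names = [d.name for d in self.dims]
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        valid = {f.name for f in dataclasses.fields(CanopyParams)}
        for d in self.dims:
            if d.name not in valid:
                raise ValueError(f"unknown parameter dimension {d.name!r}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ParameterSpace":
        dims = tuple(
            Dim(d["name"], float(d["low"]), float(d["high"]), d.get("scale", "linear"))
            for d in cfg["dims"]
        )
        return cls(dims=dims, crop=cfg["crop"], n_stages=int(cfg.get("n_stages", 4)))

    @classmethod
    def from_yaml(cls, path) -> "ParameterSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "crop": self.crop,
            "n_stages": self.n_stages,
            "dims": [dataclasses.asdict(d) for d in self.dims],
        }


#: CanopyParams fields that are integer counts (rounded on materialization)
_INT_FIELDS = frozenset({"tillers_per_plant", "leaves_per_tiller"})


@dataclass(frozen=True)
class CanopyParams:
    """One point of the simulation parameter space, for one growth stage.

    plant_density      plants per square meter
    row_spacing        distance between sowing rows [m]
    plant_jitter       max positional noise along/across row [m]
    leaf_inclination   angle of the leaf base tangent above horizontal [deg]
    leaf_curvature     dimensionless droop coefficient (0 = straight leaf)
    leaf_hue, leaf_saturation  greenness scalars in [0, 1]
    """

    crop: str = "wheat"
    growth_stage: int = 1
    n_stages: int = 1
    plant_density: float = 150.0
    row_spacing: float = 0.15
    plant_jitter: float = 0.01
    tillers_per_plant: int = 3
    leaves_per_tiller: int = 4
    leaf_length: float = 0.20
    leaf_max_width: float = 0.012
    leaf_inclination: float = 60.0
    leaf_curvature: float = 1.0
    plant_height: float = 0.5
    leaf_hue: float = 0.5
    leaf_saturation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop not in ("rice", "wheat"):
            raise ValueError(f"crop must be 'rice' or 'wheat', got {self.crop!r}")
        if not 1 <= self.growth_stage <= self.n_stages:
            raise ValueError("growth_stage must lie in [1, n_stages]")
        for name in ("plant_density", "row_spacing", "tillers_per_plant",
                     "leaves_per_tiller", "leaf_length", "leaf_max_width",
                     "plant_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.row_spacing <= 0:
            raise ValueError("row_spacing must be > 0")
        if self.plant_jitter < 0 or self.leaf_curvature < 0:
            raise ValueError("plant_jitter and leaf_curvature must be >= 0")
        if not 0 <= self.leaf_inclination <= 90:
            raise ValueError("leaf_inclination must lie in [0, 90] degrees")
        for name in ("leaf_hue", "leaf_saturation"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CanopyParams":
        return cls(**d)


@dataclass(frozen=True)
class Background:
    """Background plane descriptor: mottled soil (wheat) or flat water (rice).

    Rice paddies image as a light-gray specular water surface; wheat plots
    as textured brown soil.
    """

    kind: str  # "soil" or "water"
    # soil
    albedo: tuple[float, float, float] = (0.42, 0.30, 0.19)
    mottle: float = 0.35  # relative amplitude of the albedo texture
    # water
    gray_level: float = 0.62
    specular_strength: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("soil", "water"):
            raise ValueError(f"background kind must be 'soil' or 'water', got {self.kind!r}")
        object.__setattr__(self, "albedo", tuple(self.albedo))

    @classmethod
    def for_crop(cls, crop: str) -> "Background":
        return cls(kind="water" if crop == "rice" else "soil")


@dataclass
class Scene:
    """Geometric canopy: green-organ triangles over a background plane.

    ``triangles`` is (n, 3, 3) float64 in world meters; every triangle is
    tagged ``green_vegetation``.  ``leaf_colors`` carries one linear-RGB
    base color per triangle (rendering input, not geometry).
    """

    triangles: np.ndarray
    organ_class: list[str]
    background: Background
    plot_extent: tuple[float, float]
    leaf_colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.triangles = np.asarray(self.triangles, dtype=np.float64).reshape(-1, 3, 3)
        if not np.all(np.isfinite(self.triangles)):
            raise ValueError("scene triangles must be finite")
        if self.triangles.size and self.triangles[..., 2].min() < -1e-9:
            raise ValueError("scene triangles must lie above the background plane z=0")
        if len(self.organ_class) != len(self.triangles):
            raise ValueError("one organ_class tag per triangle required")
        if self.leaf_colors is None:
            self.leaf_colors = np.full((len(self.triangles), 3), (0.1, 0.45, 0.08))
        self.leaf_colors = np.asarray(self.leaf_colors, dtype=np.float64).reshape(-1, 3)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def total_area(self) -> float:
        """Summed one-sided surface area of all triangles [m^2]."""
        if not self.triangles.size:
            return 0.0
        a = self.triangles[:, 1] - self.triangles[:, 0]
        b = self.triangles[:, 2] - self.triangles[:, 0]
        return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())

    def to_json(self, path) -> None:
        payload = {
            "plot_extent": list(self.plot_extent),
            "background": dataclasses.asdict(self.background),
            "organ_class": self.organ_class,
            "triangles": self.triangles.tolist(),
            "leaf_colors": self.leaf_colors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Scene":
        with open(path) as fh:
            payload = json.load(fh)
        bg = Background(**payload["background"])
        return cls(
            triangles=np.array(payload["triangles"]),
            organ_class=payload["organ_class"],
            background=bg,
            plot_extent=tuple(payload["plot_extent"]),
            leaf_colors=np.array(payload["leaf_colors"]),
        )


def default_space(crop: str = "wheat", n_stages: int = 4) -> ParameterSpace:
    """Default ~13-dimensional parameter space reproducing a <=2 m,
    0.3-0.6 mm/pixel nadir-to-45-degree capture regime for field plots."""
    rice = crop == "rice"
    dims = (
        Dim("plant_density", 40.0, 120.0 if rice else 300.0),
        Dim("row_spacing", 0.18 if rice else 0.12, 0.30 if rice else 0.20),
        Dim("plant_jitter", 0.0, 0.03),
        Dim("tillers_per_plant", 1.0, 8.0),
        Dim("leaves_per_tiller", 2.0, 6.0),
        Dim("leaf_length", 0.12, 0.45 if rice else 0.30),
        Dim("leaf_max_width", 0.006, 0.018),
        Dim("leaf_inclination", 25.0, 85.0),
        Dim("leaf_curvature", 0.0, 2.5),
        Dim("plant_height", 0.2, 1.0),
        Dim("leaf_hue", 0.25, 0.75),
        Dim("leaf_saturation", 0.45, 0.95),
    )
    return ParameterSpace(dims=dims, crop=crop, n_stages=n_stages)


def low_fidelity_space(crop: str = "wheat", n_stages: int = 4) -> ParameterSpace:
    """Sparse-canopy variant of :func:`default_space` for bulk runs:
    identical structure and capture regime, but low plant densities and
    organ counts so that thousands of scenes render quickly on one CPU."""
    rice = crop == "rice"
    dims = (
        Dim("plant_density", 5.0, 25.0),
        Dim("row_spacing", 0.18 if rice else 0.12, 0.30 if rice else 0.20),
        Dim("plant_jitter", 0.0, 0.03),
        Dim("tillers_per_plant", 1.0, 2.0),
        Dim("leaves_per_tiller", 2.0, 3.0),
        Dim("leaf_length", 0.12, 0.35),
        Dim("leaf_max_width", 0.006, 0.018),
        Dim("leaf_inclination", 25.0, 85.0),
        Dim("leaf_curvature", 0.0, 2.5),
        Dim("plant_height", 0.2, 1.0),
        Dim("leaf_hue", 0.25, 0.75),
        Dim("leaf_saturation", 0.45, 0.95),
    )
    return ParameterSpace(dims=dims, crop=crop, n_stages=n_stages)


def sample_parameter_space(
    space: ParameterSpace, n: int, seed: int
) -> list[CanopyParams]:
    """Draw ``n`` Latin-hypercube samples of ``space``.

    For every dimension the samples occupy the ``n`` equal-probability
    strata with exactly one point per stratum.  Log-scaled dimensions are
    stratified in log10 space.  Each returned point is at growth stage 1;
    pair with :func:`expand_stages` to replicate across stages.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    from scipy.stats import qmc

    sampler = qmc.LatinHypercube(d=len(space.dims), seed=seed)
    unit = sampler.random(n)
    out: list[CanopyParams] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    for i in range(n):
        kwargs: dict = {
            "crop": space.crop,
            "growth_stage": 1,
            "n_stages": space.n_stages,
            "seed": int(child_seeds[i]),
        }
        for j, d in enumerate(space.dims):
            u = unit[i, j]
            if d.scale == "log":
                v = 10 ** (math.log10(d.low) + u * (math.log10(d.high) - math.log10(d.low)))
            else:
                v = d.low + u * (d.high - d.low)
            kwargs[d.name] = int(round(v)) if d.name in _INT_FIELDS else float(v)
        out.append(CanopyParams(**kwargs))
    return out


def expand_stages(samples: Sequence[CanopyParams], n_stages: int | None = None) -> list[CanopyParams]:
    """Replicate each sampled point across all growth stages.

    500 sampled points with 4 stages yield 2,000 scene specifications.
    """
    out = []
    for p in samples:
        k = n_stages if n_stages is not None else p.n_stages
        for s in range(1, k + 1):
            out.append(dataclasses.replace(p, growth_stage=s, n_stages=k))
    return out


def _stage_factor(params: CanopyParams) -> float:
    """Monotone organ-size/count multiplier: 1/n_stages ... 1."""
    return params.growth_stage / params.n_stages


def leaf_surface(
    length: float,
    max_width: float,
    inclination: float,
    curvature: float,
    azimuth: float,
    base: Sequence[float],
) -> np.ndarray:
    """Triangulated drooping-leaf strip.

    The midrib is a planar arc leaving ``base`` at ``inclination`` degrees
    above horizontal; the tangent angle decreases linearly with arc length
    at total rate ``curvature * 90 degrees`` over the full length, so
    curvature 0 gives a straight midrib and large curvature folds the tip
    below the base.  The half-width profile rises linearly from 0 to
    ``max_width`` at 30% of the length, then tapers linearly to 0 at the
    tip; the strip is ruled horizontally, perpendicular to the azimuth.

    Returns an (n, 3, 3) triangle array (n = 2 * segments).
    """
    if length <= 0 or max_width <= 0:
        raise ValueError("length and max_width must be > 0")
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    base = np.asarray(base, dtype=float)
    theta0 = math.radians(inclination)
    rate = curvature * (math.pi / 2) / length  # d(theta)/ds
    az = math.radians(azimuth)
    e_r = np.array([math.sin(az), math.cos(az), 0.0])  # horizontal run direction
    e_w = np.array([math.cos(az), -math.sin(az), 0.0])  # lateral (width) direction

    s = np.linspace(0.0, length, _N_SEGMENTS + 1)
    theta = theta0 - rate * s
    # exact arc integral of (cos theta, sin theta) ds
    if rate > 0:
        run = (np.sin(theta0) - np.sin(theta)) / rate
        rise = (np.cos(theta) - np.cos(theta0)) / rate
    else:
        run = np.cos(theta0) * s
        rise = np.sin(theta0) * s
    midrib = base[None, :] + run[:, None] * e_r[None, :] + rise[:, None] * np.array([0, 0, 1.0])[None, :]

    w = np.where(
        s <= _WIDTH_PEAK * length,
        max_width * s / (_WIDTH_PEAK * length),
        max_width * (length - s) / ((1.0 - _WIDTH_PEAK) * length),
    )
    left = midrib - 0.5 * w[:, None] * e_w[None, :]
    right = midrib + 0.5 * w[:, None] * e_w[None, :]

    tris = []
    for k in range(_N_SEGMENTS):
        # base and tip rows are degenerate on one side; emit both triangles
        # of the quad anyway (zero-area ones contribute nothing)
        tris.append([left[k], right[k], right[k + 1]])
        tris.append([left[k], right[k + 1], left[k + 1]])
    return np.asarray(tris)


def _hsv_leaf_color(hue: float, sat: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded per-leaf base color in linear RGB, biased green."""
    import colorsys

    h = 0.22 + 0.12 * hue + rng.uniform(-0.015, 0.015)  # green hues
    s = np.clip(sat + rng.uniform(-0.08, 0.08), 0.2, 1.0)
    v = np.clip(0.45 + 0.25 * rng.uniform(), 0.1, 1.0)
    return np.asarray(colorsys.hsv_to_rgb(h % 1.0, float(s), float(v)))


def build_canopy(params: CanopyParams, plot_extent: tuple[float, float] = (2.0, 2.0)) -> Scene:
    """Build a canopy :class:`Scene` from one parameter point.

    Plants are placed on a regular row grid (spacing ``row_spacing``
    across rows; within-row spacing chosen so the realized plant count is
    ``round(plant_density * plot_area)``) with seeded uniform jitter.
    Growth stage scales leaf dimensions and organ counts monotonically.
    Deterministic for a given ``params`` (the per-leaf random variation is
    keyed on stable plant/tiller/leaf indices).
    """
    ex, ey = plot_extent
    if ex <= 0 or ey <= 0:
        raise ValueError("plot extent must be positive")
    f = _stage_factor(params)
    n_plants = int(round(params.plant_density * ex * ey))
    bg = Background.for_crop(params.crop)
    if n_plants == 0:
        return Scene(np.empty((0, 3, 3)), [], bg, plot_extent, np.empty((0, 3)))

    n_rows = max(1, int(round(ex / params.row_spacing)))
    per_row = [n_plants // n_rows] * n_rows
    for r in range(n_plants % n_rows):
        per_row[r] += 1

    n_tillers = max(1, int(round(params.tillers_per_plant * f)))
    n_leaves = max(1, int(round(params.leaves_per_tiller * f)))
    leaf_len = params.leaf_length * f
    leaf_wid = params.leaf_max_width * (0.5 + 0.5 * f)
    height = params.plant_height * f

    tris: list[np.ndarray] = []
    colors: list[np.ndarray] = []
    plant_idx = 0
    for r, count in enumerate(per_row):
        x0 = (r + 0.5) * ex / n_rows - ex / 2
        for q in range(count):
            y0 = (q + 0.5) * ey / max(count, 1) - ey / 2
            prng = np.random.default_rng(np.random.SeedSequence((params.seed, plant_idx)))
            jx, jy = prng.uniform(-params.plant_jitter, params.plant_jitter, 2)
            px, py = x0 + jx, y0 + jy
            for t in range(n_tillers):
                t_az = prng.uniform(0, 360)
                for l in range(n_leaves):
                    lrng = np.random.default_rng(
                        np.random.SeedSequence((params.seed, plant_idx, t, l))
                    )
                    var = lrng.uniform(0.9, 1.1)
                    base_z = height * (l + 1) / (n_leaves + 1)
                    az = (t_az + l * 137.5 + lrng.uniform(-20, 20)) % 360
                    incl = float(np.clip(params.leaf_inclination + lrng.uniform(-8, 8), 0, 90))
                    leaf = leaf_surface(
                        length=leaf_len * var,
                        max_width=leaf_wid * var,
                        inclination=incl,
                        curvature=params.leaf_curvature,
                        azimuth=az,
                        base=(px, py, base_z),
                    )
                    leaf[..., 2] = np.maximum(leaf[..., 2], 0.0)  # clamp droop at ground
                    color = _hsv_leaf_color(params.leaf_hue, params.leaf_saturation, lrng)
                    tris.append(leaf)
                    colors.append(np.tile(color, (len(leaf), 1)))
            plant_idx += 1

    all_tris = np.concatenate(tris, axis=0)
    all_colors = np.concatenate(colors, axis=0)
    return Scene(
        triangles=all_tris,
        organ_class=[GREEN_VEGETATION] * len(all_tris),
        background=bg,
        plot_extent=plot_extent,
        leaf_colors=all_colors,
    )
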