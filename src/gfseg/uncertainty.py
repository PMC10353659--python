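"""Per-pixel uncertainty analysis of segmentation errors.

Two per-pixel features drive the analysis: the excess-green index
ExG = 2G - R - B on raw 8-bit digital numbers (greenness axis) and
CIELAB L* under sRGB/D65 (brightness axis).  Prediction/truth pairs are
decomposed into TP/TN/FP/FN error maps; per-class feature distributions
are summarized by Gaussian kernel density estimates (Scott's rule), and
error maps render to color-coded overlay images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "CLASS_TP", "CLASS_TN", "CLASS_FP", "CLASS_FN",
    "CLASS_NAMES", "DEFAULT_PALETTE",
    "PixelErrorMap", "DensityEstimate",
    "exg_map", "lightness_map", "error_map", "class_density",
    "render_error_overlay", "decode_error_overlay",
]

CLASS_TP, CLASS_TN, CLASS_FP, CLASS_FN = 0, 1, 2, 3
CLASS_NAMES = {CLASS_TP: "TP", CLASS_TN: "TN", CLASS_FP: "FP", CLASS_FN: "FN"}

#: TP green, TN black, FP red, FN blue — distinct, bijective
DEFAULT_PALETTE = {
    CLASS_TP: (0, 170, 0),
    CLASS_TN: (30, 30, 30),
    CLASS_FP: (230, 40, 40),
    CLASS_FN: (40, 80, 230),
}


def exg_map(rgb: np.ndarray) -> np.ndarray:
    """Excess green, 2G - R - B, per pixel on raw digital numbers.

    Range [-510, 510]; positive values indicate green-dominant pixels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    r = rgb[..., 0].astype(np.int32)
    g = rgb[..., 1].astype(np.int32)
    b = rgb[..., 2].astype(np.int32)
    return (2 * g - r - b).astype(np.float64)


def lightness_map(rgb: np.ndarray) -> np.ndarray:
    """CIELAB L* in [0, 100], interpreting the input as sRGB under D65."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return rgb2lab(rgb.astype(np.float64) / 255.0)[..., 0]


@dataclass
class PixelErrorMap:
    """H x W per-pixel error classes (values CLASS_TP..CLASS_FN)."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.size and self.classes.max() > CLASS_FN:
            raise ValueError("error map contains invalid class values")

    def proportions(self) -> dict[str, float]:
        n = self.classes.size
        return {CLASS_NAMES[c]: int(np.count_nonzero(self.classes == c)) / n
                for c in CLASS_NAMES}


def error_map(pred, truth) -> PixelErrorMap:
    """Classify every pixel of a prediction/truth pair as TP/TN/FP/FN
    (green vegetation positive)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"dimension mismatch: {pred.shape} vs {truth.shape}")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    out = np.empty(pred.shape, dtype=np.uint8)
    out[pred & truth] = CLASS_TP
    out[~pred & ~truth] = CLASS_TN
    out[pred & ~truth] = CLASS_FP
    out[~pred & truth] = CLASS_FN
    return PixelErrorMap(classes=out)


@dataclass
class DensityEstimate:
    """1-D Gaussian-kernel density of one error class's feature values.

    ``absent`` flags a class with no pixels (grid/density empty).
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int
    class_label: str

    @property
    def absent(self) -> bool:
        return self.n_samples == 0

    def integral(self) -> float:
        if self.absent:
            return 0.0
        return float(np.trapezoid(self.density, self.grid))


def class_density(values: np.ndarray, emap: PixelErrorMap, cls: int,
                  grid_size: int = 256) -> DensityEstimate:
    """KDE of the feature ``values`` restricted to error class ``cls``.

    Gaussian kernels, Scott's-rule bandwidth, evaluated on a uniform grid
    spanning [min - 3bw, max + 3bw].  An empty class yields an explicit
    absent-class result rather than an exception.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=np.float64)
    if values.shape != emap.classes.shape:
        raise ValueError("feature field and error map dimensions must match")
    label = CLASS_NAMES[cls]
    sel = values[emap.classes == cls]
    if sel.size == 0:
        return DensityEstimate(np.empty(0), np.empty(0), 0.0, 0, label)
    if sel.size < 2:
        raise ValueError(f"class {label} needs >= 2 pixels for a density estimate")
    if sel.std() == 0:
        raise ValueError(f"class {label} values are constant; no density bandwidth exists")
    kde = gaussian_kde(sel, bw_method="scott")
    bw = float(kde.factor * sel.std(ddof=1))
    grid = np.linspace(sel.min() - 3 * bw, sel.max() + 3 * bw, grid_size)
    dens = kde(grid)
    return DensityEstimate(grid=grid, density=dens, bandwidth=bw,
                           n_samples=int(sel.size), class_label=label)


def render_error_overlay(emap: PixelErrorMap, palette: dict | None = None,
                         sidecar_path=None) -> np.ndarray:
    """Color-code the four error classes into an RGB image.

    The palette must be injective so that overlays decode back to the
    exact class map.  Legend metadata can be written to a sidecar JSON.
    """
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    if len({tuple(v) for v in palette.values()}) != len(palette):
        raise ValueError("palette colors must be distinct")
    h, w = emap.classes.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for cls, color in palette.items():
        out[emap.classes == cls] = color
    if sidecar_path is not None:
        legend = {CLASS_NAMES[c]: list(palette[c]) for c in palette}
        with open(sidecar_path, "w") as fh:
            json.dump({"legend": legend}, fh, indent=1)
    return out


def decode_error_overlay(overlay: np.ndarray, palette: dict | None = None) -> PixelErrorMap:
    """Inverse of :func:`render_error_overlay` (bijective palette)."""
    palette = dict(DEFAULT_PALETTE if palette is None else palette)
    overlay = np.asarray(overlay)
    out = np.full(overlay.shape[:2], 255, dtype=np.uint8)
    for cls, color in palette.items():
        out[np.all(overlay == np.asarray(color, dtype=np.uint8), axis=-1)] = cls
    if (out == 255).any():
        raise ValueError("overlay contains colors outside the palette")
    return PixelErrorMap(classes=out)


def densities_to_csv(estimates: list[DensityEstimate], path) -> None:
    """Export densities as long-form CSV (class, grid, density)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "grid", "density", "bandwidth", "n_samples"])
        for est in estimates:
            if est.absent:
                continue
            for g, d in zip(est.grid, est.density):
                w.writerow([est.class_label, g, d, est.bandwidth, est.n_samples])
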