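"""Segmenter contract, excess-green baseline, and external adapters.

Any segmenter maps an RGB image to a binary mask of identical size with
green vegetation as the positive class.  The shipped baseline thresholds
the per-pixel excess-green index (ExG = 2G - R - B) with Otsu's method —
the classical static-thresholding approach, usable at desk scale without
a GPU.  Deep models plug in through :func:`run_external`, a subprocess
contract that reads RGB PNGs and writes mask PNGs.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image

from .dataset import DatasetManifest, read_mask
from .uncertainty import exg_map

__all__ = [
    "SegmenterContract",
    "otsu_threshold",
    "segment_exg_otsu",
    "exg_otsu_segmenter",
    "run_external",
]


@dataclass(frozen=True)
class SegmenterContract:
    """A named function RGB image -> boolean mask of identical H x W."""

    name: str
    segment: Callable[[np.ndarray], np.ndarray]

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        mask = self.segment(rgb)
        mask = np.asarray(mask)
        if mask.shape != rgb.shape[:2]:
            raise ValueError(f"segmenter {self.name!r} returned wrong dimensions")
        if mask.dtype != bool:
            vals = np.unique(mask)
            if not set(vals.tolist()) <= {0, 1, 255}:
                raise ValueError(f"segmenter {self.name!r} output is not two-valued")
            mask = mask > 0
        return mask


def otsu_threshold(values, bins: int = 256) -> float:
    """Otsu's threshold over a histogram of ``values``.

    Returns the bin edge maximizing the between-class variance, with ties
    broken toward the smallest threshold.  Foreground is ``value >
    threshold``.  Raises on constant input (no split exists).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or values.min() == values.max():
        raise ValueError("otsu_threshold requires >= 2 distinct values")
    counts, edges = np.histogram(values, bins=bins)
    # candidate thresholds are the interior bin edges; class 1 = bins <= t
    w = counts.astype(np.float64)
    total = w.sum()
    omega = np.cumsum(w)[:-1] / total
    centers = (edges[:-1] + edges[1:]) / 2
    mu_cum = np.cumsum(w * centers)[:-1] / total
    mu_total = (w * centers).sum() / total
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu_cum) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # ties (within fp tolerance of the maximum) break to the smallest threshold
    smax = sigma_b.max()
    best = int(np.flatnonzero(sigma_b >= smax - 1e-10 * abs(smax))[0])
    return float(edges[best + 1])


def segment_exg_otsu(rgb: np.ndarray) -> np.ndarray:
    """Excess-green + Otsu baseline: pixels with ExG above the Otsu
    threshold are green.  A constant-color image (no threshold exists)
    falls back to an all-background mask."""
    exg = exg_map(rgb)
    try:
        t = otsu_threshold(exg)
    except ValueError:
        return np.zeros(rgb.shape[:2], dtype=bool)
    return exg > t


exg_otsu_segmenter = SegmenterContract(name="exg-otsu", segment=segment_exg_otsu)


def run_external(adapter_cmd: list[str] | str, manifest: DatasetManifest,
                 out_dir, split: str | None = None) -> dict:
    """Run an external segmenter over the manifest's tiles.

    The adapter is any executable invoked as ``adapter_cmd <rgb.png>
    <mask_out.png>`` per image; it must write a binary (0/255) mask PNG
    of the same dimensions.  Malformed outputs and adapter failures are
    recorded per image and the run continues.

    Returns ``{"predictions": {tile_path: mask_path}, "errors":
    {tile_path: reason}}``.
    """
    if isinstance(adapter_cmd, str):
        adapter_cmd = [adapter_cmd]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = manifest.entries if split is None else manifest.subset(split)
    predictions: dict[str, str] = {}
    errors: dict[str, str] = {}
    for e in entries:
        tile = Path(e["tile"])
        pred_path = out / f"{tile.stem}_pred.png"
        try:
            proc = subprocess.run([*adapter_cmd, str(tile), str(pred_path)],
                                  capture_output=True, text=True)
        except OSError as exc:
            errors[str(tile)] = f"adapter launch failed: {exc}"
            continue
        if proc.returncode != 0:
            errors[str(tile)] = f"adapter exit {proc.returncode}: {proc.stderr.strip()[:200]}"
            continue
        if not pred_path.exists():
            errors[str(tile)] = "adapter wrote no output"
            continue
        pred = np.asarray(Image.open(pred_path).convert("L"))
        shape = np.asarray(Image.open(tile)).shape[:2]
        if pred.shape != shape:
            errors[str(tile)] = f"wrong dimensions {pred.shape} != {shape}"
            pred_path.unlink()
            continue
        if not set(np.unique(pred).tolist()) <= {0, 255}:
            errors[str(tile)] = "non-binary mask"
            pred_path.unlink()
            continue
        predictions[str(tile)] = str(pred_path)
    return {"predictions": predictions, "errors": errors}


def segment_manifest(segmenter: SegmenterContract, manifest: DatasetManifest,
                     out_dir, split: str | None = None) -> dict:
    """Run an in-process segmenter over manifest tiles, writing 0/255
    mask PNGs next to a provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = manifest.entries if split is None else manifest.subset(split)
    predictions = {}
    for e in entries:
        tile = Path(e["tile"])
        rgb = np.asarray(Image.open(tile).convert("RGB"))
        mask = segmenter(rgb)
        pred_path = out / f"{tile.stem}_pred.png"
        Image.fromarray(mask.astype(np.uint8) * 255).save(pred_path)
        predictions[str(tile)] = str(pred_path)
    return {"predictions": predictions, "errors": {}}
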