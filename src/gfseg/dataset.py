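"""Tiling, manifests/splits, and unpaired-folder export.

Rendered (or real) image/mask pairs are center-cropped to the largest
multiple of the tile size and cut into a non-overlapping grid of square
tiles (default 512).  Manifests record tile/mask path pairs with a
source-grouped train/val/test split, so all tiles of one source image
share a split and cannot leak across it.  ``export_unpaired`` writes the
``trainA/``/``trainB/`` folder layout that unpaired image-translation
tools (CycleGAN-style) consume.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Tile",
    "DatasetManifest",
    "tile_sample",
    "write_tiles",
    "build_manifest",
    "export_unpaired",
    "read_mask",
]

TILE_SIZE = 512


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; any nonzero value counts as green (with a
    warning when values other than 0/255 are present)."""
    arr = np.asarray(Image.open(path).convert("L"))
    vals = np.unique(arr)
    if not set(vals.tolist()) <= {0, 255}:
        warnings.warn(f"mask {path} contains values other than 0/255; treating nonzero as green")
    return arr > 0


@dataclass
class Tile:
    """One tile cut from a source image (and mask, when present)."""

    rgb: np.ndarray
    mask: np.ndarray | None
    source_id: str
    offset: tuple[int, int]  # (row, col) pixel origin within the center crop


def tile_sample(rgb: np.ndarray, mask: np.ndarray | None = None,
                tile_size: int = TILE_SIZE, source_id: str = "") -> list[Tile]:
    """Center-crop to the largest multiple of ``tile_size`` and cut a
    non-overlapping grid; the mask (if given) is tiled identically."""
    h, w = rgb.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than tile size {tile_size}")
    if mask is not None and mask.shape[:2] != (h, w):
        raise ValueError("mask dimensions must match the image")
    ch = (h // tile_size) * tile_size
    cw = (w // tile_size) * tile_size
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    tiles = []
    for r in range(0, ch, tile_size):
        for c in range(0, cw, tile_size):
            sub = rgb[r0 + r:r0 + r + tile_size, c0 + c:c0 + c + tile_size]
            msub = None
            if mask is not None:
                msub = mask[r0 + r:r0 + r + tile_size, c0 + c:c0 + c + tile_size]
            tiles.append(Tile(rgb=sub, mask=msub, source_id=source_id, offset=(r, c)))
    return tiles


def write_tiles(tiles: list[Tile], out_dir) -> list[dict]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for t in tiles:
        stem = f"{t.source_id}_r{t.offset[0]:05d}_c{t.offset[1]:05d}"
        rgb_path = out / f"{stem}_rgb.png"
        Image.fromarray(t.rgb).save(rgb_path)
        rec = {"tile": str(rgb_path), "mask": None, "source_id": t.source_id,
               "offset": list(t.offset)}
        if t.mask is not None:
            mask_path = out / f"{stem}_mask.png"
            Image.fromarray(t.mask.astype(np.uint8) * 255).save(mask_path)
            rec["mask"] = str(mask_path)
        records.append(rec)
    return records


@dataclass
class DatasetManifest:
    """Tile inventory with per-tile split assignment."""

    entries: list[dict] = field(default_factory=list)
    # each entry: tile, mask, source_id, crop, tag, split

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e["split"]] = out.get(e["split"], 0) + 1
        return out

    def subset(self, split: str) -> list[dict]:
        return [e for e in self.entries if e["split"] == split]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.entries, "counts": self.counts()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            return cls(entries=json.load(fh)["entries"])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["tile", "mask", "source_id", "crop", "tag", "split"])
            w.writeheader()
            for e in self.entries:
                w.writerow({k: e.get(k) for k in w.fieldnames})


def build_manifest(tile_dir, split_fractions=(0.8, 0.1, 0.1), seed: int = 0,
                   crop: str = "", tag: str = "") -> DatasetManifest:
    """Scan a directory of ``*_rgb.png``/``*_mask.png`` tile pairs and
    assign a seeded, source-grouped train/val/test split.

    All tiles sharing a source image id travel together, so no source
    straddles two splits.  RGB tiles without a mask partner are rejected.
    """
    fr = tuple(float(x) for x in split_fractions)
    if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError("split_fractions must be three non-negative numbers summing to 1")
    tile_dir = Path(tile_dir)
    rgbs = sorted(tile_dir.glob("*_rgb.png"))
    if not rgbs:
        raise ValueError(f"no '*_rgb.png' tiles found in {tile_dir}")
    pairs = []
    unpaired = []
    for p in rgbs:
        m = p.with_name(p.name.replace("_rgb.png", "_mask.png"))
        if m.exists():
            pairs.append((p, m))
        else:
            unpaired.append(str(p))
    if unpaired:
        raise ValueError(f"unpaired tiles (no mask): {unpaired}")

    def source_of(p: Path) -> str:
        stem = p.name[: -len("_rgb.png")]
        parts = stem.rsplit("_", 2)
        if len(parts) == 3 and parts[1].startswith("r") and parts[2].startswith("c"):
            return parts[0]
        return stem

    sources = sorted({source_of(p) for p, _ in pairs})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sources))
    n = len(sources)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    n_val = min(n_val, n - n_train)
    assign = {}
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
        assign[sources[idx]] = split

    entries = [
        {"tile": str(p), "mask": str(m), "source_id": source_of(p),
         "crop": crop, "tag": tag, "split": assign[source_of(p)]}
        for p, m in pairs
    ]
    return DatasetManifest(entries=entries)


def export_unpaired(manifest_a: DatasetManifest, manifest_b: DatasetManifest,
                    out_dir, n_each: int, seed: int = 0, force: bool = False) -> dict:
    """Write ``trainA/`` and ``trainB/`` folders of ``n_each`` RGB tiles
    each (no masks): the standard unpaired-translation dataset layout."""
    if not manifest_a.entries or not manifest_b.entries:
        raise ValueError("both manifests must be non-empty")
    if n_each < 0:
        raise ValueError("n_each must be >= 0")
    if n_each > len(manifest_a.entries) or n_each > len(manifest_b.entries):
        raise ValueError(
            f"n_each={n_each} exceeds availability "
            f"({len(manifest_a.entries)} / {len(manifest_b.entries)})")
    out = Path(out_dir)
    for sub in ("trainA", "trainB"):
        d = out / sub
        if d.exists() and any(d.iterdir()) and not force:
            raise FileExistsError(f"{d} already contains files (use force=True to overwrite)")
    rng = np.random.default_rng(seed)
    written = {}
    for sub, manifest in (("trainA", manifest_a), ("trainB", manifest_b)):
        d = out / sub
        d.mkdir(parents=True, exist_ok=True)
        idx = rng.choice(len(manifest.entries), size=n_each, replace=False)
        files = []
        for k, i in enumerate(sorted(idx.tolist())):
            src = Path(manifest.entries[i]["tile"])
            dst = d / f"{k:05d}.png"
            Image.open(src).convert("RGB").save(dst)
            files.append(str(dst))
        written[sub] = files
    return written
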