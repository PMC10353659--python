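"""Segmentation metrics at pixel and image scale.

Pixel scale: confusion proportions (TP/TN/FP/FN, green vegetation as the
positive class), Accuracy = TP+TN and F1 = 2TP/(2TP+FP+FN), plus a
normalized Euclidean distance between images used to quantify the
sim-to-real domain gap.  Image scale: green fraction GF (green pixels /
total pixels), R² and RMSE of predicted vs reference GF, and GF time
series.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "GFSeries",
    "confusion_counts",
    "pool_confusion",
    "pixel_metrics",
    "green_fraction",
    "regression_metrics",
    "euclidean_image_distance",
    "domain_gap",
    "gf_series",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN as proportions of all evaluated pixels."""

    tp: float
    tn: float
    fp: float
    fn: float
    n_pixels: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.tp + self.tn + self.fp + self.fn - 1.0) > 1e-9:
            raise ValueError("confusion proportions must sum to 1")


@dataclass(frozen=True)
class MetricsReport:
    confusion: ConfusionCounts
    accuracy: float
    f1: float
    n_pixels: int
    tag: str = ""


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"dimension mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Per-pixel confusion proportions for one prediction/truth pair."""
    pred, truth = _check_binary_pair(pred, truth)
    n = pred.size
    if n == 0:
        raise ValueError("empty masks")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = n - tp - tn - fp
    return ConfusionCounts(tp / n, tn / n, fp / n, fn / n, n_pixels=n)


def pool_confusion(counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Pixel-weighted pooling of per-image confusion proportions."""
    if not counts:
        raise ValueError("nothing to pool")
    total = sum(c.n_pixels for c in counts)
    if total == 0:
        raise ValueError("pooled counts need n_pixels set")
    agg = {k: sum(getattr(c, k) * c.n_pixels for c in counts) / total
           for k in ("tp", "tn", "fp", "fn")}
    return ConfusionCounts(n_pixels=total, **agg)


def pixel_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(Accuracy, F1) from confusion proportions; F1 defined as 0 when
    its denominator vanishes (no green anywhere)."""
    accuracy = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom > 0 else 0.0
    return accuracy, f1


def report(pred, truth, tag: str = "") -> MetricsReport:
    c = confusion_counts(pred, truth)
    acc, f1 = pixel_metrics(c)
    return MetricsReport(confusion=c, accuracy=acc, f1=f1, n_pixels=c.n_pixels, tag=tag)


def green_fraction(mask) -> float:
    """Green pixels divided by total pixels."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return int(np.count_nonzero(mask)) / mask.size


def regression_metrics(predicted, reference) -> tuple[float | None, float]:
    """(R², RMSE) of predicted vs reference values.

    R² is the coefficient of determination 1 - SS_res/SS_tot; it is
    undefined (None) for a constant reference.
    """
    f = np.asarray(predicted, dtype=float)
    y = np.asarray(reference, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D vectors")
    if f.size < 2:
        raise ValueError("need at least 2 points")
    rmse = float(np.sqrt(np.mean((f - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return None, rmse
    r2 = 1.0 - float(np.sum((f - y) ** 2)) / ss_tot
    return r2, rmse


def euclidean_image_distance(img_x, img_y) -> float:
    """Normalized Euclidean distance between two images.

    sqrt(mean(((x - y)/255)^2)) over all digital numbers (all channels):
    0 for identical images, 1 for all-black vs all-white.
    """
    x = np.asarray(img_x, dtype=np.float64)
    y = np.asarray(img_y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d = (x - y) / 255.0
    return float(np.sqrt(np.mean(d * d)))


def _set_digest(images) -> bytes:
    h = hashlib.sha1()
    for im in images:
        a = np.ascontiguousarray(np.asarray(im, dtype=np.uint8))
        h.update(str(a.shape).encode())
        h.update(a.tobytes()[:4096])
    return h.digest()


def domain_gap(set_a, set_b, n_pairs: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Mean normalized Euclidean distance over seeded random cross-set
    pairs; returns (mean, standard error).

    The pairing is made independent of argument order (the two index
    streams are assigned by a content hash of each set), so
    ``domain_gap(A, B)`` equals ``domain_gap(B, A)`` for the same seed.
    """
    set_a = list(set_a)
    set_b = list(set_b)
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    shape = np.asarray(set_a[0]).shape
    for im in (*set_a, *set_b):
        if np.asarray(im).shape != shape:
            raise ValueError("all images must share dimensions")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    swapped = _set_digest(set_a) > _set_digest(set_b)
    first, second = (set_b, set_a) if swapped else (set_a, set_b)
    ss = np.random.SeedSequence(seed).spawn(2)
    ia = np.random.default_rng(ss[0]).integers(0, len(first), n_pairs)
    ib = np.random.default_rng(ss[1]).integers(0, len(second), n_pairs)
    d = np.array([euclidean_image_distance(first[i], second[j]) for i, j in zip(ia, ib)])
    sem = float(d.std(ddof=1) / np.sqrt(n_pairs)) if n_pairs > 1 else 0.0
    return float(d.mean()), sem


@dataclass
class GFSeries:
    """Ordered (timestamp, GF) pairs with source ids."""

    timestamps: list
    gf: list[float]
    source_ids: list

    def __post_init__(self) -> None:
        if any(not 0 <= g <= 1 for g in self.gf):
            raise ValueError("GF values must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")


def gf_series(samples) -> GFSeries:
    """Green-fraction time series from (timestamp, mask[, source_id])
    tuples; sorted by timestamp, duplicate timestamps averaged."""
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    buckets: dict = {}
    for item in samples:
        ts, mask = item[0], item[1]
        sid = item[2] if len(item) > 2 else ""
        buckets.setdefault(ts, []).append((green_fraction(mask), sid))
    ts_sorted = sorted(buckets)
    gf = [float(np.mean([g for g, _ in buckets[t]])) for t in ts_sorted]
    sids = [";".join(s for _, s in buckets[t] if s) for t in ts_sorted]
    return GFSeries(timestamps=ts_sorted, gf=gf, source_ids=sids)
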