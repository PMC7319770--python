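"""2D confocal synaptosome colocalization analysis.

Single optical sections carry three channels: the active-zone marker Bassoon,
the vesicle Ca²⁺ sensor Synaptotagmin-1 (Syt1), and the dopamine-axon marker
TH. Each channel is background-subtracted (rolling-ball, radius 1 µm),
thresholded with Otsu, and segmented into puncta retained by size
(0.2-1 µm², inclusive) and shape (bounding-box x:y extent ratio < 1.5,
larger over smaller). Bassoon and TH puncta are then assigned to mutually
exclusive categories (Bassoon+TH+, Bassoon-TH+, Bassoon+TH-) by pixel
overlap, and each category object is called Synaptotagmin-1 positive when
Syt1 pixels cover 20-100% of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "PunctaImage",
    "Punctum",
    "PunctumSet",
    "CategoryTable",
    "rolling_ball_background",
    "detect_puncta",
    "categorize_objects",
    "analyze_image",
]

SIZE_BOUNDS_UM2 = (0.2, 1.0)
SHAPE_RATIO_MAX = 1.5
SYT1_OVERLAP_RANGE = (0.20, 1.0)
CO_OVERLAP_MIN = 0.20
ROLLING_BALL_RADIUS_UM = 1.0

CATEGORIES = ("Bassoon+TH+", "Bassoon-TH+", "Bassoon+TH-")


@dataclass(frozen=True)
class PunctaImage:
    """Three-channel 2D image (Bassoon, Syt1, TH) with square pixels."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channels must share a shape")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} missing; available: {sorted(self.channels)}")
        return self.channels[name]


@dataclass(frozen=True)
class Punctum:
    label: int
    pixels: np.ndarray  # (n, 2) int indices (y, x)
    area_um2: float
    bbox_extent_px: tuple[int, int]  # (y extent, x extent)


@dataclass(frozen=True)
class PunctumSet:
    objects: tuple[Punctum, ...]
    source_channel: str
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.objects)


@dataclass(frozen=True)
class CategoryTable:
    """Per-object categories and Syt1 positivity, with per-category summaries."""

    table: pd.DataFrame  # columns: category, syt1_positive, area_um2, source
    counts: dict[str, int]
    positive_fractions: dict[str, float | None]  # None when a category is empty


def rolling_ball_background(
    channel: np.ndarray, pixel_size_um: float, radius_um: float = ROLLING_BALL_RADIUS_UM
) -> np.ndarray:
    """Background subtraction by grayscale opening with a disk of the given radius.

    An approximation of the classical rolling-ball estimator: the opening
    removes structures narrower than the disk, and the remainder (clipped at
    zero) keeps puncta while flattening smooth background.
    """
    radius_px = radius_um / pixel_size_um
    if radius_px < 1:
        raise ValueError("rolling-ball radius smaller than one pixel")
    footprint = disk(int(round(radius_px)))
    background = ndimage.grey_opening(channel, footprint=footprint)
    return np.clip(channel - background, 0, None)


def detect_puncta(
    channel: np.ndarray,
    pixel_size_um: float,
    size_bounds_um2: tuple[float, float] = SIZE_BOUNDS_UM2,
    shape_ratio_max: float = SHAPE_RATIO_MAX,
    source_channel: str = "",
) -> PunctumSet:
    """Otsu threshold, 8-connected labeling, size and shape filters.

    Retains objects with area in ``size_bounds_um2`` (inclusive) and
    bounding-box extent ratio max(x, y)/min(x, y) strictly below
    ``shape_ratio_max``.
    """
    channel = np.asarray(channel)
    if np.unique(channel).size < 2:
        raise ValueError("constant channel: nothing to detect")
    thr = threshold_otsu(channel, nbins=256)
    mask = channel > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    px_area = pixel_size_um**2
    objects = []
    all_idx = np.argwhere(labels > 0)
    lab_of = labels[tuple(all_idx.T)]
    order = np.argsort(lab_of, kind="stable")
    all_idx = all_idx[order]
    splits = np.searchsorted(lab_of[order], np.arange(2, n + 1))
    for lab, pix in zip(range(1, n + 1), np.split(all_idx, splits)):
        area = len(pix) * px_area
        ext_y = int(pix[:, 0].max() - pix[:, 0].min() + 1)
        ext_x = int(pix[:, 1].max() - pix[:, 1].min() + 1)
        ratio = max(ext_x, ext_y) / min(ext_x, ext_y)
        if size_bounds_um2[0] <= area <= size_bounds_um2[1] and ratio < shape_ratio_max:
            objects.append(Punctum(lab, pix, area, (ext_y, ext_x)))
    return PunctumSet(tuple(objects), source_channel, pixel_size_um)


def _pixel_set(p: Punctum) -> set[tuple[int, int]]:
    return set(map(tuple, p.pixels))


def categorize_objects(
    bassoon: PunctumSet,
    th: PunctumSet,
    syt1: PunctumSet,
    co_overlap_min: float = CO_OVERLAP_MIN,
    syt1_overlap_range: tuple[float, float] = SYT1_OVERLAP_RANGE,
) -> CategoryTable:
    """Assign Bassoon/TH categories and Synaptotagmin-1 positivity.

    Bassoon/TH co-positivity: a Bassoon and a TH punctum are matched when
    their pixel overlap, as a fraction of the smaller object, is at least
    ``co_overlap_min``. Matched pairs form one Bassoon+TH+ object (the pixel
    union); unmatched TH puncta are Bassoon-TH+ and unmatched Bassoon puncta
    Bassoon+TH-, so the categories partition the union of filtered objects.

    Syt1 positivity: the fraction of the category object's pixels covered by
    Syt1 puncta must fall within ``syt1_overlap_range`` (default 20-100%).
    """
    syt1_pixels: set[tuple[int, int]] = set()
    for p in syt1.objects:
        syt1_pixels.update(map(tuple, p.pixels))

    th_sets = [_pixel_set(p) for p in th.objects]
    b_sets = [_pixel_set(p) for p in bassoon.objects]

    matched_th: set[int] = set()
    matched_b: set[int] = set()
    entries: list[tuple[str, set[tuple[int, int]], float]] = []
    px_area = th.pixel_size_um**2

    for bi, bset in enumerate(b_sets):
        best_j, best_frac = None, 0.0
        for tj, tset in enumerate(th_sets):
            if tj in matched_th:
                continue
            inter = len(bset & tset)
            if inter == 0:
                continue
            frac = inter / min(len(bset), len(tset))
            if frac > best_frac:
                best_j, best_frac = tj, frac
        if best_j is not None and best_frac >= co_overlap_min:
            matched_b.add(bi)
            matched_th.add(best_j)
            union = bset | th_sets[best_j]
            entries.append(("Bassoon+TH+", union, len(union) * px_area))
    for tj, tset in enumerate(th_sets):
        if tj not in matched_th:
            entries.append(("Bassoon-TH+", tset, len(tset) * px_area))
    for bi, bset in enumerate(b_sets):
        if bi not in matched_b:
            entries.append(("Bassoon+TH-", bset, len(bset) * px_area))

    lo, hi = syt1_overlap_range
    rows = []
    for cat, pixels, area in entries:
        cover = len(pixels & syt1_pixels) / len(pixels) if pixels else 0.0
        rows.append({
            "category": cat,
            "syt1_positive": bool(lo <= cover <= hi),
            "syt1_overlap": cover,
            "area_um2": area,
        })
    table = pd.DataFrame(rows, columns=["category", "syt1_positive", "syt1_overlap", "area_um2"])
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    fractions: dict[str, float | None] = {}
    for c in CATEGORIES:
        sub = table[table["category"] == c]
        fractions[c] = float(sub["syt1_positive"].mean()) if len(sub) else None
    return CategoryTable(table=table, counts=counts, positive_fractions=fractions)


def analyze_image(
    image: PunctaImage,
    rolling_ball_radius_um: float = ROLLING_BALL_RADIUS_UM,
    co_overlap_min: float = CO_OVERLAP_MIN,
) -> CategoryTable:
    """Full pipeline on a three-channel image: subtract, detect, categorize."""
    sets = {}
    for name in ("bassoon", "syt1", "th"):
        sub = rolling_ball_background(
            image.channel(name).astype(float), image.pixel_size_um, rolling_ball_radius_um
        )
        sets[name] = detect_puncta(sub, image.pixel_size_um, source_channel=name)
    return categorize_objects(sets["bassoon"], sets["th"], sets["syt1"],
                              co_overlap_min=co_overlap_min)
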