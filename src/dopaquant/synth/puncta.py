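"""Synthetic synaptosome punctum fields with controlled colocalization.

Round puncta are placed without overlap in a 2D field, in three mutually
exclusive categories: Bassoon+TH+ (the same punctum appears in both the
Bassoon and TH channels), Bassoon-TH+ (TH only) and Bassoon+TH- (Bassoon
only). Within each category a configurable fraction of objects is rendered
Synaptotagmin-1-positive by adding a co-centered punctum to the Syt1 channel
(covering the object fully, i.e. a 100% overlap, which satisfies any
criterion within the 20-100% band); negative objects receive no Syt1 signal.
A per-object truth table records category, area and the planted Syt1 label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .._rng import substream
from ..synaptosomes import PunctaImage

__all__ = ["PunctaFieldSpec", "generate_puncta_field"]

CATEGORIES = ("Bassoon+TH+", "Bassoon-TH+", "Bassoon+TH-")


@dataclass(frozen=True)
class PunctaFieldSpec:
    """Parameters of a synthetic three-channel punctum field."""

    image_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    n_objects: dict[str, int] | None = None  # per category; default 100 each
    punctum_area_range_um2: tuple[float, float] = (0.3, 0.9)
    syt1_positive_fraction: dict[str, float] | None = None  # default 0.5 each
    psf_sigma_um: float = 0.0
    noise_sd: float = 0.0  # relative to punctum amplitude 1
    max_placement_tries: int = 2000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.punctum_area_range_um2
        if not 0 < lo <= hi:
            raise ValueError("punctum area range must be ordered and positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        counts = self.counts
        if any(v < 0 for v in counts.values()):
            raise ValueError("object counts must be non-negative")
        fracs = self.fractions
        if any(not 0 <= f <= 1 for f in fracs.values()):
            raise ValueError("syt1 fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def counts(self) -> dict[str, int]:
        base = {c: 100 for c in CATEGORIES}
        if self.n_objects:
            base.update(self.n_objects)
        return base

    @property
    def fractions(self) -> dict[str, float]:
        base = {c: 0.5 for c in CATEGORIES}
        if self.syt1_positive_fraction:
            base.update(self.syt1_positive_fraction)
        return base


def _disk_pixels(center: np.ndarray, radius_px: float, shape) -> np.ndarray | None:
    lo = np.floor(center - radius_px).astype(int)
    hi = np.ceil(center + radius_px).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > shape):
        return None
    yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    return np.stack([yy[inside], xx[inside]], axis=1)


def generate_puncta_field(spec: PunctaFieldSpec) -> tuple[PunctaImage, pd.DataFrame]:
    """Render the field and return (image, per-object truth table).

    Truth table columns: object_id, category, syt1_positive, area_um2,
    center_y_px, center_x_px. Placement enforces zero overlap between
    distinct objects (min center separation of two max radii plus one pixel);
    a field too crowded to place raises ValueError.
    """
    rng = substream(spec.seed, "synth.puncta")
    shape = tuple(spec.image_shape_px)
    px_area = spec.pixel_size_um**2
    chans = {n: np.zeros(shape, dtype=float) for n in ("bassoon", "syt1", "th")}

    r_max_px = math.sqrt(spec.punctum_area_range_um2[1] / math.pi) / spec.pixel_size_um
    min_sep = 2 * r_max_px + 1.0
    centers: list[np.ndarray] = []
    rows = []
    oid = 0
    for cat in CATEGORIES:
        n = spec.counts[cat]
        frac = spec.fractions[cat]
        for i in range(n):
            area = rng.uniform(*spec.punctum_area_range_um2)
            radius_px = math.sqrt(area / math.pi) / spec.pixel_size_um
            for _try in range(spec.max_placement_tries):
                c = rng.uniform(r_max_px + 1, np.array(shape) - r_max_px - 1)
                if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                    break
            else:
                raise ValueError(
                    "cannot place the requested object count without overlap; "
                    "reduce counts or enlarge the field"
                )
            pix = _disk_pixels(c, radius_px, shape)
            if pix is None or len(pix) == 0:
                raise ValueError("punctum does not fit in the field")
            centers.append(c)
            target = []
            if "Bassoon+" in cat:
                target.append("bassoon")
            if "TH+" in cat:
                target.append("th")
            for ch in target:
                chans[ch][pix[:, 0], pix[:, 1]] = 1.0
            syt1_pos = bool(rng.random() < frac)  # Bernoulli label per object
            if syt1_pos:
                chans["syt1"][pix[:, 0], pix[:, 1]] = 1.0
            rows.append({
                "object_id": oid,
                "category": cat,
                "syt1_positive": bool(syt1_pos),
                "area_um2": len(pix) * px_area,
                "center_y_px": float(c[0]),
                "center_x_px": float(c[1]),
            })
            oid += 1

    if spec.psf_sigma_um > 0:
        sigma_px = spec.psf_sigma_um / spec.pixel_size_um
        for name in chans:
            chans[name] = ndimage.gaussian_filter(chans[name], sigma_px)
    if spec.noise_sd > 0:
        for name in chans:
            chans[name] = chans[name] + rng.normal(0.0, spec.noise_sd, shape)

    truth = pd.DataFrame(rows, columns=[
        "object_id", "category", "syt1_positive", "area_um2",
        "center_y_px", "center_x_px",
    ])
    image = PunctaImage(channels=chans, pixel_size_um=spec.pixel_size_um)
    return image, truth
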