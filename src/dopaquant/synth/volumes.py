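"""Synthetic two-channel 3D volumes of dopamine axons and release-site clusters.

The scene model: axons are tubes of fixed radius around random-walk
centerlines (fixed step length, Gaussian angular jitter per step); clusters
are ellipsoids placed either on axon centerlines (Poisson along arclength) or
in the non-axon complement (Poisson per unit volume, whole ellipsoid outside
the axon mask). The rendered binary scene is then degraded by a Gaussian PSF
and additive Gaussian read noise — the ground truth always describes the
pre-degradation scene.

Defaults emulate reconstructed 3D-SIM volumes of striatum: 0.125 µm z step,
0.04 µm lateral voxels, 0.25 µm axon radius, clusters of 0.003-0.04 µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .._rng import substream
from ..sim3d import ImageVolume

__all__ = [
    "VolumeSpec",
    "VolumeTruth",
    "ClusterTruth",
    "generate_volume",
    "render_scene",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Parameters of a synthetic axon/cluster volume.

    Physical sizes in µm; voxel order (z, y, x).
    """

    shape_voxels: tuple[int, int, int] = (48, 128, 128)
    voxel_size_um: tuple[float, float, float] = (0.125, 0.04, 0.04)
    n_axons: int = 2
    axon_radius_um: float = 0.25
    axon_step_um: float = 0.5
    axon_bend_sd_rad: float = 0.15
    cluster_rate_inside: float = 1.0  # expected clusters per µm of axon
    cluster_rate_outside: float = 0.05  # expected clusters per µm³ of non-axon volume
    cluster_volume_range_um3: tuple[float, float] = (0.005, 0.03)
    cluster_volume_range_outside_um3: tuple[float, float] | None = None
    psf_sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0  # relative to signal peak (foreground = 1)
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.shape_voxels):
            raise ValueError("shape_voxels must each be >= 8")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.axon_radius_um <= 0 or self.axon_step_um <= 0:
            raise ValueError("axon radius and step must be positive")
        lo, hi = self.cluster_volume_range_um3
        if not 0 < lo <= hi:
            raise ValueError("cluster volume range must be ordered and positive")
        if self.cluster_volume_range_outside_um3 is not None:
            lo2, hi2 = self.cluster_volume_range_outside_um3
            if not 0 < lo2 <= hi2:
                raise ValueError("outside cluster volume range must be ordered and positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_axons > 0:
            if any(self.axon_radius_um < v for v in self.voxel_size_um):
                raise ValueError(
                    "axon radius smaller than one voxel in some axis is unresolvable"
                )
            extent = [s * v for s, v in zip(self.shape_voxels, self.voxel_size_um)]
            if self.axon_step_um > max(extent):
                raise ValueError("volume too small to contain one axon step")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape_voxels, self.voxel_size_um))

    @property
    def outside_range(self) -> tuple[float, float]:
        return self.cluster_volume_range_outside_um3 or self.cluster_volume_range_um3


@dataclass(frozen=True)
class ClusterTruth:
    centroid_um: tuple[float, float, float]
    volume_um3: float  # rendered (voxelized) volume — what a pipeline can recover
    requested_volume_um3: float
    inside_axon: bool


@dataclass(frozen=True)
class VolumeTruth:
    """Pre-degradation scene description (invariant to PSF and noise)."""

    axon_centerlines: tuple[np.ndarray, ...]  # each (n, 3) in µm, (z, y, x)
    true_axon_length_um: float
    true_axon_mask: np.ndarray = field(repr=False)
    true_th_volume_fraction: float
    clusters: tuple[ClusterTruth, ...]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _render_tube(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                 radius: float, voxel: np.ndarray) -> None:
    """Mark voxels within ``radius`` of segment p0-p1 (physical distance)."""
    lo_um = np.minimum(p0, p1) - radius
    hi_um = np.maximum(p0, p1) + radius
    lo = np.maximum(np.floor(lo_um / voxel).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / voxel).astype(int) + 1, mask.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[(np.arange(l, h) + 0.5) * v for l, h, v in zip(lo, hi, voxel)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    mask[sub] |= dist <= radius


def _render_ellipsoid(mask: np.ndarray, center_um: np.ndarray,
                      semi_axes_um: np.ndarray, voxel: np.ndarray) -> int:
    """Mark an axis-aligned ellipsoid; returns the number of voxels set."""
    lo = np.maximum(np.floor((center_um - semi_axes_um) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + semi_axes_um) / voxel).astype(int) + 1, mask.shape)
    if np.any(hi <= lo):
        return 0
    grids = np.meshgrid(
        *[(np.arange(l, h) + 0.5) * v for l, h, v in zip(lo, hi, voxel)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    r = np.sum(((pts - center_um) / semi_axes_um) ** 2, axis=-1)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    inside = r <= 1.0
    newly = inside & ~mask[sub]
    mask[sub] |= inside
    return int(newly.sum())


def _ellipsoid_semi_axes(volume_um3: float, rng: np.random.Generator) -> np.ndarray:
    """Random mildly anisotropic semi-axes with the requested analytic volume."""
    ratios = rng.uniform(0.75, 1.3, size=3)
    base = (3.0 * volume_um3 / (4.0 * math.pi * float(np.prod(ratios)))) ** (1.0 / 3.0)
    return base * ratios


def _random_walk_centerline(
    spec: VolumeSpec, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-step random walk, clipped at the volume boundary."""
    extent = np.array(spec.extent_um)
    margin = spec.axon_radius_um
    start = rng.uniform(margin, extent - margin)
    # uniform direction on the sphere
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    max_steps = int(4 * max(extent) / spec.axon_step_um) + 2
    for _ in range(max_steps):
        if spec.axon_bend_sd_rad > 0:
            d = d + rng.normal(0.0, spec.axon_bend_sd_rad, size=3)
            d /= np.linalg.norm(d)
        nxt = pts[-1] + d * spec.axon_step_um
        if np.any(nxt < 0) or np.any(nxt > extent):
            # clip the final segment at the boundary and stop
            prev = pts[-1]
            ts = []
            for ax in range(3):
                if nxt[ax] < 0:
                    ts.append((0 - prev[ax]) / (nxt[ax] - prev[ax]))
                elif nxt[ax] > extent[ax]:
                    ts.append((extent[ax] - prev[ax]) / (nxt[ax] - prev[ax]))
            t = min(ts)
            if t > 1e-9:
                pts.append(prev + t * (nxt - prev))
            break
        pts.append(nxt)
    return np.array(pts)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------


def render_scene(
    centerlines: Sequence[np.ndarray],
    spec: VolumeSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, VolumeTruth]:
    """Render axon tubes around given centerlines, place and render clusters.

    Entry point for controlled geometries (straight or L-shaped tubes in
    tests); :func:`generate_volume` draws the centerlines first and delegates
    here. ``rng`` drives cluster placement; None disables random clusters.
    """
    voxel = np.array(spec.voxel_size_um)
    shape = tuple(spec.shape_voxels)
    axon_mask = np.zeros(shape, dtype=bool)
    for line in centerlines:
        line = np.asarray(line, dtype=float)
        if line.ndim != 2 or line.shape[1] != 3:
            raise ValueError("each centerline must be an (n, 3) array in µm")
        if len(line) == 1:
            _render_tube(axon_mask, line[0], line[0], spec.axon_radius_um, voxel)
        for p0, p1 in zip(line[:-1], line[1:]):
            _render_tube(axon_mask, p0, p1, spec.axon_radius_um, voxel)

    total_length = float(sum(_polyline_length(np.asarray(l)) for l in centerlines))
    cluster_mask = np.zeros(shape, dtype=bool)
    clusters: list[ClusterTruth] = []

    if rng is not None:
        clusters = _place_clusters(spec, centerlines, axon_mask, cluster_mask, rng)

    voxel_vol = float(np.prod(voxel))
    truth = VolumeTruth(
        axon_centerlines=tuple(np.asarray(l, dtype=float) for l in centerlines),
        true_axon_length_um=total_length,
        true_axon_mask=axon_mask,
        true_th_volume_fraction=float(axon_mask.mean()),
        clusters=tuple(clusters),
    )

    axon_img = axon_mask.astype(float)
    cluster_img = cluster_mask.astype(float)
    if any(s > 0 for s in spec.psf_sigma_um):
        sigma_vox = tuple(s / v for s, v in zip(spec.psf_sigma_um, spec.voxel_size_um))
        axon_img = ndimage.gaussian_filter(axon_img, sigma_vox)
        cluster_img = ndimage.gaussian_filter(cluster_img, sigma_vox)
    if spec.noise_sd > 0:
        noise_rng = substream(spec.seed, "synth.volume.noise")
        axon_img = axon_img + noise_rng.normal(0.0, spec.noise_sd, shape)
        cluster_img = cluster_img + noise_rng.normal(0.0, spec.noise_sd, shape)

    vol = ImageVolume(
        channels={"axon": axon_img, "cluster": cluster_img},
        voxel_size_um=tuple(spec.voxel_size_um),
    )
    return vol, truth


def _sample_on_polylines(
    centerlines: Sequence[np.ndarray], arclength: float
) -> np.ndarray:
    """Point at a given cumulative arclength along the concatenated centerlines."""
    remaining = arclength
    for line in centerlines:
        line = np.asarray(line, dtype=float)
        for p0, p1 in zip(line[:-1], line[1:]):
            seg = float(np.linalg.norm(p1 - p0))
            if remaining <= seg:
                return p0 + (remaining / seg) * (p1 - p0) if seg > 0 else p0
            remaining -= seg
    return np.asarray(centerlines[-1], dtype=float)[-1]


def _place_clusters(spec, centerlines, axon_mask, cluster_mask, rng):
    voxel = np.array(spec.voxel_size_um)
    voxel_vol = float(np.prod(voxel))
    extent = np.array(spec.extent_um)
    clusters: list[ClusterTruth] = []
    vmax = max(spec.cluster_volume_range_um3[1], spec.outside_range[1])
    # centers at least two max radii apart -> rendered clusters cannot merge
    min_sep_um = 2.0 * 1.3 * (3 * vmax / (4 * math.pi)) ** (1 / 3)
    placed_centers: list[np.ndarray] = []

    def far_enough(c):
        return all(np.linalg.norm(c - p) > min_sep_um for p in placed_centers)

    # inside clusters: Poisson along axon arclength, centered on the centerline.
    # The Poisson count is always honored; the separation constraint is
    # best-effort (relaxed when the axon is too crowded), so cluster counts
    # stay unbiased while merges remain rare at realistic rates.
    total_length = float(sum(_polyline_length(np.asarray(l)) for l in centerlines))
    n_inside = rng.poisson(spec.cluster_rate_inside * total_length) if total_length > 0 else 0
    for _ in range(n_inside):
        center = None
        for _attempt in range(200):
            s = rng.uniform(0.0, total_length)
            candidate = _sample_on_polylines(centerlines, s)
            center = candidate
            if far_enough(candidate):
                break
        vol_req = rng.uniform(*spec.cluster_volume_range_um3)
        axes = _ellipsoid_semi_axes(vol_req, rng)
        n_vox = _render_ellipsoid(cluster_mask, center, axes, voxel)
        placed_centers.append(center)
        clusters.append(ClusterTruth(tuple(center), n_vox * voxel_vol, vol_req, True))

    # outside clusters: Poisson in the complement volume; positions are
    # redrawn (not dropped) until the whole ellipsoid avoids the axon, which
    # realizes a Poisson process restricted to the complement by thinning.
    complement_um3 = float((~axon_mask).sum()) * voxel_vol
    n_outside = rng.poisson(spec.cluster_rate_outside * complement_um3)
    for _ in range(n_outside):
        vol_req = rng.uniform(*spec.outside_range)
        axes = _ellipsoid_semi_axes(vol_req, rng)
        chosen = None
        for _attempt in range(2000):
            center = rng.uniform(0.0, extent)
            probe = np.zeros(axon_mask.shape, dtype=bool)
            n_vox = _render_ellipsoid(probe, center, axes, voxel)
            if n_vox == 0 or (probe & axon_mask).any():
                continue
            if _attempt < 500 and (not far_enough(center) or (probe & cluster_mask).any()):
                continue  # prefer well-separated placements while room remains
            chosen = (center, probe, n_vox)
            break
        if chosen is None:
            continue  # complement genuinely too small for this ellipsoid
        center, probe, n_vox = chosen
        cluster_mask |= probe
        placed_centers.append(center)
        clusters.append(ClusterTruth(tuple(center), n_vox * voxel_vol, vol_req, False))
    return clusters


def generate_volume(spec: VolumeSpec) -> tuple[ImageVolume, VolumeTruth]:
    """Draw random-walk axon centerlines, then render the full scene.

    Deterministic for a fixed seed; the returned truth describes the scene
    before PSF blur and noise are applied.
    """
    rng = substream(spec.seed, "synth.volume")
    centerlines = [_random_walk_centerline(spec, rng) for _ in range(spec.n_axons)]
    centerlines = [l for l in centerlines if len(l) >= 2]
    return render_scene(centerlines, spec, rng)
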