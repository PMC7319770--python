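"""File I/O, run configuration, and reporting.

Volumes and punctum images travel as multichannel TIFF with physical
voxel/pixel size and channel names in the image-description metadata (OME-TIFF
is accepted on read); traces as two-column CSV (``time_s,value``) with units
in a JSON sidecar; metrics as tidy CSV plus a JSON run record that echoes the
seed and every parameter, so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .sim3d import ImageVolume
from .synaptosomes import PunctaImage
from .traces import Trace

__all__ = [
    "RunConfig",
    "MetricsTable",
    "read_volume",
    "write_volume",
    "read_trace",
    "write_trace",
    "read_puncta_image",
    "write_puncta_image",
    "write_report",
]

VERSION = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one analysis or simulation stage."""

    stage: str
    seed: int
    parameters: dict = field(default_factory=dict)
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    version: str = VERSION

    def to_json(self) -> str:
        payload = {
            "stage": self.stage,
            "seed": self.seed,
            "parameters": self.parameters,
            "inputs": list(self.inputs),
            "outputs": list(self.outputs),
            "version": self.version,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class MetricsTable:
    """Tidy metric rows keyed by (run_id, item_id, metric); units required."""

    rows: list[dict] = field(default_factory=list)

    def add(self, run_id: str, item_id: str, metric: str, value, units: str) -> None:
        if not units:
            raise ValueError(f"metric {metric!r} needs non-empty units "
                             "(use 'dimensionless' for pure numbers)")
        key = (run_id, item_id, metric)
        if any((r["run_id"], r["item_id"], r["metric"]) == key for r in self.rows):
            raise ValueError(f"duplicate metric key {key}")
        self.rows.append({
            "run_id": run_id, "item_id": item_id, "metric": metric,
            "value": value, "units": units,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["run_id", "item_id", "metric", "value", "units"]
        )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def write_volume(path: str | Path, volume: ImageVolume, sidecar: dict | None = None) -> None:
    """Write a multichannel volume as TIFF (+ optional JSON sidecar).

    Channel order in the file follows sorted channel names; voxel size and
    channel names go into the image-description metadata. Plain (non-OME)
    TIFF is written so that repeated runs are byte-identical — the OME writer
    embeds a fresh UUID per file. :func:`read_volume` accepts both.
    """
    path = Path(path)
    names = sorted(volume.channels)
    stack = np.stack([np.asarray(volume.channels[n], dtype=np.float32) for n in names])
    vz, vy, vx = volume.voxel_size_um
    tifffile.imwrite(
        path,
        stack,
        ome=False,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "ChannelNames": names,
        },
    )
    if sidecar is not None:
        side = dict(sidecar)
        side.setdefault("channels", names)
        side.setdefault("voxel_size_um", list(volume.voxel_size_um))
        Path(str(path) + ".json").write_text(
            json.dumps(side, indent=2, sort_keys=True, default=_jsonify)
        )


def _ome_physical_sizes(ome_xml: str) -> dict[str, float]:
    sizes = {}
    for axis in "ZYX":
        m = re.search(rf'PhysicalSize{axis}="([0-9.eE+-]+)"', ome_xml)
        if m:
            sizes[axis] = float(m.group(1))
    return sizes


def _ome_channel_names(ome_xml: str) -> list[str]:
    return re.findall(r'<Channel[^>]*Name="([^"]+)"', ome_xml)


def _file_metadata(tf: tifffile.TiffFile) -> dict:
    """Voxel/pixel sizes and channel names from shaped-JSON or OME metadata."""
    meta: dict = {}
    if tf.shaped_metadata:
        meta.update(tf.shaped_metadata[0])
    if tf.ome_metadata:
        sizes = _ome_physical_sizes(tf.ome_metadata)
        for axis, value in sizes.items():
            meta.setdefault(f"PhysicalSize{axis}", value)
        names = _ome_channel_names(tf.ome_metadata)
        if names:
            meta.setdefault("ChannelNames", names)
    return meta


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
    required_channels: tuple[str, ...] = (),
) -> ImageVolume:
    """Read a multichannel TIFF/OME-TIFF volume.

    Voxel size comes from the OME metadata unless an override is given (the
    override wins on conflict); channel names from the metadata unless
    supplied. Missing voxel size with no override, or a missing required
    channel, is an error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = _file_metadata(tf)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if data.ndim == 3:
        data = data[np.newaxis]
    if data.ndim != 4 or 0 in data.shape:
        raise ValueError(f"{path}: expected a CZYX or ZYX volume, got shape {data.shape}")

    have_sizes = all(f"PhysicalSize{a}" in meta for a in "ZYX")
    if voxel_size_um is None:
        if not have_sizes:
            raise ValueError(f"{path} has no voxel size metadata and no override given")
        voxel = tuple(float(meta[f"PhysicalSize{a}"]) for a in "ZYX")
    else:
        voxel = tuple(voxel_size_um)

    names = channel_names or list(meta.get("ChannelNames", []))
    if not names:
        names = [f"channel{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(f"{len(names)} channel names for {data.shape[0]} channels")
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    for req in required_channels:
        if req not in channels:
            raise ValueError(f"required channel {req!r} missing from {path}")
    return ImageVolume(channels=channels, voxel_size_um=voxel)


# ---------------------------------------------------------------------------
# 2D puncta images
# ---------------------------------------------------------------------------


def write_puncta_image(path: str | Path, image: PunctaImage,
                       sidecar: dict | None = None) -> None:
    names = sorted(image.channels)
    stack = np.stack([np.asarray(image.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(
        Path(path), stack,
        ome=False,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeX": image.pixel_size_um,
            "ChannelNames": names,
        },
    )
    if sidecar is not None:
        side = dict(sidecar)
        side.setdefault("channels", names)
        side.setdefault("pixel_size_um", image.pixel_size_um)
        Path(str(path) + ".json").write_text(
            json.dumps(side, indent=2, sort_keys=True, default=_jsonify)
        )


def read_puncta_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_names: list[str] | None = None,
) -> PunctaImage:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = _file_metadata(tf)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if pixel_size_um is None:
        if "PhysicalSizeX" not in meta:
            raise ValueError(f"{path} has no pixel size metadata and no override given")
        pixel_size_um = float(meta["PhysicalSizeX"])
    names = channel_names or list(meta.get("ChannelNames", []))
    if not names:
        names = [f"channel{i}" for i in range(data.shape[0])]
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    return PunctaImage(channels=channels, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(path: str | Path, trace: Trace, sidecar: dict | None = None) -> None:
    """CSV with header ``time_s,value``; units and metadata in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(path, index=False, float_format="%.10g")
    side = dict(sidecar or {})
    side.setdefault("units", trace.units)
    side.setdefault("sampling_rate_hz", trace.sampling_rate_hz)
    Path(str(path) + ".json").write_text(
        json.dumps(side, indent=2, sort_keys=True, default=_jsonify)
    )


def read_trace(path: str | Path, units: str | None = None,
               spacing_tolerance: float = 1e-6) -> Trace:
    """Read a ``time_s,value`` CSV; sampling rate from the median spacing.

    Non-uniform spacing beyond ``spacing_tolerance`` (relative, default 1 ppm)
    is rejected with the offending row indices named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 rows")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = np.nonzero(dt <= 0)[0] + 1
        raise ValueError(f"{path}: non-monotone time at rows {bad[:10].tolist()}")
    med = float(np.median(dt))
    off = np.abs(dt - med) > spacing_tolerance * med
    if off.any():
        bad = (np.nonzero(off)[0] + 1).tolist()[:10]
        raise ValueError(f"{path}: non-uniform sampling at rows {bad}")
    if units is None:
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            units = json.loads(sidecar.read_text()).get("units", "uM")
        else:
            units = "uM"
    return Trace(df["value"].to_numpy(dtype=float), 1.0 / med, float(t[0]), units)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(metrics: MetricsTable, run: RunConfig, out_dir: str | Path,
                 basename: str = "metrics") -> tuple[Path, Path]:
    """Write the tidy metrics CSV and the JSON run record.

    Output is deterministic: rows are sorted by key and floats serialized with
    a fixed format, so identical runs produce byte-identical files.
    """
    if not metrics.rows:
        raise ValueError("refusing to write an empty metrics table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{basename}.csv"
    json_path = out_dir / f"{basename}.run.json"
    df = metrics.to_frame().sort_values(
        ["run_id", "item_id", "metric"], kind="stable"
    ).reset_index(drop=True)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    json_path.write_text(run.to_json())
    return csv_path, json_path
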