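"""Readers and writers shared by the pipeline: TIFF images, annotation JSON,
profile and matrix CSVs, ordering JSON, and provenance records.

All writers are deterministic for identical inputs: stable column order and
shortest round-trip float notation, so CSV round-trips are value-exact.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ordering import OrderingState
from .profiles import AxisSpec, IntensityMatrix, RoiMask, SpatialProfile, project_stack

def _csv_float(value) -> str:
    """Shortest round-trip decimal form: exact and deterministic for doubles."""
    return repr(float(value))


__all__ = [
    "read_image",
    "read_annotations",
    "write_profiles",
    "read_profiles",
    "write_matrix",
    "read_matrix",
    "write_ordering",
    "read_ordering",
    "write_provenance",
]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _ome_channel_names(tif: tifffile.TiffFile) -> list[str]:
    if not tif.ome_metadata:
        return []
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return []
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    return [
        ch.get("Name") or f"channel_{i}"
        for i, ch in enumerate(root.iter(f"{{{ns['ome']}}}Channel"))
    ]


def read_image(
    path: str | Path, channel: int | str | None = None, z_policy: str = "keep-stack"
) -> np.ndarray:
    """Read a TIFF / OME-TIFF, select a channel, and apply the z policy.

    ``channel`` may be an integer index or an OME channel name; ``z_policy``
    is ``keep-stack`` or ``project:max|mean|sum``.  Returns a 2-D image or a
    (z, y, x) stack.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'YX', 'ZYX', 'CYX', 'ZCYX'
        names = _ome_channel_names(tif)

    axes = axes.replace("S", "C")
    if "C" in axes:
        c_axis = axes.index("C")
        n_channels = data.shape[c_axis]
        if channel is None:
            if n_channels > 1:
                raise ValueError(
                    f"multi-channel image; pick one of {names or list(range(n_channels))}"
                )
            index = 0
        elif isinstance(channel, int):
            if not 0 <= channel < n_channels:
                raise ValueError(
                    f"channel {channel} out of range; available: {names or list(range(n_channels))}"
                )
            index = channel
        else:
            if channel not in names:
                raise ValueError(f"channel {channel!r} not found; available: {names}")
            index = names.index(channel)
        data = np.take(data, index, axis=c_axis)
        axes = axes.replace("C", "", 1)
    elif isinstance(channel, (int, str)) and channel not in (0, None):
        raise ValueError("image has a single channel; available: [0]")

    if "Z" not in axes:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"unsupported image layout with axes {axes!r}")
        return data
    z_axis = axes.index("Z")
    stack = np.moveaxis(data, z_axis, 0).astype(float)
    if z_policy == "keep-stack":
        return stack
    if z_policy.startswith("project:"):
        return project_stack(stack, z_policy.split(":", 1)[1])
    raise ValueError(f"unknown z_policy {z_policy!r}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict:
    """Load one sample's annotation JSON into RoiMask / AxisSpec objects.

    Expected keys: ``sample_id``, ``roi`` (polygon vertices), ``axis``
    (``origin``, ``polyline``, ``unit_length``) and optionally
    ``control_of`` linking a no-primary control to its experimental sample.
    """
    payload = json.loads(Path(path).read_text())
    try:
        sample_id = payload["sample_id"]
        roi = RoiMask(polygon=np.asarray(payload["roi"], float), sample_id=sample_id)
        ax = payload["axis"]
        axis = AxisSpec(
            origin=np.asarray(ax["origin"], float),
            polyline=np.asarray(ax["polyline"], float),
            unit_length=float(ax["unit_length"]),
        )
    except KeyError as exc:
        raise ValueError(f"annotation file {path} is missing key {exc}") from None
    return {
        "sample_id": sample_id,
        "roi": roi,
        "axis": axis,
        "control_of": payload.get("control_of"),
    }


# ---------------------------------------------------------------------------
# profiles and matrices (CSV)
# ---------------------------------------------------------------------------

def write_profiles(profiles: list[SpatialProfile], path: str | Path) -> Path:
    """Long-format CSV: sample_id, channel, position, intensity, normalized."""
    frames = [
        pd.DataFrame(
            {
                "sample_id": p.sample_id,
                "channel": p.channel,
                "position": p.positions,
                "intensity": p.intensities,
                "normalized": p.normalized,
            }
        )
        for p in profiles
    ]
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_csv_float)
    return path


def read_profiles(path: str | Path, channel: str | None = None) -> list[SpatialProfile]:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "channel", "position", "intensity", "normalized"}
    if not required.issubset(frame.columns):
        raise ValueError(f"profile CSV must have columns {sorted(required)}")
    if channel is not None:
        frame = frame[frame["channel"] == channel]
        if frame.empty:
            raise ValueError(f"no profiles for channel {channel!r} in {path}")
    profiles = []
    for (sid, chan), group in frame.groupby(["sample_id", "channel"], sort=False):
        group = group.sort_values("position")
        profiles.append(
            SpatialProfile(
                sample_id=str(sid),
                channel=str(chan),
                positions=group["position"].to_numpy(float),
                intensities=group["intensity"].to_numpy(float),
                normalized=bool(group["normalized"].iloc[0]),
            )
        )
    return profiles


def write_matrix(matrix: IntensityMatrix, path: str | Path) -> Path:
    """Matrix CSV (first column bin_center, one column per sample) + sidecar."""
    path = Path(path)
    frame = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    frame.insert(0, "bin_center", matrix.bin_centers)
    frame.to_csv(path, index=False, float_format=_csv_float)
    sidecar = {"channel": matrix.channel, "tool": f"kymoclock {__version__}"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_matrix(path: str | Path) -> IntensityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if "bin_center" not in frame.columns:
        raise ValueError("matrix CSV must start with a bin_center column")
    sample_ids = [c for c in frame.columns if c != "bin_center"]
    if not sample_ids:
        raise ValueError("matrix CSV contains no sample columns")
    sidecar_path = Path(str(path) + ".json")
    channel = ""
    if sidecar_path.exists():
        channel = json.loads(sidecar_path.read_text()).get("channel", "")
    return IntensityMatrix(
        values=frame[sample_ids].to_numpy(float),
        bin_centers=frame["bin_center"].to_numpy(float),
        sample_ids=sample_ids,
        channel=channel,
    )


# ---------------------------------------------------------------------------
# orderings and provenance
# ---------------------------------------------------------------------------

def write_ordering(
    state: OrderingState,
    sample_ids: list[str],
    path: str | Path,
    config: dict | None = None,
    trace_file: str | None = None,
) -> Path:
    path = Path(path)
    payload = {
        "channel": state.channel,
        "permutation": [sample_ids[j] for j in state.permutation],
        "permutation_indices": state.permutation.tolist(),
        "objective": state.objective,
        "n_admissible_rows": state.n_admissible_rows,
        "config": config or {},
        "trace_file": trace_file,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_ordering(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["state"] = OrderingState(
        permutation=np.asarray(payload["permutation_indices"], int),
        objective=float(payload["objective"]),
        channel=payload.get("channel", ""),
        n_admissible_rows=int(payload.get("n_admissible_rows", 0)),
    )
    return payload


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(out_dir: str | Path, config: dict, inputs: list[str | Path]) -> Path:
    """Record the resolved run configuration and input digests next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "kymoclock",
        "version": __version__,
        "config": config,
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
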