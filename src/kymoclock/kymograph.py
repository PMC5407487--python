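"""Ordered kymographs: temporally ranked profile stacks and their rendering.

A kymograph here is the cohort's intensity matrix with columns re-ordered by
the inferred temporal ranking and transposed for display: each row is one
explant's spatial profile, rows run down the page in inferred clock order,
and the axial position runs left (posterior) to right (anterior).  Tiling
the one-cycle kymograph vertically — the periodic extension — visualizes
the pattern through multiple simulated oscillations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from matplotlib import colormaps
import matplotlib.pyplot as plt

from .ordering import OrderingState
from .profiles import IntensityMatrix

__all__ = [
    "Kymograph",
    "build_kymograph",
    "periodic_extension",
    "render",
    "render_figure",
    "write_kymograph_csv",
    "read_kymograph_csv",
]


@dataclass
class Kymograph:
    """An ordered (optionally periodically extended) stack of profiles.

    ``values[r]`` is the length-N profile at temporal rank r; ``cycles[r]``
    says which tiling copy the row belongs to (0 for an unextended
    kymograph).
    """

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str]
    channel: str
    n_cycles: int = 1
    cycles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.sample_ids = list(self.sample_ids)
        r, n = self.values.shape
        if self.bin_centers.shape != (n,):
            raise ValueError("bin_centers must match the profile length")
        if len(self.sample_ids) != r:
            raise ValueError("one sample_id per row required")
        if self.n_cycles < 1 or r % self.n_cycles != 0:
            raise ValueError("row count must be n_cycles x M")
        if self.cycles is None:
            self.cycles = np.repeat(np.arange(self.n_cycles), r // self.n_cycles)
        self.cycles = np.asarray(self.cycles, dtype=int)
        if self.cycles.shape != (r,):
            raise ValueError("cycles must have one entry per row")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(self.n_rows)

    @property
    def rows(self) -> list[tuple[int, str, np.ndarray]]:
        """Rows as (rank, sample_id, profile) triples."""
        return [
            (r, self.sample_ids[r], self.values[r]) for r in range(self.n_rows)
        ]


def build_kymograph(
    matrix: IntensityMatrix, ordering: OrderingState | Sequence[int]
) -> Kymograph:
    """Stack matrix columns in temporal order: row at rank r is sample pi(r)."""
    perm = ordering.permutation if isinstance(ordering, OrderingState) else np.asarray(ordering, int)
    if perm.size != matrix.n_samples or not np.array_equal(
        np.sort(perm), np.arange(matrix.n_samples)
    ):
        raise ValueError("ordering is not a permutation of the matrix columns")
    return Kymograph(
        values=matrix.values[:, perm].T,
        bin_centers=matrix.bin_centers.copy(),
        sample_ids=[matrix.sample_ids[j] for j in perm],
        channel=matrix.channel,
        n_cycles=1,
    )


def periodic_extension(kymo: Kymograph, n_cycles: int) -> Kymograph:
    """Tile a one-cycle kymograph ``n_cycles`` times (exact copy, no resampling)."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if kymo.n_cycles != 1:
        raise ValueError("periodic extension starts from an unextended kymograph")
    return Kymograph(
        values=np.tile(kymo.values, (n_cycles, 1)),
        bin_centers=kymo.bin_centers.copy(),
        sample_ids=kymo.sample_ids * n_cycles,
        channel=kymo.channel,
        n_cycles=n_cycles,
    )


def _crop(kymo: Kymograph, crop_axial, crop_ranks):
    values = kymo.values
    centers = kymo.bin_centers
    if crop_axial is not None:
        lo, hi = crop_axial
        keep = (centers >= lo) & (centers <= hi)
        if not np.any(keep):
            raise ValueError("axial crop window contains no bins")
        values = values[:, keep]
        centers = centers[keep]
    rows = np.arange(values.shape[0])
    if crop_ranks is not None:
        lo, hi = crop_ranks
        rows = rows[(rows >= lo) & (rows <= hi)]
        if rows.size == 0:
            raise ValueError("rank crop window contains no rows")
        values = values[rows]
    return values, centers, rows


def render(
    kymo: Kymograph,
    output_path: str | Path,
    palette: str = "viridis",
    scale: int = 1,
    crop_axial: tuple[float, float] | None = None,
    crop_ranks: tuple[int, int] | None = None,
    row_normalize: bool = False,
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Write the kymograph as a deterministic raster heat-map (PNG).

    One pixel per (rank, bin) before ``scale``-fold nearest-neighbour
    upscaling; x runs posterior -> anterior (anterior right), y is temporal
    rank increasing downward.  ``crop_axial`` (position window) and
    ``crop_ranks`` reproduce the magnified-crop style of figure panels.
    ``row_normalize`` divides each row by its own maximum before color
    mapping (off by default: rows are shown on a common scale).
    """
    if kymo.n_rows == 0:
        raise ValueError("empty kymograph")
    values, _, _ = _crop(kymo, crop_axial, crop_ranks)
    values = values.astype(float)
    if row_normalize:
        peaks = values.max(axis=1, keepdims=True)
        peaks[peaks == 0] = 1.0
        values = values / peaks
    lo = values.min() if vmin is None else vmin
    hi = values.max() if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    unit = np.clip((values - lo) / span, 0.0, 1.0)
    rgb = (colormaps[palette](unit)[..., :3] * 255).astype(np.uint8)
    if scale > 1:
        rgb = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    output_path = Path(output_path)
    iio.imwrite(output_path, rgb, extension=".png")
    return output_path


def render_figure(
    kymo: Kymograph,
    output_path: str | Path | None = None,
    palette: str = "viridis",
    crop_axial: tuple[float, float] | None = None,
    crop_ranks: tuple[int, int] | None = None,
    title: str | None = None,
):
    """Publication-style annotated rendering (axes, labels, colorbar)."""
    values, centers, rows = _crop(kymo, crop_axial, crop_ranks)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        values,
        aspect="auto",
        cmap=palette,
        origin="upper",
        extent=[centers[0], centers[-1], rows[-1] + 0.5, rows[0] - 0.5],
    )
    ax.set_xlabel("axial position (P → A)")
    ax.set_ylabel("temporal rank")
    ax.set_title(title or kymo.channel)
    fig.colorbar(im, ax=ax, label="intensity (a.u.)")
    if output_path is not None:
        fig.savefig(output_path, dpi=150)
        plt.close(fig)
        return Path(output_path)
    return fig


def write_kymograph_csv(kymo: Kymograph, path: str | Path) -> Path:
    """Write rows as ``rank, sample_id, cycle, bin_0..bin_{N-1}`` plus a sidecar.

    Floats are written in shortest round-trip notation, so reading the file
    back reproduces the values exactly.
    """
    path = Path(path)
    frame = pd.DataFrame(
        kymo.values, columns=[f"bin_{i}" for i in range(kymo.values.shape[1])]
    )
    frame.insert(0, "cycle", kymo.cycles)
    frame.insert(0, "sample_id", kymo.sample_ids)
    frame.insert(0, "rank", kymo.ranks)
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    sidecar = {
        "channel": kymo.channel,
        "n_cycles": kymo.n_cycles,
        "bin_centers": kymo.bin_centers.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_kymograph_csv(path: str | Path) -> Kymograph:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    bins = [c for c in frame.columns if c.startswith("bin_")]
    return Kymograph(
        values=frame[bins].to_numpy(dtype=float),
        bin_centers=np.asarray(sidecar["bin_centers"], dtype=float),
        sample_ids=[str(s) for s in frame["sample_id"]],
        channel=sidecar["channel"],
        n_cycles=int(sidecar["n_cycles"]),
        cycles=frame["cycle"].to_numpy(dtype=int),
    )
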