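"""Quantification of fluorescence intensity along the rostro-caudal axis.

Converts annotated confocal images of whole-mount PSM explants into
one-dimensional intensity-vs-position profiles and assembles cohorts of
profiles into an intensity matrix ``f(i, j)`` (spatial bin ``i``, sample
``j``).  The axial coordinate is an arclength fraction along a user-supplied
polyline: 0 at the posterior (caudal) origin, 1 one unit length towards the
anterior (rostral) end.

The processing chain mirrors standard whole-mount quantification practice:
z-projection, background subtraction / thresholding to a no-primary control
level, per-pixel projection onto the axis, binned averaging, and per-profile
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "AxisSpec",
    "RoiMask",
    "SpatialProfile",
    "IntensityMatrix",
    "PhaseCall",
    "project_stack",
    "subtract_background_and_threshold",
    "control_level_from_sample",
    "extract_profile",
    "normalize_profile",
    "build_matrix",
    "assign_phase",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AxisSpec:
    """Origin, axis polyline and unit length defining the normalized axis.

    Parameters
    ----------
    origin : (2,) array-like
        Posterior reference point in pixel coordinates (x, y).
    polyline : (k, 2) array-like
        Ordered axis vertices running posterior -> anterior, pixel (x, y).
    unit_length : float
        Length in pixels used to normalize axial position to [0, 1]
        (e.g. posterior tip to the most recent somite boundary).
    """

    origin: np.ndarray
    polyline: np.ndarray
    unit_length: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise ValueError("axis polyline needs at least two 2-D points")
        seg = np.diff(self.polyline, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len == 0):
            raise ValueError("axis polyline has repeated consecutive points")
        if not self.unit_length > 0:
            raise ValueError("unit_length must be positive")

    @property
    def line(self) -> LineString:
        return LineString(self.polyline)

    @property
    def arclength(self) -> float:
        return float(self.line.length)


@dataclass
class RoiMask:
    """Polygonal region of interest within the PSM of one sample."""

    polygon: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.polygon = np.atleast_2d(np.asarray(self.polygon, dtype=float))
        if self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("ROI polygon needs at least three 2-D points")
        poly = Polygon(self.polygon)
        if not poly.is_valid:
            raise ValueError("ROI polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ValueError("ROI polygon has zero area")

    @property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class SpatialProfile:
    """Channel intensity of one sample as a function of normalized position.

    ``positions`` are bin centers on [0, 1] (0 = posterior, 1 = anterior);
    ``intensities`` are non-negative fluorescence values in arbitrary units.
    """

    sample_id: str
    channel: str
    positions: np.ndarray
    intensities: np.ndarray
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if self.positions.size < 2:
            raise ValueError("profile needs at least two bins")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.positions.size


@dataclass
class IntensityMatrix:
    """The intensity matrix f(i, j): spatial bin i of sample j, one channel."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str]
    channel: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (bins x samples)")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 spatial bins and 1 sample")
        if self.bin_centers.shape != (n,):
            raise ValueError("bin_centers length must match the number of rows")
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length must match the number of columns")
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("matrix values must be finite and non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


class PhaseCall(NamedTuple):
    """Phase label (1-3) with the band centroid and fractional width behind it."""

    label: int
    centroid: float
    width: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def project_stack(stack: np.ndarray, method: str = "max") -> np.ndarray:
    """Collapse a z-stack (z, y, x) to a single 2-D image.

    ``method`` is one of ``max`` (default; preserves thin expression bands),
    ``mean`` or ``sum``.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1 or stack.size == 0:
        raise ValueError("stack must be a non-empty (z, y, x) array")
    reducers = {"max": np.max, "mean": np.mean, "sum": np.sum}
    try:
        reduce = reducers[method]
    except KeyError:
        raise ValueError(f"unknown projection method {method!r}") from None
    return reduce(stack.astype(float), axis=0)


def subtract_background_and_threshold(image: np.ndarray, control_level: float) -> np.ndarray:
    """Subtract a scalar background and clip at zero.

    Every pixel ``p`` maps to ``max(p - control_level, 0)``, so pixels at or
    below the no-primary control level become exactly zero.  Idempotent for a
    fixed level.
    """
    if control_level < 0:
        raise ValueError("control_level must be non-negative")
    return np.maximum(np.asarray(image, dtype=float) - control_level, 0.0)


def _roi_pixel_mask(image: np.ndarray, roi: RoiMask) -> np.ndarray:
    """Boolean mask of pixels whose centers (col+0.5, row+0.5) fall in the ROI."""
    h, w = image.shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs = cols.ravel() + 0.5
    ys = rows.ravel() + 0.5
    inside = shapely.contains_xy(roi.shape, xs, ys)
    return inside.reshape(h, w)


def control_level_from_sample(
    image: np.ndarray, roi: RoiMask, statistic: str = "mean"
) -> float:
    """Summarize pixel values inside the ROI of a no-primary control image.

    ``statistic`` is ``"mean"`` (default) or ``"percentile-q"`` with q in
    [0, 100], e.g. ``"percentile-95"``.
    """
    image = np.asarray(image, dtype=float)
    mask = _roi_pixel_mask(image, roi)
    pixels = image[mask]
    if pixels.size == 0:
        raise ValueError("control ROI contains no pixel centers")
    if statistic == "mean":
        return float(pixels.mean())
    if statistic.startswith("percentile-"):
        q = float(statistic.split("-", 1)[1])
        if not 0 <= q <= 100:
            raise ValueError("percentile must be in [0, 100]")
        return float(np.percentile(pixels, q))
    raise ValueError(f"unknown statistic {statistic!r}")


def axial_coordinates(points_xy: np.ndarray, axis: AxisSpec) -> np.ndarray:
    """Normalized axial coordinate of each (x, y) point.

    Each point is projected orthogonally onto the axis polyline (nearest
    point on the line); its coordinate is the arclength of that projection,
    measured from the projection of the origin, divided by the unit length.
    """
    line = axis.line
    pts = shapely.points(np.asarray(points_xy, dtype=float))
    s = shapely.line_locate_point(line, pts)
    s0 = line.project(Point(axis.origin))
    return (np.asarray(s, dtype=float) - s0) / axis.unit_length


def extract_profile(
    image: np.ndarray,
    roi: RoiMask,
    axis: AxisSpec,
    n_bins: int,
    sample_id: str | None = None,
    channel: str = "",
) -> SpatialProfile:
    """Bin ROI pixel intensities by normalized axial position.

    Every pixel center inside the ROI is assigned the arclength fraction of
    its orthogonal projection onto the axis; pixels outside [0, 1] are
    discarded.  Bin ``i`` covers [i/n, (i+1)/n) (last bin closed) and carries
    the mean of its pixels.  Empty interior bins are filled by linear
    interpolation from their non-empty neighbours and listed in
    ``metadata["empty_bins"]``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = _roi_pixel_mask(image, roi)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("ROI does not overlap the image")
    coords = axial_coordinates(np.column_stack([cols + 0.5, rows + 0.5]), axis)
    keep = (coords >= 0.0) & (coords <= 1.0)
    if not np.any(keep):
        raise ValueError("no ROI pixel projects into the [0, 1] axial range")
    coords = coords[keep]
    values = image[rows[keep], cols[keep]]

    idx = np.minimum((coords * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    filled = counts > 0
    if not np.any(filled):
        raise ValueError("all axial bins are empty")
    intensities = np.zeros(n_bins)
    intensities[filled] = sums[filled] / counts[filled]
    empty = np.nonzero(~filled)[0]
    if empty.size:
        intensities[empty] = np.interp(
            empty, np.nonzero(filled)[0], intensities[filled]
        )
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return SpatialProfile(
        sample_id=sample_id if sample_id is not None else roi.sample_id,
        channel=channel,
        positions=centers,
        intensities=np.maximum(intensities, 0.0),
        normalized=False,
        metadata={"empty_bins": empty.tolist(), "n_pixels": int(coords.size)},
    )


def normalize_profile(profile: SpatialProfile, mode: str = "max") -> SpatialProfile:
    """Normalize a profile so cross-sample columns are comparable.

    ``mode="max"`` divides by the peak (peak becomes 1); ``mode="area"``
    divides by the trapezoidal integral over the position range.
    """
    peak = profile.intensities.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    if mode == "max":
        scale = peak
    elif mode == "area":
        scale = np.trapezoid(profile.intensities, profile.positions)
        if scale <= 0:
            raise ValueError("profile has zero area")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return SpatialProfile(
        sample_id=profile.sample_id,
        channel=profile.channel,
        positions=profile.positions.copy(),
        intensities=profile.intensities / scale,
        normalized=True,
        metadata={**profile.metadata, "normalization": mode},
    )


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear extrapolation at the edges."""
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        if np.any(lo):
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[lo] = fp[0] + slope * (x[lo] - xp[0])
        if np.any(hi):
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


def build_matrix(profiles: Sequence[SpatialProfile], n_bins: int) -> IntensityMatrix:
    """Place profiles side by side on a common grid: the intensity matrix.

    Each profile is resampled by piecewise-linear interpolation (with linear
    extrapolation beyond its own grid) onto ``n_bins`` centers at
    ``(i + 0.5) / n_bins``.  Column ``j`` holds sample ``j`` in input order.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    channels = {p.channel for p in profiles}
    if len(channels) != 1:
        raise ValueError(f"profiles mix channels: {sorted(channels)}")
    flags = {p.normalized for p in profiles}
    if len(flags) != 1:
        raise ValueError("profiles mix normalized and raw intensities")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    centers = (np.arange(n_bins) + 0.5) / n_bins
    cols = [
        _interp_extrapolate(centers, p.positions, p.intensities) for p in profiles
    ]
    values = np.clip(np.column_stack(cols), 0.0, None)
    return IntensityMatrix(
        values=values,
        bin_centers=centers,
        sample_ids=ids,
        channel=profiles[0].channel,
    )


def assign_phase(profile: SpatialProfile, threshold_fraction: float = 0.5) -> PhaseCall:
    """Classify a clock-gene profile into Phase 1, 2 or 3 of the clock cycle.

    The expression band is the set of bins at or above
    ``threshold_fraction x max``; its intensity-weighted centroid ``c``
    determines the label (c < 1/3: Phase 1, posterior band; c < 2/3: Phase 2;
    otherwise Phase 3, anterior band).  The returned width is the fraction of
    bins inside the band.  These cut-offs are an explicit convention for a
    call that is made by eye in practice.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    peak = profile.intensities.max()
    if peak <= 0:
        raise ValueError("cannot phase an all-zero profile")
    band = profile.intensities >= threshold_fraction * peak
    weights = profile.intensities[band]
    centroid = float(np.sum(profile.positions[band] * weights) / np.sum(weights))
    width = float(band.sum() / band.size)
    if centroid < 1 / 3:
        label = 1
    elif centroid < 2 / 3:
        label = 2
    else:
        label = 3
    return PhaseCall(label=label, centroid=centroid, width=width)
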