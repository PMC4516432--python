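"""Denaturing-gel densitometry for in vitro uridylation time courses.

Each lane is a 1-D signal-intensity profile along the migration axis
(sampled at 20 pixels/mm from a phosphorimager scan).  The quantification
chain is:

1. per-lane background = mean of the 25th and 50th intensity percentiles,
   subtracted and clipped at zero;
2. marker-band detection on a marker lane via Savitzky-Golay smoothing
   (window 31 px, polynomial order 3): band centers are positions where
   the smoothed first derivative crosses from positive to negative and the
   second derivative falls below a threshold (default -100, in raw
   intensity units — scanner-dependent, so exposed as a parameter);
3. a cubic-spline position<->size calibration through the marker bands;
4. resampling of lane intensity into size space as first differences of
   the cumulative intensity on an equal-width size grid (0.1 nt);
5. the average extension length L = sum_p I_p (s_p - r) / sum_p I_p over
   grid positions p with size s_p >= r - 3 nt, where r is the reference
   size of the unextended RNA (maximum-intensity position of the 0-min
   lane).  Products more than 3 nt shorter than r are treated as
   degradation and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter


@dataclass(frozen=True)
class LaneProfile:
    """1-D intensity profile along the migration axis (20 px/mm)."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intensities", np.asarray(self.intensities, dtype=float)
        )
        if self.intensities.ndim != 1 or self.intensities.size == 0:
            raise ValueError("lane profile must be a non-empty 1-D vector")

    def __len__(self) -> int:
        return self.intensities.size


@dataclass(frozen=True)
class SizeCalibration:
    """Monotone cubic-spline map between gel position (px) and RNA size (nt).

    The inverse map solves the forward spline's cubic pieces directly, so
    position_at(size_at(p)) round-trips to machine precision.
    """

    marker_positions: np.ndarray
    marker_sizes: np.ndarray
    _pos_to_size: CubicSpline

    def size_at(self, positions) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        lo, hi = self.marker_positions[0], self.marker_positions[-1]
        if np.any(positions < lo) or np.any(positions > hi):
            warnings.warn("position query outside marker range; extrapolating")
        return self._pos_to_size(positions)

    def position_at(self, sizes):
        arr = np.atleast_1d(np.asarray(sizes, dtype=float))
        s_lo = float(self.marker_sizes.min())
        s_hi = float(self.marker_sizes.max())
        if np.any(arr < s_lo) or np.any(arr > s_hi):
            warnings.warn("size query outside marker range; extrapolating")
        p_lo, p_hi = self.marker_positions[0], self.marker_positions[-1]
        out = np.empty_like(arr)
        for i, s in enumerate(arr):
            roots = self._pos_to_size.solve(s, extrapolate=True)
            if roots.size == 0:
                raise ValueError(f"size {s} nt unreachable by the calibration")
            inside = roots[(roots >= p_lo) & (roots <= p_hi)]
            if inside.size:
                out[i] = inside[0]
            else:  # extrapolation region: root nearest the calibrated span
                out[i] = roots[np.argmin(np.abs(roots - np.clip(roots, p_lo, p_hi)))]
        return float(out[0]) if np.isscalar(sizes) or np.ndim(sizes) == 0 else out


@dataclass(frozen=True)
class SizeDensity:
    """RNA amount density on an equal-width size grid (bin centers)."""

    sizes: np.ndarray  # nt, 0.1-nt spacing by default
    density: np.ndarray  # non-negative, one value per bin

    def total(self) -> float:
        return float(self.density.sum())


def subtract_background(lane: LaneProfile) -> LaneProfile:
    """Subtract mean(P25, P50) of the lane and clip at zero."""
    x = lane.intensities
    background = 0.5 * (np.percentile(x, 25) + np.percentile(x, 50))
    return LaneProfile(np.clip(x - background, 0.0, None))


def detect_markers(
    marker_lane: LaneProfile,
    window: int = 31,
    order: int = 3,
    d2_threshold: float = -100.0,
    expected_count: int | None = None,
) -> np.ndarray:
    """Marker band centers from derivative sign changes of the smoothed lane.

    A band center is a position where the Savitzky-Golay first derivative
    turns from positive to non-positive and the second derivative is below
    ``d2_threshold``.  When ``expected_count`` is given and fewer bands are
    found, raises ValueError (supply manual positions instead).
    """
    x = marker_lane.intensities
    if x.size <= window:
        raise ValueError(f"lane length {x.size} must exceed window {window}")
    d1 = savgol_filter(x, window, order, deriv=1)
    d2 = savgol_filter(x, window, order, deriv=2)
    crossings = np.flatnonzero((d1[:-1] > 0) & (d1[1:] <= 0)) + 1
    positions = crossings[d2[crossings] < d2_threshold]
    if expected_count is not None and positions.size < expected_count:
        raise ValueError(
            f"detected {positions.size} marker bands, expected {expected_count}; "
            "provide marker positions manually"
        )
    return positions.astype(float)


def calibrate_sizes(
    marker_positions: Sequence[float],
    marker_sizes: Sequence[float],
) -> SizeCalibration:
    """Cubic-spline interpolant through (position, size) marker knots.

    Positions must be strictly increasing and sizes strictly monotone
    (decreasing for a conventional gel, where small RNAs migrate further).
    At least 4 markers are required.
    """
    pos = np.asarray(marker_positions, dtype=float)
    size = np.asarray(marker_sizes, dtype=float)
    if pos.size != size.size:
        raise ValueError("marker position/size length mismatch")
    if pos.size < 4:
        raise ValueError("need at least 4 markers for a cubic spline")
    if not np.all(np.diff(pos) > 0):
        raise ValueError("marker positions must be strictly increasing")
    dsz = np.diff(size)
    if not (np.all(dsz > 0) or np.all(dsz < 0)):
        raise ValueError("marker sizes must be strictly monotone")
    return SizeCalibration(pos, size, CubicSpline(pos, size))


def density_in_size_space(
    lane: LaneProfile,
    calibration: SizeCalibration,
    bin_nt: float = 0.1,
    size_range: tuple[float, float] | None = None,
) -> SizeDensity:
    """Resample lane intensity onto an equal-width size grid.

    The cumulative intensity along position is evaluated (linear
    interpolation between pixels) at the positions of the size-grid edges
    and differenced once; bin mass is the absolute cumulative difference,
    so total density equals total lane intensity over the mapped range.
    """
    x = lane.intensities
    cum = np.concatenate([[0.0], np.cumsum(x)])  # cum[i] = mass of pixels < i
    pixel_edges = np.arange(x.size + 1, dtype=float) - 0.5
    if size_range is None:
        edge_sizes = calibration.size_at(np.array([pixel_edges[0], pixel_edges[-1]]))
        lo, hi = float(min(edge_sizes)), float(max(edge_sizes))
    else:
        lo, hi = size_range
    n_bins = max(1, int(round((hi - lo) / bin_nt)))
    grid_edges = lo + bin_nt * np.arange(n_bins + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        edge_positions = calibration.position_at(grid_edges)
    edge_cum = np.interp(edge_positions, pixel_edges, cum)
    mass = np.abs(np.diff(edge_cum))
    centers = 0.5 * (grid_edges[:-1] + grid_edges[1:])
    return SizeDensity(sizes=centers, density=mass)


def reference_size(lane: LaneProfile, calibration: SizeCalibration) -> float:
    """Size of the maximum-intensity position of a (0-min) reference lane."""
    peak = int(np.argmax(lane.intensities))
    return float(calibration.size_at(float(peak)))


def average_extension(
    density: SizeDensity,
    r: float,
    degrade_cutoff: float = 3.0,
    min_included_fraction: float = 1e-3,
) -> float:
    """Intensity-weighted mean extension beyond the reference size r (nt).

    Bins with size below ``r - degrade_cutoff`` (degradation products) are
    excluded.  Returns NaN (undefined) when the remaining intensity is zero
    or a negligible fraction of the lane total — numerical dust from band
    tails and interpolation must not masquerade as signal.
    """
    keep = density.sizes >= r - degrade_cutoff
    total = density.density[keep].sum()
    grand_total = density.density.sum()
    if total <= 0 or (grand_total > 0 and total < min_included_fraction * grand_total):
        return float("nan")
    return float(
        np.sum(density.density[keep] * (density.sizes[keep] - r)) / total
    )


def quantify_lanes(
    lanes: Sequence[LaneProfile],
    marker_lane: LaneProfile,
    marker_sizes: Sequence[float],
    reference_lane_index: int = 0,
    bin_nt: float = 0.1,
    degrade_cutoff: float = 3.0,
    d2_threshold: float = -100.0,
    marker_positions: Sequence[float] | None = None,
) -> list[float]:
    """End-to-end lane quantification: average extension per lane (nt).

    The reference size r is taken from the designated lane (default the
    first, i.e. the 0-min time point) after background subtraction.
    ``marker_positions`` overrides automatic marker detection.  Detected
    positions (ascending) are paired with the marker sizes in descending
    order: on a conventional denaturing gel the smaller RNA migrates
    further.  Pass explicit ``marker_positions`` for any other layout.
    """
    sizes_desc = sorted(marker_sizes, reverse=True)
    marker_bg = subtract_background(marker_lane)
    if marker_positions is None:
        positions = detect_markers(
            marker_bg, d2_threshold=d2_threshold, expected_count=len(sizes_desc)
        )
        if positions.size != len(sizes_desc):
            raise ValueError(
                f"detected {positions.size} markers for {len(sizes_desc)} sizes"
            )
    else:
        positions = np.asarray(marker_positions, dtype=float)
    calibration = calibrate_sizes(positions, sizes_desc)
    subtracted = [subtract_background(lane) for lane in lanes]
    r = reference_size(subtracted[reference_lane_index], calibration)
    return [
        average_extension(
            density_in_size_space(lane, calibration, bin_nt=bin_nt),
            r,
            degrade_cutoff=degrade_cutoff,
        )
        for lane in subtracted
    ]
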