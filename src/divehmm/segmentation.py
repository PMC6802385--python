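"""Dive segmentation from depth time series.

A dive is a maximal excursion of the depth trace beyond the surface
threshold (0.5 m) whose maximum depth reaches at least 1 m; start and end
times are placed at the threshold crossings by linear interpolation between
adjacent samples.  The bottom phase of a dive is the interval from the
first to the last sample at or beyond 70% of the dive's maximum depth.
Dives beginning within the first five minutes of tag attachment are
excluded to guard against short-term tagging responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthSeries",
    "DiveSegment",
    "downsample_depth",
    "detect_dives",
    "bottom_phase",
    "exclude_initial",
    "apply_overrides",
]

logger = logging.getLogger(__name__)

SURFACE_THRESHOLD_M = 0.5
MIN_MAX_DEPTH_M = 1.0
BOTTOM_FRACTION = 0.70
INITIAL_EXCLUSION_S = 300.0


@dataclass
class DepthSeries:
    """Uniformly sampled depth trace (m) for one deployment."""

    time: np.ndarray
    depth: np.ndarray
    sample_rate: float
    deployment_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.depth = np.asarray(self.depth, float)
        if self.time.shape != self.depth.shape:
            raise ValueError("time and depth must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if dt.min() <= 0:
                raise ValueError("time must be strictly increasing")
            if np.abs(dt - 1.0 / self.sample_rate).max() > 1e-6:
                raise ValueError("time must be uniform at sample_rate")
        if np.any(~np.isfinite(self.depth)):
            raise ValueError("depth contains non-finite values")
        if self.depth.min() < -0.5:
            raise ValueError("depth below -0.5 m (sensor-noise allowance)")


@dataclass
class DiveSegment:
    """One detected dive with interpolated boundaries and bottom phase."""

    deployment_id: str
    dive_index: int
    start_time: float
    end_time: float
    max_depth: float
    bottom_start: float = np.nan
    bottom_end: float = np.nan

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def downsample_depth(series: DepthSeries, target_rate: float) -> DepthSeries:
    """Decimate a depth trace by block averaging to ``target_rate``.

    An integer decimation factor averages each block of source samples; a
    non-integer factor falls back to interpolation of a mean-smoothed trace
    (with a warning).
    """
    if target_rate > series.sample_rate:
        raise ValueError("target_rate must not exceed the source rate")
    ratio = series.sample_rate / target_rate
    n = series.depth.size
    if abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        if f == 1:
            return series
        m = n // f
        depth = series.depth[: m * f].reshape(m, f).mean(axis=1)
        time = series.time[: m * f].reshape(m, f)[:, 0]
        return DepthSeries(time, depth, target_rate, series.deployment_id)
    warnings.warn(
        f"non-integer decimation factor {ratio:.3f}: resampling by "
        "interpolation of a mean-smoothed trace",
        stacklevel=2,
    )
    w = max(int(round(ratio)), 1)
    kernel = np.ones(w) / w
    padded = np.pad(series.depth, (w // 2, w - 1 - w // 2), mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    new_t = np.arange(series.time[0], series.time[-1], 1.0 / target_rate)
    return DepthSeries(
        new_t, np.interp(new_t, series.time, smooth), target_rate,
        series.deployment_id,
    )


def _cross_time(t0: float, d0: float, t1: float, d1: float, thr: float) -> float:
    if d1 == d0:
        return t0
    return t0 + (thr - d0) / (d1 - d0) * (t1 - t0)


def detect_dives(
    series: DepthSeries,
    surface_m: float = SURFACE_THRESHOLD_M,
    min_max_depth_m: float = MIN_MAX_DEPTH_M,
) -> list[DiveSegment]:
    """Find all dives: contiguous runs below the surface threshold reaching
    at least ``min_max_depth_m``, with linearly interpolated boundaries.

    Runs truncated by the start or end of the record are incomplete dives
    and are dropped (logged).  Bottom phases are filled in for each dive.
    """
    d = series.depth
    below = d > surface_m
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]])
    flips = np.diff(padded.astype(int))
    starts = np.flatnonzero(flips == 1)  # first sample of each run
    ends = np.flatnonzero(flips == -1)  # one past last sample of each run
    if below[0]:
        logger.info("%s: record starts mid-dive; leading run dropped",
                    series.deployment_id)
        starts, ends = starts[1:], ends[1:]
    if below[-1] and starts.size:
        logger.info("%s: record ends mid-dive; final incomplete dive dropped",
                    series.deployment_id)
        starts, ends = starts[:-1], ends[:-1]
    dives: list[DiveSegment] = []
    for i0, i1 in zip(starts, ends):
        seg = d[i0:i1]
        max_depth = float(seg.max())
        if max_depth < min_max_depth_m:
            continue
        t = series.time
        start = _cross_time(t[i0 - 1], d[i0 - 1], t[i0], d[i0], surface_m)
        end = _cross_time(t[i1 - 1], d[i1 - 1], t[i1], d[i1], surface_m)
        dive = DiveSegment(
            deployment_id=series.deployment_id,
            dive_index=len(dives),
            start_time=start,
            end_time=end,
            max_depth=max_depth,
        )
        dive.bottom_start, dive.bottom_end = bottom_phase(dive, series)
        dives.append(dive)
    return dives


def bottom_phase(
    dive: DiveSegment, series: DepthSeries, fraction: float = BOTTOM_FRACTION
) -> tuple[float, float]:
    """Interval from first to last sample at >= fraction x max depth."""
    mask = (series.time >= dive.start_time) & (series.time <= dive.end_time)
    idx = np.flatnonzero(mask & (series.depth >= fraction * dive.max_depth))
    # the max-depth sample always qualifies
    return float(series.time[idx[0]]), float(series.time[idx[-1]])


def exclude_initial(
    dives: list[DiveSegment],
    cutoff_s: float = INITIAL_EXCLUSION_S,
    attachment_time: float = 0.0,
) -> list[DiveSegment]:
    """Drop dives beginning within ``cutoff_s`` of tag attachment (strict)."""
    kept = [d for d in dives if d.start_time >= attachment_time + cutoff_s]
    removed = len(dives) - len(kept)
    if removed:
        logger.info("excluded %d dive(s) starting within %.0f s of attachment",
                    removed, cutoff_s)
    return kept


def apply_overrides(
    dives: list[DiveSegment], overrides, series: DepthSeries
) -> list[DiveSegment]:
    """Apply manual start/end edits (rows: dive_index, start_s, end_s).

    Stands in for the manual review step of dive detection; edited dives get
    their max depth and bottom phase recomputed from the series.
    """
    table = {int(r["dive_index"]): (float(r["start_s"]), float(r["end_s"]))
             for _, r in overrides.iterrows()}
    out = []
    for d in dives:
        if d.dive_index in table:
            s, e = table[d.dive_index]
            mask = (series.time >= s) & (series.time <= e)
            d = DiveSegment(d.deployment_id, d.dive_index, s, e,
                            float(series.depth[mask].max()))
            d.bottom_start, d.bottom_end = bottom_phase(d, series)
        out.append(d)
    return out
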