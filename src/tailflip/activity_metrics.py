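"""Per-minute activity series, baseline normalization and period binning.

The assay's endpoint is each fish's activity expressed as a percentage of the
median of its own *stable* pre-treatment window (by default the last 20 min of
the baseline recording), which removes the large between-fish differences in
absolute activity.  Post-treatment minutes are then averaged into recording
periods (15 min for the biosensor arm, 10 min for the video arm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, NormalizationError, ParameterError
from .types import ActivitySeries, NormalizedSeries

__all__ = [
    "StableWindow",
    "speed_from_trajectory",
    "stable_window",
    "normalize",
    "bin_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StableWindow:
    """Bounds (minutes relative to phase start, half-open) and median of the stable window."""

    start_min: int
    end_min: int
    median: float


def speed_from_trajectory(
    positions: np.ndarray,
    fps: float,
    fish_id: str = "fish",
    phase: str = "pre",
) -> ActivitySeries:
    """Per-minute swimming speed (mm/s) from a centroid trajectory.

    Speed is the Euclidean change in position in two dimensions per frame
    times the frame rate; each minute's value is the mean over that minute's
    frames.  Trailing frames that do not fill a whole minute are dropped.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise InputError(f"positions must have shape (n_frames, 2), got {pos.shape}")
    if pos.shape[0] < 2:
        raise InputError("need at least two frames to compute speed")
    if not np.all(np.isfinite(pos)):
        raise InputError("positions must be finite")
    if fps <= 0:
        raise ParameterError("fps must be positive")
    speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps  # mm/s per frame step
    frames_per_min = fps * 60.0
    minute = np.floor((np.arange(speeds.size) + 0.5) / frames_per_min).astype(int)
    n_full = int(pos.shape[0] // frames_per_min)
    if n_full < 1:
        raise InputError("trajectory shorter than one minute")
    values = np.array([speeds[minute == m].mean() for m in range(n_full)])
    return ActivitySeries(values, phase=phase, fish_id=fish_id, metric="speed")


def stable_window(pre: ActivitySeries, window_min: int = 20) -> StableWindow:
    """Stable pre-treatment window: the last ``window_min`` minutes and their median.

    Fish are more active early in the baseline recording, so the stable
    window anchors the normalization where activity has settled.
    """
    if window_min < 1:
        raise ParameterError("window_min must be >= 1")
    if pre.n_minutes < window_min:
        raise InputError(
            f"pre-treatment series ({pre.n_minutes} min) shorter than the stable window ({window_min} min)"
        )
    tail = pre.values[-window_min:]
    start = int(pre.minute_index[-window_min])
    return StableWindow(start_min=start, end_min=start + window_min, median=float(np.median(tail)))


def normalize(
    series: ActivitySeries,
    baseline_median: float,
    time_offset_min: float | None = None,
    group: str = "",
) -> NormalizedSeries:
    """Express activity as percent of the fish's stable pre-treatment median.

    ``time_offset_min`` maps the series' phase-local minutes onto minutes
    relative to the injection; it defaults to +30 (the recovery gap) for a
    post series and -60 for a pre series, matching the default timeline.
    A non-positive baseline median means the fish cannot be normalized and is
    excluded upstream.
    """
    if not np.isfinite(baseline_median) or baseline_median <= 0:
        raise NormalizationError(
            f"baseline median must be positive to normalize, got {baseline_median} "
            f"(fish {series.fish_id!r})"
        )
    if time_offset_min is None:
        time_offset_min = 30.0 if series.phase == "post" else -60.0
    values = 100.0 * series.values / baseline_median
    times = series.minute_index.astype(float) + time_offset_min
    return NormalizedSeries(
        values, times, bin_width_min=1.0, fish_id=series.fish_id, group=group
    )


def bin_series(ns: NormalizedSeries, bin_width_min: float) -> NormalizedSeries:
    """Average a per-minute normalized series into recording periods.

    Bins are timestamped by their start minute relative to injection.  A
    trailing span that does not fill a whole bin is dropped (and logged), so
    an 80-min recording at 15-min bins yields 5 bins covering 75 min.
    Binning an already-binned series at the same width is the identity.
    """
    if bin_width_min <= 0:
        raise ParameterError("bin_width_min must be positive")
    if math.isclose(bin_width_min, ns.bin_width_min):
        return ns
    if ns.bin_width_min != 1.0:
        raise InputError("can only re-bin an unbinned (per-minute) series")
    width = bin_width_min
    n_bins = int(ns.values.size // width)
    if n_bins < 1:
        raise InputError("series shorter than one bin")
    used = int(n_bins * width)
    if used < ns.values.size:
        logger.info(
            "fish %s: dropping %d trailing minute(s) not filling a %g-min bin",
            ns.fish_id,
            ns.values.size - used,
            width,
        )
    per_bin = int(width)
    values = ns.values[:used].reshape(n_bins, per_bin).mean(axis=1)
    starts = ns.time_min[0] + width * np.arange(n_bins)
    return NormalizedSeries(
        values, starts, bin_width_min=width, fish_id=ns.fish_id, group=ns.group
    )
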