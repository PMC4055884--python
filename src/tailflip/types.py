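"""Core data containers shared across the pipeline.

All containers are frozen dataclasses holding numpy arrays.  Times inside a
phase are in seconds (event times) or minutes (per-minute series) relative to
the start of that phase's recording; normalized series carry times in minutes
relative to the injection (injection = 0, pre-treatment minutes negative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import InputError, ParameterError

Phase = Literal["pre", "post"]

__all__ = ["FlipTrain", "Trace", "ActivitySeries", "NormalizedSeries", "Phase"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FlipTrain:
    """Tail-flip event times for one fish in one recording phase.

    Parameters
    ----------
    event_times
        Event times in seconds since the start of the phase recording,
        strictly increasing.
    duration_min
        Length of the recording the events live in, minutes.
    source
        ``"truth"`` for generator ground truth, ``"detected"`` for events
        recovered from a trace.
    """

    event_times: np.ndarray
    duration_min: float
    fish_id: str = "fish"
    phase: Phase = "pre"
    source: Literal["truth", "detected"] = "truth"

    def __post_init__(self):
        times = _as_float_array(self.event_times, "event_times")
        object.__setattr__(self, "event_times", times)
        if not np.isfinite(self.duration_min) or self.duration_min <= 0:
            raise ParameterError(f"duration_min must be positive, got {self.duration_min}")
        if times.size:
            if not np.all(np.isfinite(times)):
                raise InputError("event times must be finite")
            if np.any(np.diff(times) <= 0):
                raise InputError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration_min * 60.0:
                raise InputError("event times must lie within [0, duration]")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled 1-D activity signal (arbitrary impedance units)."""

    samples: np.ndarray
    sample_rate: float = 100.0
    t0: float = 0.0  # seconds relative to phase start
    phase: Phase = "pre"
    fish_id: str = "fish"

    def __post_init__(self):
        samples = _as_float_array(self.samples, "samples")
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise InputError("trace samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to phase start."""
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class ActivitySeries:
    """Per-minute activity of one fish (tail-flips/min or mm/s).

    ``minute_index`` is relative to the start of the phase recording and must
    be consecutive: a recorded section has no internal gaps.
    """

    values: np.ndarray
    minute_index: np.ndarray = None  # type: ignore[assignment]
    phase: Phase = "pre"
    fish_id: str = "fish"
    metric: Literal["flips", "speed"] = "flips"

    def __post_init__(self):
        values = _as_float_array(self.values, "values")
        object.__setattr__(self, "values", values)
        if self.minute_index is None:
            idx = np.arange(values.size)
        else:
            idx = np.asarray(self.minute_index, dtype=int)
        object.__setattr__(self, "minute_index", idx)
        if idx.shape != values.shape:
            raise InputError("minute_index and values must have matching shapes")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InputError("activity values must be finite and non-negative")
        if idx.size > 1 and np.any(np.diff(idx) != 1):
            raise InputError("minute_index must be consecutive (no gaps)")

    @property
    def n_minutes(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class NormalizedSeries:
    """Activity as percent of a fish's stable pre-treatment median.

    ``time_min`` holds the start of each bin in minutes relative to the
    injection (pre-treatment times are negative); ``bin_width_min`` is 1.0 for
    an unbinned per-minute series.
    """

    values: np.ndarray
    time_min: np.ndarray
    bin_width_min: float = 1.0
    fish_id: str = "fish"
    group: str = ""

    def __post_init__(self):
        values = _as_float_array(self.values, "values")
        times = _as_float_array(self.time_min, "time_min")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "time_min", times)
        if values.shape != times.shape:
            raise InputError("values and time_min must have matching shapes")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise InputError("normalized values must be finite and non-negative")
        if self.bin_width_min <= 0:
            raise ParameterError("bin_width_min must be positive")
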