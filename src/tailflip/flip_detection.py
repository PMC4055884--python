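"""Tail-flip event detection from a sampled biosensor trace.

Processing chain, mirroring the biosensor's software:

1. zero-phase band-pass to the 0.2-40 Hz activity band,
2. automatic gain control (running robust-scale normalization), so detection
   thresholds stay valid under slow multiplicative gain drift,
3. sharpness detection: local maxima of the first-difference magnitude above
   an adaptive threshold (multiple of the local robust scale), separated by a
   refractory interval,
4. false-positive rejection: an accepted event must have at least one other
   candidate nearby, because real swimming comes in bursts of several flips;
   isolated spikes (artifacts) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InputError, ParameterError
from .types import ActivitySeries, FlipTrain, Trace

__all__ = [
    "DetectorConfig",
    "bandpass",
    "agc",
    "detect_flips",
    "counts_per_minute",
    "match_events",
]

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass(frozen=True)
class DetectorConfig:
    """Tuning of the detection chain.

    ``sharpness_threshold`` is a multiple of the local robust scale of the
    sharpness signal; ``refractory_s`` must stay below the 0.2 s minimum
    credible inter-flip interval (5 flips/s); ``burst_context_neighbors``
    candidates within ``burst_context_window_s`` are required to accept an
    event.
    """

    band_hz: tuple[float, float] = (0.2, 40.0)
    agc_window_s: float = 10.0
    sharpness_threshold: float = 4.0
    relative_floor: float = 0.08
    refractory_s: float = 0.15
    burst_context_neighbors: int = 1
    burst_context_window_s: float = 1.0
    preprocess: bool = True

    def __post_init__(self):
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ParameterError(f"band must satisfy 0 < low < high, got {self.band_hz}")
        if self.agc_window_s < 1.0:
            raise ParameterError("agc_window_s must be >= 1 s")
        if not (0 < self.refractory_s < 0.2):
            raise ParameterError("refractory_s must lie in (0, 0.2) s")
        if self.sharpness_threshold <= 0:
            raise ParameterError("sharpness_threshold must be positive")
        if self.burst_context_neighbors < 0:
            raise ParameterError("burst_context_neighbors must be >= 0")


def _bandpass_sos(band_hz: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band_hz
    if hi >= fs / 2.0:
        raise ParameterError(f"band_high ({hi} Hz) must be below the Nyquist frequency ({fs / 2} Hz)")
    # high-pass and low-pass cascade; zero-phase application doubles the order,
    # giving > 40 dB one octave below the low edge and sharp roll-off above.
    sos_hp = sps.butter(4, lo, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(8, hi, btype="lowpass", fs=fs, output="sos")
    return np.vstack([sos_hp, sos_lp])


def bandpass(trace: Trace, band_hz: tuple[float, float] = (0.2, 40.0)) -> Trace:
    """Zero-phase band-pass filter; event timing is not shifted."""
    sos = _bandpass_sos(band_hz, trace.sample_rate)
    if trace.samples.size < 50:
        raise InputError("trace too short to band-pass filter")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(filtered)


def _block_scale(x: np.ndarray, block: int) -> np.ndarray:
    """Per-sample robust scale (MAD * 1.4826), piecewise from blocks, interpolated."""
    n = x.size
    block = max(1, min(block, n))
    n_blocks = max(1, n // block)
    trimmed = x[: n_blocks * block].reshape(n_blocks, block)
    med = np.median(trimmed, axis=1, keepdims=True)
    mad = np.median(np.abs(trimmed - med), axis=1)
    scale = _MAD_TO_SD * mad
    if n_blocks == 1:
        return np.full(n, scale[0])
    centers = (np.arange(n_blocks) + 0.5) * block
    return np.interp(np.arange(n), centers, scale)


def agc(trace: Trace, window_s: float = 10.0) -> Trace:
    """Automatic gain control: divide by the running robust amplitude.

    The running scale is the median absolute deviation over ``window_s``
    blocks (linearly interpolated between block centres), so the output is
    invariant to constant and slow multiplicative rescaling.  Regions of zero
    amplitude map to zero rather than blowing up.
    """
    if window_s < 1.0:
        raise ParameterError("agc window must be >= 1 s")
    x = trace.samples
    if x.size == 0:
        return trace
    block = int(round(window_s * trace.sample_rate))
    scale = _block_scale(x, block)
    tiny = 1e-12 * max(float(np.max(np.abs(x))), 1.0)
    positive = scale[scale > tiny]
    if positive.size:
        # cap the amplification of quiet stretches relative to typical
        # activity; keeps the output scale-invariant (floor tracks the data)
        scale = np.maximum(scale, 0.1 * float(np.median(positive)))
    out = np.where(scale > tiny, x / np.where(scale > tiny, scale, 1.0), 0.0)
    return trace.with_samples(out)


def detect_flips(trace: Trace, cfg: DetectorConfig = DetectorConfig()) -> FlipTrain:
    """Recover tail-flip events from a trace.

    If ``cfg.preprocess`` the trace is band-passed and gain-controlled first.
    Events are local maxima of the first-difference magnitude exceeding
    ``sharpness_threshold`` times the local robust scale, separated by the
    refractory interval; candidates without burst context are rejected.
    """
    fs = trace.sample_rate
    if trace.duration_s < cfg.agc_window_s:
        raise InputError(
            f"trace ({trace.duration_s:.1f} s) is shorter than the AGC window ({cfg.agc_window_s} s)"
        )
    work = trace
    if cfg.preprocess:
        work = agc(bandpass(work, cfg.band_hz), cfg.agc_window_s)
    derivative = np.diff(work.samples)
    sharpness = np.abs(derivative)
    block = int(round(cfg.agc_window_s * fs))
    # scale of the signed derivative (median ~ 0), against which the
    # rectified sharpness is thresholded
    local_scale = _block_scale(derivative, block)
    # relative floor: filter ringing around a transient is ~2% of the main
    # peak, so a few-percent floor on the near-maximal sharpness rejects it
    # even when the local noise scale is degenerate (noise-free renders)
    global_floor = cfg.relative_floor * float(np.percentile(sharpness, 99.9)) if sharpness.size else 0.0
    height = np.maximum(cfg.sharpness_threshold * local_scale, global_floor)
    height = np.maximum(height, 1e-12)
    distance = max(1, int(round(cfg.refractory_s * fs)))
    peaks, _ = sps.find_peaks(sharpness, height=height, distance=distance)
    # sharpness[i] sits between samples i and i+1
    times = trace.t0 + (peaks + 0.5) / fs
    if cfg.burst_context_neighbors > 0 and times.size:
        w = cfg.burst_context_window_s
        left = np.searchsorted(times, times - w, side="left")
        right = np.searchsorted(times, times + w, side="right")
        neighbors = right - left - 1
        times = times[neighbors >= cfg.burst_context_neighbors]
    return FlipTrain(
        times,
        duration_min=trace.duration_s / 60.0,
        fish_id=trace.fish_id,
        phase=trace.phase,
        source="detected",
    )


def counts_per_minute(train: FlipTrain, span_min: float | None = None) -> ActivitySeries:
    """Bin a flip train into tail-flips per minute.

    The span defaults to the train's duration rounded up to whole minutes;
    the sum of counts always equals the number of events.
    """
    if span_min is None:
        span_min = math.ceil(train.duration_min)
    n_minutes = int(math.ceil(span_min))
    if n_minutes < 1:
        raise InputError("span must cover at least one minute")
    if train.event_times.size and train.event_times[-1] >= n_minutes * 60.0:
        raise InputError("events fall outside the requested span")
    counts, _ = np.histogram(train.event_times, bins=np.arange(n_minutes + 1) * 60.0)
    return ActivitySeries(
        counts.astype(float),
        phase=train.phase,
        fish_id=train.fish_id,
        metric="flips",
    )


def match_events(
    truth: FlipTrain, detected: FlipTrain, tolerance_s: float = 0.05
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected events to ground truth.

    Returns ``(n_matched, n_false_positive, n_missed)``; recall is
    ``matched / truth`` and precision ``matched / detected``.
    """
    t_truth = truth.event_times
    t_det = detected.event_times
    used = np.zeros(t_det.size, dtype=bool)
    matched = 0
    j = 0
    for t in t_truth:
        lo = np.searchsorted(t_det, t - tolerance_s, side="left")
        hi = np.searchsorted(t_det, t + tolerance_s, side="right")
        for j in range(lo, hi):
            if not used[j]:
                used[j] = True
                matched += 1
                break
    return matched, int(t_det.size - matched), int(t_truth.size - matched)
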