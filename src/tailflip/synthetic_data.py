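"""Ground-truthed synthetic fish behaviour.

The raw recordings behind the assay are not available, so this module stands
in for them with a generative model of zebrafish locomotion as seen by an
impedance biosensor:

* swimming happens in *bursts*: burst initiations follow an inhomogeneous
  Poisson process (bursts/min), each burst carries 1 + Poisson(mean - 1)
  tail-flips, and within a burst consecutive flips are 0.2-0.5 s apart
  (instantaneous rate 2-5 flips/s);
* each fish carries a lognormal activity gain (large between-fish differences
  in absolute activity), a fish-specific acclimation amplitude (fish are more
  active early in the baseline recording and settle exponentially), and a
  lognormal post-treatment response multiplier;
* treatments act through a multiplicative *effect curve* over time since
  injection (logistic onset to an asymptote, optional late drift);
* the measurement channel adds a biphasic transient per flip, white noise,
  slow multiplicative gain drift and sporadic isolated artifacts.

Every public generator accepts either a seed or a ``numpy.random.Generator``
and is bit-reproducible.  Study-level simulation uses hierarchical seed
spawning so each fish owns an independent stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DesignError, ParameterError
from .types import ActivitySeries, FlipTrain, Phase, Trace

__all__ = [
    "EffectCurve",
    "BehaviorProfile",
    "MeasurementModel",
    "Timeline",
    "GroupSpec",
    "StudyDesign",
    "FishState",
    "FishRecord",
    "DOSING_GROUPS",
    "DEFAULT_PROFILE",
    "profile_for_group",
    "draw_fish_state",
    "simulate_flip_train",
    "render_trace",
    "simulate_trajectory",
    "simulate_study",
    "minute_count_matrix",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_sigma_mu(cv: float) -> tuple[float, float]:
    """(sigma, mu) of a lognormal with mean 1 and the given coefficient of variation."""
    sigma2 = math.log1p(cv * cv)
    return math.sqrt(sigma2), -0.5 * sigma2


def _unit_lognormal(rng: np.random.Generator, cv, size=None) -> np.ndarray:
    """Mean-1 lognormal draws; ``cv`` may be scalar or array (broadcast over size)."""
    cv = np.asarray(cv, dtype=float)
    if np.all(cv == 0):
        return np.ones(size if size is not None else cv.shape)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    z = rng.standard_normal(size if size is not None else cv.shape)
    return np.exp(sigma * z - 0.5 * sigma2)


# --------------------------------------------------------------------------
# parameterization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectCurve:
    """Multiplicative activity factor as a function of time since injection.

    The factor runs from 1 (no effect) through a logistic onset centred at
    ``onset_min`` to ``asymptote``; ``late_slope_per_min`` adds a linear drift
    after ``late_onset_min`` (used for dose profiles that only separate late
    in the recording).  The factor is clipped at zero.
    """

    asymptote: float = 1.0
    onset_min: float = 10.0
    onset_scale_min: float = 4.0
    late_slope_per_min: float = 0.0
    late_onset_min: float = 60.0

    def __post_init__(self):
        if not np.isfinite(self.asymptote) or self.asymptote < 0:
            raise ParameterError(f"asymptote must be finite and >= 0, got {self.asymptote}")
        if self.onset_scale_min <= 0:
            raise ParameterError("onset_scale_min must be positive")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        f = 1.0 - (1.0 - self.asymptote) * expit((t - self.onset_min) / self.onset_scale_min)
        if self.late_slope_per_min != 0.0:
            f = f + self.late_slope_per_min * np.clip(t - self.late_onset_min, 0.0, None)
        return np.clip(f, 0.0, None)

    @classmethod
    def constant(cls, level: float) -> "EffectCurve":
        """A flat effect: factor == ``level`` for all post-injection times."""
        return cls(asymptote=level, onset_min=-1e6, onset_scale_min=1.0)


@dataclass(frozen=True)
class BehaviorProfile:
    """Statistical description of one treatment group's behaviour.

    Parameters
    ----------
    baseline_burst_rate
        Expected burst initiations per minute at the stable baseline,
        averaged across fish.
    flip_interval_s
        (low, high) bounds of within-burst inter-flip intervals in seconds;
        the default (0.2, 0.5) corresponds to 2-5 tail-flips/s.
    flips_per_burst_mean
        Mean flips per burst; burst sizes are 1 + Poisson(mean - 1).
    acclimation_trend
        Fractional elevation of activity at the start of the baseline
        recording relative to the stable level (population mean).
    acclimation_tau_min
        Exponential decay time constant of the acclimation elevation, minutes.
    acclimation_trend_cv
        Between-fish lognormal cv of the acclimation amplitude.
    early_noise_inflation
        Factor by which the within-fish per-minute noise cv is inflated at
        the very start of the baseline; decays with ``acclimation_tau_min``.
    effect_curve
        Post-injection multiplicative effect.
    between_fish_cv
        Lognormal cv of the per-fish activity gain (applied to both phases).
    within_fish_noise_cv
        Lognormal cv of the minute-to-minute rate modulation within a fish.
    post_response_cv
        Lognormal cv of a fish-level post-treatment response multiplier
        (day-to-day state change between the two phases).
    """

    baseline_burst_rate: float = 15.0
    flip_interval_s: tuple[float, float] = (0.2, 0.5)
    flips_per_burst_mean: float = 6.0
    acclimation_trend: float = 0.6
    acclimation_tau_min: float = 12.0
    acclimation_trend_cv: float = 0.5
    early_noise_inflation: float = 2.0
    effect_curve: EffectCurve = field(default_factory=EffectCurve)
    between_fish_cv: float = 0.5
    within_fish_noise_cv: float = 0.15
    post_response_cv: float = 0.05

    def __post_init__(self):
        scalars = {
            "baseline_burst_rate": self.baseline_burst_rate,
            "flips_per_burst_mean": self.flips_per_burst_mean,
            "acclimation_trend": self.acclimation_trend,
            "acclimation_tau_min": self.acclimation_tau_min,
            "acclimation_trend_cv": self.acclimation_trend_cv,
            "early_noise_inflation": self.early_noise_inflation,
            "between_fish_cv": self.between_fish_cv,
            "within_fish_noise_cv": self.within_fish_noise_cv,
            "post_response_cv": self.post_response_cv,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value}")
        if self.baseline_burst_rate < 0:
            raise ParameterError("baseline_burst_rate must be >= 0")
        if self.flips_per_burst_mean < 1:
            raise ParameterError("flips_per_burst_mean must be >= 1")
        lo, hi = self.flip_interval_s
        if not (0 < lo <= hi):
            raise ParameterError(f"flip_interval_s bounds must satisfy 0 < low <= high, got {self.flip_interval_s}")
        if self.acclimation_tau_min <= 0:
            raise ParameterError("acclimation_tau_min must be positive")
        for name in ("acclimation_trend_cv", "between_fish_cv", "within_fish_noise_cv", "post_response_cv"):
            if scalars[name] < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.early_noise_inflation < 1:
            raise ParameterError("early_noise_inflation must be >= 1")

    def acclimation_factor(self, t_min, trend_amp: float | None = None) -> np.ndarray:
        """Activity factor during the baseline, ``1 + A * exp(-t/tau)``."""
        amp = self.acclimation_trend if trend_amp is None else trend_amp
        t = np.asarray(t_min, dtype=float)
        return 1.0 + amp * np.exp(-t / self.acclimation_tau_min)

    def noise_cv(self, t_min, phase: Phase) -> np.ndarray:
        """Per-minute lognormal modulation cv; inflated early in the baseline."""
        t = np.asarray(t_min, dtype=float)
        if phase == "pre":
            infl = 1.0 + (self.early_noise_inflation - 1.0) * np.exp(-t / self.acclimation_tau_min)
        else:
            infl = np.ones_like(t)
        return self.within_fish_noise_cv * infl


@dataclass(frozen=True)
class MeasurementModel:
    """Forward model of the biosensor channel (demodulated, 100 Hz)."""

    sample_rate: float = 100.0
    kernel_width_s: float = 0.04
    kernel_amplitude: float = 1.0
    noise_sd: float = 0.1
    gain_drift_amplitude: float = 0.3
    gain_drift_period_min: float = 10.0
    artifact_rate_per_min: float = 0.5
    artifact_amplitude: float = 4.0

    def __post_init__(self):
        if self.sample_rate <= 80.0:
            # must support the 0.2-40 Hz analysis band
            raise ParameterError("sample_rate must exceed twice the 40 Hz band edge")
        if self.kernel_width_s <= 0 or 1.0 / self.kernel_width_s < 20.0:
            raise ParameterError(
                "kernel_width_s must be positive and short enough that the flip "
                "transient has spectral content beyond 20 Hz (width <= 50 ms)"
            )
        for name in ("noise_sd", "gain_drift_amplitude", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def kernel(self) -> np.ndarray:
        """Biphasic flip transient: one full sine cycle of the given width."""
        n = max(2, int(round(self.kernel_width_s * self.sample_rate)))
        return self.kernel_amplitude * np.sin(2.0 * np.pi * (np.arange(n) + 0.5) / n)


@dataclass(frozen=True)
class Timeline:
    """Recording timeline in minutes (chamber acclimation, baseline, recovery, post)."""

    acclimation_min: float = 30.0
    baseline_min: float = 60.0
    recovery_min: float = 30.0
    post_min: float = 80.0

    def __post_init__(self):
        for name in ("acclimation_min", "baseline_min", "recovery_min", "post_min"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0")

    @property
    def post_span_min(self) -> float:
        """Total time from injection to the end of recording (default 110 min)."""
        return self.recovery_min + self.post_min


@dataclass(frozen=True)
class GroupSpec:
    label: str
    profile: BehaviorProfile
    n_fish: int


@dataclass(frozen=True)
class StudyDesign:
    """A whole study: treatment groups, timeline, binning, master seed."""

    groups: tuple[GroupSpec, ...]
    timeline: Timeline = field(default_factory=Timeline)
    bin_width_min: float = 15.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise DesignError(f"duplicate group labels: {labels}")
        for g in self.groups:
            if g.n_fish < 1:
                raise DesignError(f"group {g.label!r} must have n_fish >= 1")
        if self.bin_width_min <= 0:
            raise ParameterError("bin_width_min must be positive")


@dataclass(frozen=True)
class FishState:
    """Per-fish latent variables, drawn once and shared by both phases."""

    gain: float  # lognormal activity multiplier
    trend_amp: float  # fish-specific acclimation amplitude
    response: float  # lognormal post-phase response multiplier


def draw_fish_state(profile: BehaviorProfile, rng) -> FishState:
    rng = _rng(rng)
    gain = float(_unit_lognormal(rng, profile.between_fish_cv, size=()))
    trend = profile.acclimation_trend * float(
        _unit_lognormal(rng, profile.acclimation_trend_cv, size=())
    )
    response = float(_unit_lognormal(rng, profile.post_response_cv, size=()))
    return FishState(gain=gain, trend_amp=trend, response=response)


# Default effect levels for the dosing-scheme group labels.  Asymptotes follow
# the reported activity levels: strong, stable suppression under 10% acid,
# intermediate under 5% acid, partial saline recovery, morphine attenuation of
# the acid response to ~70% (with the low dose drifting down late in the
# recording), and a naloxone block returning activity close to acid alone.
DOSING_GROUPS: dict[str, EffectCurve] = {
    "saline": EffectCurve(asymptote=0.85),
    "acid_5pct": EffectCurve(asymptote=0.62),
    "acid_10pct": EffectCurve(asymptote=0.45),
    "saline_im+acid_10pct": EffectCurve(asymptote=0.45),
    "morphine_3mg+acid_10pct": EffectCurve(asymptote=0.70, late_slope_per_min=-0.003),
    "morphine_6mg+acid_10pct": EffectCurve(asymptote=0.70),
    "morphine_3mg+saline": EffectCurve(asymptote=0.90),
    "saline+saline": EffectCurve(asymptote=0.95),
    "morphine_6mg+naloxone+acid_10pct": EffectCurve(asymptote=0.50),
    "morphine_6mg+saline_im+acid_10pct": EffectCurve(asymptote=0.70),
}

DEFAULT_PROFILE = BehaviorProfile()


def profile_for_group(label: str, base: BehaviorProfile = DEFAULT_PROFILE) -> BehaviorProfile:
    """The default profile with the named dosing group's effect curve."""
    try:
        curve = DOSING_GROUPS[label]
    except KeyError:
        raise DesignError(f"unknown dosing group {label!r}; known: {sorted(DOSING_GROUPS)}") from None
    return replace(base, effect_curve=curve)


# --------------------------------------------------------------------------
# per-minute count core (shared by the event-level and series-level paths)
# --------------------------------------------------------------------------


_MIN_INTERBURST_GAP_S = 0.3  # pause between consecutive bursts of one fish


def _minute_times(n_minutes: int) -> np.ndarray:
    """Minute mid-points in minutes since the start of the phase recording."""
    return np.arange(n_minutes) + 0.5


def _minute_burst_rates(
    profile: BehaviorProfile,
    states: FishState | Sequence[FishState],
    phase: Phase,
    n_minutes: int,
    rng: np.random.Generator,
    start_after_injection_min: float = 30.0,
) -> np.ndarray:
    """Stochastic per-minute burst rates, shape (n_fish, n_minutes)."""
    single = isinstance(states, FishState)
    state_list = [states] if single else list(states)
    gains = np.array([s.gain for s in state_list])
    t_local = _minute_times(n_minutes)
    if phase == "pre":
        amps = np.array([s.trend_amp for s in state_list])
        mod = 1.0 + amps[:, None] * np.exp(-t_local / profile.acclimation_tau_min)[None, :]
    else:
        t_inj = start_after_injection_min + t_local
        responses = np.array([s.response for s in state_list])
        mod = responses[:, None] * profile.effect_curve(t_inj)[None, :]
    cv = profile.noise_cv(t_local, phase)[None, :]
    noise = _unit_lognormal(rng, np.broadcast_to(cv, (len(state_list), n_minutes)))
    return profile.baseline_burst_rate * gains[:, None] * mod * noise


def _counts_from_bursts(bursts: np.ndarray, mean_flips: float, rng: np.random.Generator) -> np.ndarray:
    """Total flips given burst counts: burst sizes are 1 + Poisson(mean - 1).

    A sum of B iid such sizes is B plus Poisson(B * (mean - 1)), which lets
    the whole array be drawn at once.
    """
    flips = bursts.astype(np.int64).copy()
    if mean_flips > 1.0:
        flips += rng.poisson(bursts * (mean_flips - 1.0))
    return flips


def minute_count_matrix(
    profile: BehaviorProfile,
    states: Sequence[FishState],
    phase: Phase,
    n_minutes: int,
    rng,
    start_after_injection_min: float = 30.0,
) -> np.ndarray:
    """Ground-truth tail-flip counts per minute, shape (n_fish, n_minutes).

    This is the series-level view of the same burst process that
    :func:`simulate_flip_train` realizes event by event (bursts attributed to
    the minute they start in).
    """
    rng = _rng(rng)
    rates = _minute_burst_rates(profile, states, phase, n_minutes, rng, start_after_injection_min)
    bursts = rng.poisson(rates)
    return _counts_from_bursts(bursts, profile.flips_per_burst_mean, rng)


# --------------------------------------------------------------------------
# event-level generation
# --------------------------------------------------------------------------


def _simulate_bursts(
    profile: BehaviorProfile,
    duration_min: float,
    phase: Phase,
    rng,
    state: FishState | None = None,
    start_after_injection_min: float = 30.0,
) -> list[np.ndarray]:
    """Simulate burst event times; returns one sorted time array per burst (seconds)."""
    rng = _rng(rng)
    if not np.isfinite(duration_min) or duration_min <= 0:
        raise ParameterError(f"duration_min must be positive and finite, got {duration_min}")
    if state is None:
        state = draw_fish_state(profile, rng)
    n_minutes = int(math.ceil(duration_min))
    rates = _minute_burst_rates(profile, state, phase, n_minutes, rng, start_after_injection_min)[0]
    # truncate the final (possibly partial) minute's rate proportionally
    last_frac = duration_min - (n_minutes - 1)
    rates = rates.copy()
    rates[-1] *= last_frac
    bursts_per_min = rng.poisson(rates)
    total_bursts = int(bursts_per_min.sum())
    if total_bursts == 0:
        return []
    minute_of_burst = np.repeat(np.arange(n_minutes), bursts_per_min)
    widths = np.where(minute_of_burst == n_minutes - 1, last_frac, 1.0)
    starts = np.sort((minute_of_burst + widths * rng.uniform(size=total_bursts)) * 60.0)
    flips = 1 + rng.poisson(profile.flips_per_burst_mean - 1.0, size=total_bursts)
    lo, hi = profile.flip_interval_s
    intervals = rng.uniform(lo, hi, size=int(flips.sum()))
    seg_start = np.cumsum(flips) - flips
    durations = np.add.reduceat(intervals, seg_start) - intervals[seg_start]
    # a fish has one tail: bursts are sequential.  Queue each burst no earlier
    # than the previous burst's end plus a short inter-burst gap.
    occupied = durations + _MIN_INTERBURST_GAP_S
    shifted = np.maximum.accumulate(starts - (np.cumsum(occupied) - occupied))
    starts = shifted + (np.cumsum(occupied) - occupied)
    intervals[seg_start] = starts  # first entry of each burst = absolute start time
    csum = np.cumsum(intervals)
    base = csum[seg_start] - intervals[seg_start]
    times = csum - np.repeat(base, flips)
    return list(np.split(times, seg_start[1:]))


def simulate_flip_train(
    profile: BehaviorProfile,
    duration_min: float,
    phase: Phase = "pre",
    seed=None,
    state: FishState | None = None,
    start_after_injection_min: float = 30.0,
    fish_id: str = "fish",
) -> FlipTrain:
    """Simulate ground-truth tail-flip times for one fish over one phase.

    Burst initiations follow an inhomogeneous Poisson process whose rate is
    ``baseline_burst_rate`` times the acclimation (pre) or effect (post)
    modulation and the fish/minute noise multipliers; bursts carry a shifted-Poisson
    number of flips with inter-flip intervals uniform on ``flip_interval_s``.
    """
    rng = _rng(seed)
    bursts = _simulate_bursts(profile, duration_min, phase, rng, state, start_after_injection_min)
    if not bursts:
        return FlipTrain(np.empty(0), duration_min, fish_id=fish_id, phase=phase)
    times = np.sort(np.concatenate(bursts))
    times = times[times < duration_min * 60.0]
    if times.size > 1:
        # overlapping bursts can collide; nudge ties to keep strict ordering
        eps = 1e-9
        times = np.maximum.accumulate(times + eps * np.arange(times.size))
        times = times[times < duration_min * 60.0]
    return FlipTrain(times, duration_min, fish_id=fish_id, phase=phase)


def render_trace(
    train: FlipTrain,
    mm: MeasurementModel = MeasurementModel(),
    seed=None,
    duration_min: float | None = None,
    min_event_gap_s: float = 0.2,
) -> Trace:
    """Forward-model a flip train into a sampled biosensor trace.

    Each flip stamps a biphasic transient centred at the event time; white
    noise is added, a slow sinusoidal multiplicative gain drift is applied to
    the whole channel, and sporadic isolated spike artifacts are injected.
    The ground-truth event log (the input train) is unaffected by any of the
    measurement parameters.

    ``min_event_gap_s`` is the smallest within-burst inter-flip interval the
    flip kernel must resolve (0.2 s at the maximal 5 flips/s); a kernel wider
    than this is a configuration error.  Transients of concurrent bursts may
    still overlap and simply superpose.
    """
    rng = _rng(seed)
    duration_min = train.duration_min if duration_min is None else duration_min
    if train.event_times.size and train.event_times[-1] > duration_min * 60.0:
        raise ConfigurationError("train extends beyond the requested trace duration")
    if mm.kernel_width_s > min_event_gap_s:
        raise ConfigurationError(
            f"flip kernel ({mm.kernel_width_s} s) is wider than the minimum "
            f"inter-flip interval it must resolve ({min_event_gap_s} s)"
        )
    n = int(round(duration_min * 60.0 * mm.sample_rate))
    signal = np.zeros(n)
    kernel = mm.kernel()
    half = kernel.size // 2
    if train.event_times.size:
        starts = np.clip(
            np.round(train.event_times * mm.sample_rate).astype(int) - half,
            0,
            n - kernel.size,
        )
        idx = starts[:, None] + np.arange(kernel.size)[None, :]
        np.add.at(signal, idx.ravel(), np.tile(kernel, starts.size))
    if mm.noise_sd > 0:
        signal = signal + rng.normal(0.0, mm.noise_sd, n)
    if mm.gain_drift_amplitude > 0:
        t = np.arange(n) / mm.sample_rate
        phase_offset = rng.uniform(0.0, 2.0 * np.pi)
        gain = 1.0 + mm.gain_drift_amplitude * np.sin(
            2.0 * np.pi * t / (mm.gain_drift_period_min * 60.0) + phase_offset
        )
        signal = gain * signal
    if mm.artifact_rate_per_min > 0:
        n_art = rng.poisson(mm.artifact_rate_per_min * duration_min)
        if n_art:
            pos = rng.integers(0, n, size=n_art)
            amp = mm.artifact_amplitude * rng.uniform(0.5, 1.5, n_art) * rng.choice([-1.0, 1.0], n_art)
            signal[pos] += amp
    return Trace(signal, sample_rate=mm.sample_rate, phase=train.phase, fish_id=train.fish_id)


def simulate_trajectory(
    profile: BehaviorProfile,
    duration_min: float = 1.0,
    fps: float = 10.0,
    arena_mm: tuple[float, float] = (90.0, 80.0),
    phase: Phase = "pre",
    seed=None,
    state: FishState | None = None,
    speed_scale_mm_s: float = 25.0,
    start_after_injection_min: float = 30.0,
) -> np.ndarray:
    """Simulate a 2-D centroid trajectory in a rectangular arena.

    Returns positions in mm, shape ``(n_frames, 2)``, ``n_frames = fps *
    duration * 60``.  The fish performs a correlated random walk whose step
    length scales with the current activity factor (acclimation or effect
    modulation times the fish gain relative to the default burst rate), with
    reflecting walls.
    """
    rng = _rng(seed)
    w, h = arena_mm
    if w <= 0 or h <= 0:
        raise ParameterError(f"arena dimensions must be positive, got {arena_mm}")
    n_frames_f = fps * duration_min * 60.0
    n_frames = int(round(n_frames_f))
    if abs(n_frames_f - n_frames) > 1e-9 or n_frames < 1:
        raise ParameterError("fps * duration must give an integer frame count")
    if state is None:
        state = draw_fish_state(profile, rng)
    t_min = np.arange(n_frames) / (fps * 60.0)
    if phase == "pre":
        mod = profile.acclimation_factor(t_min, state.trend_amp)
    else:
        mod = state.response * profile.effect_curve(start_after_injection_min + t_min)
    activity = (profile.baseline_burst_rate / DEFAULT_PROFILE.baseline_burst_rate) * state.gain * mod
    # burst-like speed envelope: lognormal minute-scale modulation, frame jitter
    envelope = np.abs(rng.standard_normal(n_frames)) * np.sqrt(np.pi / 2.0)
    speed = speed_scale_mm_s * activity * envelope  # mm/s per frame
    headings = np.cumsum(rng.normal(0.0, 0.6, n_frames))
    steps = (speed / fps)[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    pos = np.empty((n_frames, 2))
    pos[0] = [w / 2.0, h / 2.0]
    cur = pos[0].copy()
    bounds = np.array([w, h])
    for i in range(1, n_frames):
        cur = cur + steps[i]
        # reflect at the walls
        for d in range(2):
            if cur[d] < 0:
                cur[d] = -cur[d]
            elif cur[d] > bounds[d]:
                cur[d] = 2 * bounds[d] - cur[d]
            cur[d] = min(max(cur[d], 0.0), bounds[d])
        pos[i] = cur
    return pos


# --------------------------------------------------------------------------
# whole studies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FishRecord:
    """Everything generated for one fish: data at the requested fidelity plus truth."""

    fish_id: str
    group: str
    state: FishState
    pre_counts: ActivitySeries
    post_counts: ActivitySeries
    pre_train: FlipTrain | None = None
    post_train: FlipTrain | None = None
    pre_trace: Trace | None = None
    post_trace: Trace | None = None


Fidelity = Literal["counts", "events", "trace"]


def simulate_study(
    design: StudyDesign,
    fidelity: Fidelity = "counts",
    measurement: MeasurementModel | None = None,
) -> list[FishRecord]:
    """Simulate a whole study under the given design.

    Fidelity levels: ``"counts"`` draws ground-truth per-minute flip counts
    directly (fastest); ``"events"`` realizes full flip trains and counts them;
    ``"trace"`` additionally renders biosensor traces (the counts remain the
    ground truth -- run the detector on the traces to get measured counts).

    Seeds are hierarchical (study seed -> per-fish streams), so records are
    bit-reproducible and adding a group does not perturb earlier groups.
    """
    mm = measurement or MeasurementModel()
    tl = design.timeline
    n_pre = int(round(tl.baseline_min))
    n_post = int(round(tl.post_min))
    root = np.random.SeedSequence(design.seed)
    group_seeds = root.spawn(len(design.groups))
    records: list[FishRecord] = []
    for gspec, gseed in zip(design.groups, group_seeds):
        for k, fseed in enumerate(gseed.spawn(gspec.n_fish)):
            rng = np.random.default_rng(fseed)
            state = draw_fish_state(gspec.profile, rng)
            fish_id = f"{gspec.label}_{k:02d}"
            if fidelity == "counts":
                pre_counts = minute_count_matrix(gspec.profile, [state], "pre", n_pre, rng)[0]
                post_counts = minute_count_matrix(
                    gspec.profile, [state], "post", n_post, rng, tl.recovery_min
                )[0]
                pre_train = post_train = None
                pre_trace = post_trace = None
            else:
                pre_train = simulate_flip_train(
                    gspec.profile, tl.baseline_min, "pre", rng, state, fish_id=fish_id
                )
                post_train = simulate_flip_train(
                    gspec.profile,
                    tl.post_min,
                    "post",
                    rng,
                    state,
                    start_after_injection_min=tl.recovery_min,
                    fish_id=fish_id,
                )
                pre_counts = np.histogram(
                    pre_train.event_times, bins=np.arange(n_pre + 1) * 60.0
                )[0]
                post_counts = np.histogram(
                    post_train.event_times, bins=np.arange(n_post + 1) * 60.0
                )[0]
                if fidelity == "trace":
                    pre_trace = render_trace(pre_train, mm, rng)
                    post_trace = render_trace(post_train, mm, rng)
                else:
                    pre_trace = post_trace = None
            records.append(
                FishRecord(
                    fish_id=fish_id,
                    group=gspec.label,
                    state=state,
                    pre_counts=ActivitySeries(
                        np.asarray(pre_counts, float), phase="pre", fish_id=fish_id
                    ),
                    post_counts=ActivitySeries(
                        np.asarray(post_counts, float), phase="post", fish_id=fish_id
                    ),
                    pre_train=pre_train,
                    post_train=post_train,
                    pre_trace=pre_trace,
                    post_trace=post_trace,
                )
            )
    return records
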