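"""Study-level characterization analyses.

These functions chain the generator, normalization and robust summaries into
the numeric twins of the assay's characterization figures: the pre-treatment
acclimation profile of a baseline cohort (early elevation and early/late
error-bar ratio), the recovery level of a morphine + acid group at the end of
the recording, and per-group normalized recording-period matrices for power
simulations.  They are used by the test-suite and the acceptance script and
are convenient entry points for exploring the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import robust_stats
from .activity_metrics import bin_series, normalize, stable_window
from .errors import NormalizationError
from .flip_detection import DetectorConfig, counts_per_minute, detect_flips
from .synthetic_data import (
    DEFAULT_PROFILE,
    BehaviorProfile,
    FishState,
    MeasurementModel,
    Timeline,
    draw_fish_state,
    minute_count_matrix,
    profile_for_group,
    render_trace,
    simulate_flip_train,
)

__all__ = [
    "BaselineCohortMetrics",
    "simulate_pre_normalized",
    "baseline_cohort_metrics",
    "simulate_group_bins",
    "final_bin_recovery",
]

STABLE_WINDOW_MIN = 20


def _states(profile: BehaviorProfile, n_fish: int, rng: np.random.Generator) -> list[FishState]:
    return [draw_fish_state(profile, rng) for _ in range(n_fish)]


def simulate_pre_normalized(
    profile: BehaviorProfile,
    n_fish: int,
    rng,
    baseline_min: int = 60,
    stable_min: int = STABLE_WINDOW_MIN,
) -> np.ndarray:
    """Normalized pre-treatment minutes for a cohort, shape ``(n_fish, baseline_min)``.

    Each fish's per-minute ground-truth flip counts are divided by the median
    of its last ``stable_min`` minutes and expressed in percent.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = _states(profile, n_fish, rng)
    counts = minute_count_matrix(profile, states, "pre", baseline_min, rng)
    baseline = np.median(counts[:, -stable_min:], axis=1)
    if np.any(baseline <= 0):
        raise NormalizationError("a fish's stable-window median is zero; raise the burst rate")
    return 100.0 * counts / baseline[:, None]


@dataclass(frozen=True)
class BaselineCohortMetrics:
    """Acclimation summary of a synthetic baseline cohort."""

    early_elevation_pct: float  # Winsorized mean of early normalized activity minus 100
    se_ratio: float  # Winsorized SE, first bin vs stable window
    n_fish: int
    n_replicates: int


def baseline_cohort_metrics(
    n_fish: int = 27,
    n_replicates: int = 20,
    seed=1,
    profile: BehaviorProfile = DEFAULT_PROFILE,
    early_span_min: int = 40,
    first_bin_min: int = 5,
    stable_min: int = STABLE_WINDOW_MIN,
    gamma: float = 0.10,
) -> BaselineCohortMetrics:
    """Early-baseline elevation and error-bar heteroscedasticity of a cohort.

    For each replicate cohort of ``n_fish`` pre-treatment recordings (60 min):

    * *early elevation*: the Winsorized mean (across fish) of per-fish mean
      normalized activity over the first ``early_span_min`` minutes, minus
      100 -- the percent by which early activity exceeds the stable level,
      i.e. the size of the settling decline;
    * *SE ratio*: Winsorized standard error across fish of the first
      ``first_bin_min``-minute bin divided by that of the stable-window
      values.

    Both are averaged over replicates.
    """
    rng = np.random.default_rng(seed)
    elevations, ratios = [], []
    for _ in range(n_replicates):
        norm = simulate_pre_normalized(profile, n_fish, rng, stable_min=stable_min)
        early_means = norm[:, :early_span_min].mean(axis=1)
        elevations.append(robust_stats.winsorized_mean(early_means, gamma) - 100.0)
        first_bin = norm[:, :first_bin_min].mean(axis=1)
        stable_vals = norm[:, -stable_min:].mean(axis=1)
        ratios.append(
            robust_stats.winsorized_se(first_bin, gamma)
            / robust_stats.winsorized_se(stable_vals, gamma)
        )
    return BaselineCohortMetrics(
        early_elevation_pct=float(np.mean(elevations)),
        se_ratio=float(np.mean(ratios)),
        n_fish=n_fish,
        n_replicates=n_replicates,
    )


def simulate_group_bins(
    profile: BehaviorProfile,
    n_fish: int,
    rng,
    timeline: Timeline = Timeline(),
    bin_width_min: int = 15,
    stable_min: int = STABLE_WINDOW_MIN,
) -> np.ndarray:
    """Normalized recording-period values for one group, shape ``(n_fish, n_bins)``.

    Series-level chain (ground-truth counts, detector bypassed): simulate the
    baseline and post recordings, normalize each fish to its stable-window
    median, and average post minutes into full bins; the trailing partial bin
    is dropped.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = _states(profile, n_fish, rng)
    n_pre = int(round(timeline.baseline_min))
    n_post = int(round(timeline.post_min))
    pre = minute_count_matrix(profile, states, "pre", n_pre, rng)
    post = minute_count_matrix(profile, states, "post", n_post, rng, timeline.recovery_min)
    baseline = np.median(pre[:, -stable_min:], axis=1)
    if np.any(baseline <= 0):
        raise NormalizationError("a fish's stable-window median is zero; raise the burst rate")
    norm = 100.0 * post / baseline[:, None]
    n_bins = n_post // bin_width_min
    used = n_bins * bin_width_min
    return norm[:, :used].reshape(n_fish, n_bins, bin_width_min).mean(axis=2)


def final_bin_recovery(
    group: str = "morphine_6mg+acid_10pct",
    n_fish: int = 9,
    n_replicates: int = 20,
    seed=11,
    timeline: Timeline = Timeline(),
    bin_width_min: float = 15.0,
    measurement: MeasurementModel | None = None,
    detector: DetectorConfig | None = None,
    gamma: float = 0.10,
) -> float:
    """Final-bin Winsorized mean of normalized activity via the full chain.

    Each fish is simulated event-by-event, rendered into biosensor traces for
    both phases, run through band-pass / AGC / sharpness detection, counted
    per minute, normalized to its stable pre-treatment median and binned;
    the Winsorized mean of the last full bin across fish is averaged over
    replicates.  Returns percent of baseline.
    """
    profile = profile_for_group(group)
    mm = measurement or MeasurementModel()
    cfg = detector or DetectorConfig()
    root = np.random.SeedSequence(seed)
    rep_values = []
    for rep_seed in root.spawn(n_replicates):
        rng = np.random.default_rng(rep_seed)
        finals = []
        for _ in range(n_fish):
            state = draw_fish_state(profile, rng)
            pre_train = simulate_flip_train(profile, timeline.baseline_min, "pre", rng, state)
            post_train = simulate_flip_train(
                profile,
                timeline.post_min,
                "post",
                rng,
                state,
                start_after_injection_min=timeline.recovery_min,
            )
            pre_counts = counts_per_minute(detect_flips(render_trace(pre_train, mm, rng), cfg))
            post_counts = counts_per_minute(detect_flips(render_trace(post_train, mm, rng), cfg))
            sw = stable_window(pre_counts, STABLE_WINDOW_MIN)
            ns = normalize(post_counts, sw.median, time_offset_min=timeline.recovery_min)
            binned = bin_series(ns, bin_width_min)
            finals.append(binned.values[-1])
        rep_values.append(robust_stats.winsorized_mean(finals, gamma))
    return float(np.mean(rep_values))
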