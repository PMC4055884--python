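"""Generator contracts: point-process structure, determinism, forward model."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from tailflip.errors import ConfigurationError, DesignError, ParameterError
from tailflip.synthetic_data import (
    DEFAULT_PROFILE,
    BehaviorProfile,
    EffectCurve,
    FlipTrain,
    GroupSpec,
    MeasurementModel,
    StudyDesign,
    _simulate_bursts,
    minute_count_matrix,
    profile_for_group,
    render_trace,
    simulate_flip_train,
    simulate_study,
    simulate_trajectory,
)

QUIET = MeasurementModel(noise_sd=0.0, gain_drift_amplitude=0.0, artifact_rate_per_min=0.0)


def constant_rate_profile(rate=10.0, **overrides) -> BehaviorProfile:
    """No trend, no noise sources: a homogeneous burst process."""
    kwargs = dict(
        baseline_burst_rate=rate,
        acclimation_trend=0.0,
        acclimation_trend_cv=0.0,
        early_noise_inflation=1.0,
        between_fish_cv=0.0,
        within_fish_noise_cv=0.0,
        post_response_cv=0.0,
    )
    kwargs.update(overrides)
    return BehaviorProfile(**kwargs)


def test_zero_rate_gives_empty_train():
    train = simulate_flip_train(constant_rate_profile(0.0), 10.0, seed=0)
    assert train.n_events == 0


def test_nonfinite_parameters_rejected():
    with pytest.raises(ParameterError):
        BehaviorProfile(baseline_burst_rate=np.nan)
    with pytest.raises(ParameterError):
        BehaviorProfile(flip_interval_s=(0.0, 0.5))
    with pytest.raises(ParameterError):
        simulate_flip_train(DEFAULT_PROFILE, -1.0, seed=0)


def test_mean_flip_count_matches_closed_form():
    """Monte-Carlo mean over 200 seeds vs rate * duration * E[flips/burst]."""
    profile = constant_rate_profile(rate=10.0)
    duration = 5.0
    totals = [
        simulate_flip_train(profile, duration, seed=s).n_events for s in range(200)
    ]
    expected = profile.baseline_burst_rate * duration * profile.flips_per_burst_mean
    # per-simulation variance of a Poisson cluster process: rate*T*E[F^2]
    mean_flips = profile.flips_per_burst_mean
    ef2 = (mean_flips - 1) + mean_flips**2  # var(F) + E[F]^2 for 1+Poisson(mean-1)
    sim_sd = np.sqrt(profile.baseline_burst_rate * duration * ef2)
    ci99 = 2.58 * sim_sd / np.sqrt(len(totals))
    # allow a small deficit from bursts clipped at the recording end
    edge_allowance = mean_flips
    assert abs(np.mean(totals) - expected) < ci99 + edge_allowance


def test_within_burst_intervals_match_species_flip_rate(rng):
    bursts = _simulate_bursts(DEFAULT_PROFILE, 10.0, "pre", rng)
    assert len(bursts) > 10
    for burst in bursts:
        if burst.size > 1:
            gaps = np.diff(burst)
            assert gaps.min() >= 0.2 - 1e-9 and gaps.max() <= 0.5 + 1e-9


def test_bursts_are_serialized(rng):
    """A fish has one tail: consecutive events never collide."""
    train = simulate_flip_train(DEFAULT_PROFILE, 20.0, seed=rng)
    gaps = np.diff(train.event_times)
    assert gaps.min() > 0.15  # detector-resolvable by construction


def test_event_times_strictly_increasing_and_in_span():
    for seed in range(5):
        train = simulate_flip_train(DEFAULT_PROFILE, 7.0, seed=seed)
        assert np.all(np.diff(train.event_times) > 0)
        assert train.event_times[0] >= 0.0
        assert train.event_times[-1] <= 7.0 * 60.0


def test_fixed_seed_is_bit_stable():
    a = simulate_flip_train(DEFAULT_PROFILE, 5.0, seed=42)
    b = simulate_flip_train(DEFAULT_PROFILE, 5.0, seed=42)
    np.testing.assert_array_equal(a.event_times, b.event_times)


def test_pre_post_exchangeable_under_null():
    """With no trend and a unit effect curve, phases have the same law."""
    profile = replace(
        DEFAULT_PROFILE,
        acclimation_trend=0.0,
        early_noise_inflation=1.0,
        effect_curve=EffectCurve.constant(1.0),
        post_response_cv=0.0,
        between_fish_cv=0.0,
    )
    rng = np.random.default_rng(7)
    from tailflip.synthetic_data import draw_fish_state

    st_list = [draw_fish_state(profile, rng) for _ in range(200)]
    pre = minute_count_matrix(profile, st_list, "pre", 30, rng).sum(axis=1)
    post = minute_count_matrix(profile, st_list, "post", 30, rng).sum(axis=1)
    assert stats.ks_2samp(pre, post).pvalue > 0.01


def test_count_matrix_mean_matches_generator_mean():
    profile = constant_rate_profile(rate=12.0, between_fish_cv=0.0)
    rng = np.random.default_rng(3)
    from tailflip.synthetic_data import draw_fish_state

    st_list = [draw_fish_state(profile, rng) for _ in range(300)]
    counts = minute_count_matrix(profile, st_list, "pre", 20, rng)
    expected = 12.0 * profile.flips_per_burst_mean
    se = counts.std() / np.sqrt(counts.size)
    assert abs(counts.mean() - expected) < 4 * se


# ---------------------------------------------------------------- render


def test_empty_train_quiet_model_renders_flat_trace():
    trace = render_trace(FlipTrain(np.empty(0), 2.0), QUIET, seed=0)
    assert np.all(trace.samples == 0.0)
    assert trace.samples.size == 2 * 60 * 100


def test_noise_free_flips_give_expected_sharpness_maxima():
    times = np.array([10.0, 10.3, 10.6, 10.9, 11.2])
    train = FlipTrain(times, 2.0)
    trace = render_trace(train, QUIET, seed=0)
    sharp = np.abs(np.diff(trace.samples))
    peaks, _ = sps.find_peaks(sharp, height=0.5 * QUIET.kernel_amplitude, distance=10)
    assert peaks.size == 5
    peak_times = (peaks + 0.5) / 100.0
    assert np.all(np.abs(peak_times - times) < 0.02)


def test_gain_drift_does_not_touch_ground_truth():
    train = simulate_flip_train(DEFAULT_PROFILE, 2.0, seed=5)
    before = train.event_times.copy()
    render_trace(train, replace(QUIET, gain_drift_amplitude=0.6), seed=0)
    np.testing.assert_array_equal(train.event_times, before)


def test_kernel_wider_than_min_interval_is_configuration_error():
    train = FlipTrain(np.array([1.0, 2.0]), 1.0)
    with pytest.raises(ConfigurationError):
        render_trace(train, QUIET, seed=0, min_event_gap_s=0.03)


def test_measurement_model_validation():
    with pytest.raises(ParameterError):
        MeasurementModel(sample_rate=60.0)  # cannot carry the 40 Hz band
    with pytest.raises(ParameterError):
        MeasurementModel(kernel_width_s=0.2)  # spectrum must reach 20 Hz


# ---------------------------------------------------------------- trajectory


def test_trajectory_frame_count_and_bounds():
    pos = simulate_trajectory(DEFAULT_PROFILE, duration_min=1.0, fps=10.0, seed=0)
    assert pos.shape == (600, 2)
    assert pos[:, 0].min() >= 0 and pos[:, 0].max() <= 90.0
    assert pos[:, 1].min() >= 0 and pos[:, 1].max() <= 80.0


def test_zero_activity_trajectory_is_stationary():
    pos = simulate_trajectory(constant_rate_profile(0.0), duration_min=1.0, seed=0)
    assert np.allclose(pos, pos[0])


def test_invalid_arena_rejected():
    with pytest.raises(ParameterError):
        simulate_trajectory(DEFAULT_PROFILE, arena_mm=(0.0, 80.0), seed=0)


# ---------------------------------------------------------------- studies


def table1_study1_design(seed=0) -> StudyDesign:
    return StudyDesign(
        groups=(
            GroupSpec("saline", profile_for_group("saline"), 12),
            GroupSpec("acid_5pct", profile_for_group("acid_5pct"), 6),
            GroupSpec("acid_10pct", profile_for_group("acid_10pct"), 8),
        ),
        seed=seed,
    )


def test_dose_finding_design_is_valid_and_timeline_defaults():
    design = table1_study1_design()
    assert design.timeline.post_span_min == 110.0
    records = simulate_study(design)
    assert len(records) == 26
    assert records[0].pre_counts.n_minutes == 60
    assert records[0].post_counts.n_minutes == 80


def test_duplicate_group_labels_rejected():
    g = GroupSpec("saline", DEFAULT_PROFILE, 4)
    with pytest.raises(DesignError):
        StudyDesign(groups=(g, g))


def test_same_seed_reproduces_identical_records():
    r1 = simulate_study(table1_study1_design(seed=9))
    r2 = simulate_study(table1_study1_design(seed=9))
    for a, b in zip(r1, r2):
        np.testing.assert_array_equal(a.pre_counts.values, b.pre_counts.values)
        np.testing.assert_array_equal(a.post_counts.values, b.post_counts.values)
        assert a.state == b.state


def test_event_fidelity_counts_are_consistent_with_trains():
    design = StudyDesign(groups=(GroupSpec("saline", profile_for_group("saline"), 2),), seed=3)
    records = simulate_study(design, fidelity="events")
    for rec in records:
        assert rec.pre_counts.values.sum() == pytest.approx(rec.pre_train.n_events, abs=1)
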