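"""Rank-based longitudinal model: relative effects, ATS calibration, oracles."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tailflip.errors import EstimationError, InputError
from tailflip.experiments import simulate_group_bins
from tailflip.longitudinal_inference import (
    LongitudinalDataset,
    _ats_from_matrices,
    ats_test,
    fit_rank_model,
    holm_adjust,
    pairwise_group_test,
    relative_effects,
    window_subset_test,
)
from tailflip.synthetic_data import DEFAULT_PROFILE, EffectCurve, profile_for_group

NULL_PROFILE = replace(DEFAULT_PROFILE, effect_curve=EffectCurve.constant(1.0))


def dataset_from(a, b, labels=("A", "B"), bins=None):
    return LongitudinalDataset.from_arrays({labels[0]: a, labels[1]: b}, time_bins=bins)


# ---------------------------------------------------------------- relative effects


def test_identical_cell_multisets_give_effect_one_half(rng):
    # every cell holds the same multiset of values -> complete symmetry
    base = rng.normal(size=6)
    a = np.column_stack([rng.permutation(base) for _ in range(4)])
    b = np.column_stack([rng.permutation(base) for _ in range(4)])
    eff = relative_effects(dataset_from(a, b))
    np.testing.assert_allclose(eff.to_numpy(), 0.5, atol=1e-12)


def test_identical_groups_have_equal_effect_profiles(rng):
    # same multiset per bin in both groups -> group symmetry bin by bin
    vals = rng.normal(size=(6, 4))
    eff = relative_effects(dataset_from(vals, vals.copy()))
    np.testing.assert_allclose(eff.loc["A"], eff.loc["B"], atol=1e-12)


def test_single_cell_effect_is_one_half():
    data = LongitudinalDataset.from_arrays({"only": np.array([[1.0], [2.0], [5.0]])})
    eff = relative_effects(data)
    assert eff.iloc[0, 0] == pytest.approx(0.5)


def test_tiny_case_matches_direct_midrank_computation():
    # group A = {1, 2}, group B = {3, 4}: ranks 1..4, cell means 1.5 and 3.5
    eff = relative_effects(dataset_from(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]])))
    assert eff.loc["A"].iloc[0] == pytest.approx(0.25)
    assert eff.loc["B"].iloc[0] == pytest.approx(0.75)


def test_balanced_design_effects_average_exactly_one_half(rng):
    a, b = rng.gamma(2, 2, (8, 5)), rng.gamma(3, 1, (8, 5))
    eff = relative_effects(dataset_from(a, b))
    assert eff.to_numpy().mean() == pytest.approx(0.5, abs=1e-12)
    assert np.all((eff.to_numpy() > 0) & (eff.to_numpy() < 1))


def test_effects_invariant_under_strictly_monotone_transform(rng):
    a, b = rng.normal(2, 1, (7, 3)), rng.normal(3, 2, (7, 3))
    raw = relative_effects(dataset_from(a, b))
    warped = relative_effects(dataset_from(np.exp(a), np.exp(b)))
    np.testing.assert_allclose(raw.to_numpy(), warped.to_numpy())


# ---------------------------------------------------------------- dataset validation


def test_fish_in_two_groups_rejected():
    frame = pd.DataFrame(
        {
            "fish_id": ["f1", "f1"],
            "group": ["A", "B"],
            "time_bin": [0, 1],
            "value": [1.0, 2.0],
        }
    )
    with pytest.raises(InputError):
        LongitudinalDataset(frame)


def test_duplicate_observation_rejected():
    frame = pd.DataFrame(
        {
            "fish_id": ["f1", "f1"],
            "group": ["A", "A"],
            "time_bin": [0, 0],
            "value": [1.0, 2.0],
        }
    )
    with pytest.raises(InputError):
        LongitudinalDataset(frame)


def test_incomplete_fish_removed_by_complete_case_rule():
    rows = []
    for fish, nbins in [("f1", 3), ("f2", 3), ("f3", 2)]:
        for b in range(nbins):
            rows.append({"fish_id": fish, "group": "A", "time_bin": b, "value": float(b)})
    data = LongitudinalDataset(pd.DataFrame(rows))
    assert set(data.frame["fish_id"]) == {"f1", "f2"}


def test_too_few_fish_raises_advice(rng):
    with pytest.raises(EstimationError, match="at least"):
        ats_test(dataset_from(rng.normal(size=(1, 3)), rng.normal(size=(5, 3))), "group")


# ---------------------------------------------------------------- ATS calibration


def test_large_shift_separates_with_tiny_p(rng):
    a = rng.normal(100, 10, (10, 5))
    b = a + 80.0
    res = ats_test(dataset_from(a, b), "group")
    assert res.pvalue < 1e-3


def test_type_I_error_is_near_nominal():
    """Rejection rate within [0.03, 0.07] at alpha 0.05, 1000 null replicates."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_reps = 1000
    for _ in range(n_reps):
        a = simulate_group_bins(NULL_PROFILE, 10, rng)
        b = simulate_group_bins(NULL_PROFILE, 10, rng)
        rejections += _ats_from_matrices([a, b], "group").pvalue < 0.05
    assert 0.03 <= rejections / n_reps <= 0.07


def exact_permutation_p(a, b):
    """Oracle: exact label-permutation distribution of the ATS statistic."""
    pooled = np.vstack([a, b])
    observed = _ats_from_matrices([a, b], "group").statistic
    n = a.shape[0]
    hits = total = 0
    for comb in combinations(range(2 * n), n):
        idx = np.array(comb)
        rest = np.setdiff1d(np.arange(2 * n), idx)
        s = _ats_from_matrices([pooled[idx], pooled[rest]], "group").statistic
        hits += s >= observed - 1e-12
        total += 1
    return hits / total


def test_ats_agrees_with_permutation_oracle_on_small_designs():
    """Accept/reject agreement >= 95% at alpha 0.05, n=4/group, 3 bins."""
    alt = replace(DEFAULT_PROFILE, effect_curve=EffectCurve.constant(0.5))
    rng = np.random.default_rng(11)
    agreements = 0
    n_sets = 100
    for i in range(n_sets):
        a = simulate_group_bins(NULL_PROFILE, 4, rng)[:, :3]
        b = simulate_group_bins(NULL_PROFILE if i % 2 else alt, 4, rng)[:, :3]
        p_ats = _ats_from_matrices([a, b], "group").pvalue
        p_perm = exact_permutation_p(a, b)
        agreements += (p_ats < 0.05) == (p_perm < 0.05)
    assert agreements / n_sets >= 0.95


# ---------------------------------------------------------------- pairwise tests


def test_null_pairwise_pvalues_are_uniform():
    rng = np.random.default_rng(31)
    pvals = []
    for _ in range(300):
        a = simulate_group_bins(NULL_PROFILE, 8, rng)
        b = simulate_group_bins(NULL_PROFILE, 8, rng)
        pvals.append(_ats_from_matrices([a, b], "group").pvalue)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_acid_versus_saline_detected_with_table1_sample_sizes():
    """Calibrated acid effect vs saline at n = 8 vs 12: p < 0.01 in >= 90% of sims."""
    saline = profile_for_group("saline")
    acid = profile_for_group("acid_10pct")
    rng = np.random.default_rng(41)
    hits = 0
    n_sims = 100
    for _ in range(n_sims):
        a = simulate_group_bins(saline, 12, rng)
        b = simulate_group_bins(acid, 8, rng)
        hits += _ats_from_matrices([a, b], "group").pvalue < 0.01
    assert hits / n_sims >= 0.90


def test_group_compared_with_itself_is_an_error(rng):
    data = dataset_from(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
    with pytest.raises(InputError):
        pairwise_group_test(data, "A", "A")
    with pytest.raises(InputError):
        pairwise_group_test(data, "A", "missing")


# ---------------------------------------------------------------- window subsets


def test_full_subset_equals_full_test(rng):
    a, b = rng.normal(0, 1, (6, 4)), rng.normal(1, 1, (6, 4))
    data = dataset_from(a, b, bins=[0, 1, 2, 3])
    full = ats_test(data, "group")
    sub = window_subset_test(data, [0, 1, 2, 3])
    assert sub.pvalue == pytest.approx(full.pvalue)
    assert sub.statistic == pytest.approx(full.statistic)


def test_late_separating_doses_only_significant_late():
    """Dose profiles that diverge late: late-window p below full-window p on average."""
    low = profile_for_group("morphine_3mg+acid_10pct")
    high = profile_for_group("morphine_6mg+acid_10pct")
    rng = np.random.default_rng(53)
    full_p, late_p = [], []
    for _ in range(40):
        a = simulate_group_bins(low, 9, rng)
        b = simulate_group_bins(high, 8, rng)
        data = dataset_from(a, b, bins=[30, 45, 60, 75, 90])
        full_p.append(ats_test(data, "group").pvalue)
        late_p.append(window_subset_test(data, [60, 75, 90]).pvalue)
    assert np.mean(late_p) < np.mean(full_p)


def test_single_bin_subset_matches_two_sample_rank_oracle(rng):
    a, b = rng.normal(0, 1, (12, 3)), rng.normal(0.9, 1.4, (12, 3))
    data = dataset_from(a, b, bins=[0, 1, 2])
    ours = window_subset_test(data, [1])
    oracle = stats.brunnermunzel(a[:, 1], b[:, 1])
    assert (ours.pvalue < 0.05) == (oracle.pvalue < 0.05)
    assert ours.pvalue == pytest.approx(oracle.pvalue, abs=0.06)


def test_empty_subset_rejected(rng):
    data = dataset_from(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
    with pytest.raises(InputError):
        window_subset_test(data, [])


# ---------------------------------------------------------------- misc


def test_holm_adjustment_is_monotone_and_bounded():
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert np.all(adj >= [0.01, 0.04, 0.03])
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.03)


def test_fit_rank_model_summary_structure(rng):
    data = dataset_from(rng.normal(size=(6, 4)), rng.normal(1, 1, (6, 4)))
    model = fit_rank_model(data)
    summary = model.summary()
    assert list(summary["effect"]) == ["group", "time", "interaction"]
    assert model.relative_effects.shape == (2, 4)
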