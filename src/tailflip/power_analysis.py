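"""Simulation-based power and minimal sample size for the full analysis chain.

Each Monte-Carlo replicate simulates two groups from the generator (control
at its post-treatment level and a treatment shifted down by a sustained
``delta_pct`` percentage points of normalized activity), runs baseline
normalization and recording-period binning, and applies the rank-based
pairwise group test; power is the rejection fraction at the configured alpha.
``minimal_n`` scans a grid of per-group sample sizes and returns the smallest
that attains the target power after isotonic smoothing of the Monte-Carlo
power curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .errors import EstimationError, ParameterError
from .experiments import simulate_group_bins
from .longitudinal_inference import _ats_from_matrices
from .synthetic_data import DEFAULT_PROFILE, BehaviorProfile, EffectCurve, Timeline

__all__ = ["PowerSpec", "PowerEstimate", "estimate_power", "power_curve", "minimal_n"]

MIN_REPS_FOR_REPORTING = 100


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of a power study.

    ``delta_pct`` is a sustained difference, in percentage points of
    normalized activity, between the two groups' post-treatment levels
    (control at ``control_level`` x 100%, treatment below it).
    """

    profile: BehaviorProfile = DEFAULT_PROFILE
    control_level: float = 1.0
    delta_pct: float = 10.0
    n_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    alpha: float = 0.05
    target_power: float = 0.80
    reps: int = 500
    seed: int = 7
    timeline: Timeline = field(default_factory=Timeline)
    bin_width_min: int = 15

    def __post_init__(self):
        if self.delta_pct < 0:
            raise ParameterError("delta_pct must be >= 0")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if list(self.n_grid) != sorted(self.n_grid) or len(self.n_grid) == 0:
            raise ParameterError("n_grid must be non-empty and ascending")
        if min(self.n_grid) < 2:
            raise ParameterError("n_grid entries must be >= 2")
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")

    def group_profiles(self) -> tuple[BehaviorProfile, BehaviorProfile]:
        control = replace(
            self.profile, effect_curve=EffectCurve.constant(self.control_level)
        )
        treated = replace(
            self.profile,
            effect_curve=EffectCurve.constant(self.control_level - self.delta_pct / 100.0),
        )
        return control, treated


@dataclass(frozen=True)
class PowerEstimate:
    n_per_group: int
    power: float
    se: float  # binomial standard error
    reps: int
    low_precision: bool = False


def _one_rejection(spec: PowerSpec, n: int, rng: np.random.Generator) -> bool:
    control, treated = spec.group_profiles()
    a = simulate_group_bins(control, n, rng, spec.timeline, spec.bin_width_min)
    b = simulate_group_bins(treated, n, rng, spec.timeline, spec.bin_width_min)
    result = _ats_from_matrices([a, b], "group")
    return result.pvalue < spec.alpha


def estimate_power(spec: PowerSpec, n_per_group: int, seed=None) -> PowerEstimate:
    """Monte-Carlo power of the pairwise rank test at ``n_per_group`` fish/group."""
    low_precision = spec.reps < MIN_REPS_FOR_REPORTING
    if low_precision:
        warnings.warn(
            f"reps={spec.reps} < {MIN_REPS_FOR_REPORTING}: power estimate flagged low-precision",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rejections = sum(_one_rejection(spec, n_per_group, rng) for _ in range(spec.reps))
    power = rejections / spec.reps
    se = float(np.sqrt(power * (1.0 - power) / spec.reps))
    return PowerEstimate(n_per_group, power, se, spec.reps, low_precision)


def power_curve(spec: PowerSpec) -> pd.DataFrame:
    """Power at every grid size, with an isotonic-smoothed column.

    Seeds are derived per grid point from ``spec.seed`` so the curve is
    reproducible and each point is independent.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.n_grid))
    estimates = [estimate_power(spec, n, s) for n, s in zip(spec.n_grid, seeds)]
    raw = np.array([e.power for e in estimates])
    smooth = isotonic_regression(raw).x
    return pd.DataFrame(
        {
            "n": list(spec.n_grid),
            "power": raw,
            "power_isotonic": smooth,
            "se": [e.se for e in estimates],
            "reps": [e.reps for e in estimates],
            "seed": spec.seed,
        }
    )


@dataclass(frozen=True)
class MinimalN:
    n: int
    curve: pd.DataFrame


def minimal_n(spec: PowerSpec) -> MinimalN:
    """Smallest grid size whose (isotonic-smoothed) power reaches the target.

    Raises :class:`EstimationError` with the attained maximum if no grid size
    reaches the target (e.g. at ``delta_pct = 0``), and if the smallest grid
    size already meets it, suggests extending the grid downward.
    """
    curve = power_curve(spec)
    meets = curve["power_isotonic"] >= spec.target_power
    if not meets.any():
        raise EstimationError(
            f"no n in {list(spec.n_grid)} attains power {spec.target_power:.2f} "
            f"(maximum attained: {curve['power'].max():.3f} at n={int(curve['n'].iloc[-1])}); "
            "extend n_grid upward"
        )
    n_star = int(curve.loc[meets, "n"].iloc[0])
    return MinimalN(n_star, curve)
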