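"""Rank-based nonparametric inference for the group x recording-period design.

The assay's repeated-measures data (fish nested in treatment groups, observed
over post-injection recording periods) are analysed with a rank-based marginal
model: all observations are pooled and mid-ranked, each design cell
(group, period) gets a *relative treatment effect*

    p_hat[i, s] = (mean mid-rank in cell - 1/2) / N,

the probability that a random observation from that cell exceeds a random
observation from the pooled reference distribution, and hypotheses about the
group main effect, the time main effect and their interaction are tested with
the ANOVA-type statistic (ATS): a quadratic form on the cell effects referred
to an F distribution with Box-type moment-matched degrees of freedom.
Within-fish dependence over periods enters through the empirical covariance
of each fish's rank vector; no distributional assumptions are made, and the
procedure is invariant under strictly monotone transformations of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InputError
from .types import NormalizedSeries

__all__ = [
    "LongitudinalDataset",
    "ATSResult",
    "RankModelResult",
    "relative_effects",
    "ats_test",
    "pairwise_group_test",
    "window_subset_test",
    "fit_rank_model",
]

logger = logging.getLogger(__name__)

Effect = Literal["group", "time", "interaction"]

MIN_FISH_PER_GROUP = 2
RECOMMENDED_MIN_FISH = 4


class LongitudinalDataset:
    """Long-format repeated-measures data: one value per fish per time bin.

    Each fish belongs to exactly one group and contributes at most one value
    per bin.  Fish with missing bins are removed (complete-case analysis,
    logged), mirroring the tested-versus-analysed exclusions of the assay.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"fish_id", "group", "time_bin", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise InputError(f"dataset missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["fish_id", "group", "time_bin", "value"]].copy()
        if frame.duplicated(["fish_id", "time_bin"]).any():
            raise InputError("each fish may have at most one value per time bin")
        n_groups_per_fish = frame.groupby("fish_id")["group"].nunique()
        if (n_groups_per_fish > 1).any():
            bad = n_groups_per_fish[n_groups_per_fish > 1].index.tolist()
            raise InputError(f"fish assigned to multiple groups: {bad}")
        bins = np.sort(frame["time_bin"].unique())
        counts = frame.groupby("fish_id")["time_bin"].count()
        complete = counts[counts == bins.size].index
        dropped = sorted(set(counts.index) - set(complete))
        if dropped:
            logger.info("dropping %d incomplete fish: %s", len(dropped), dropped)
        self.frame = frame[frame["fish_id"].isin(complete)].reset_index(drop=True)
        self.time_bins = bins
        self.groups = list(pd.unique(self.frame["group"]))
        if self.frame.empty:
            raise InputError("no complete-case fish remain")

    @classmethod
    def from_series(cls, series: Iterable[NormalizedSeries]) -> "LongitudinalDataset":
        rows = []
        for ns in series:
            for t, v in zip(ns.time_min, ns.values):
                rows.append({"fish_id": ns.fish_id, "group": ns.group, "time_bin": t, "value": v})
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_arrays(cls, groups: dict[str, np.ndarray], time_bins=None) -> "LongitudinalDataset":
        """Build from per-group value matrices of shape ``(n_fish, n_bins)``."""
        rows = []
        for label, mat in groups.items():
            mat = np.asarray(mat, dtype=float)
            nb = mat.shape[1]
            bins = np.arange(nb) if time_bins is None else np.asarray(time_bins)
            for k in range(mat.shape[0]):
                for s in range(nb):
                    rows.append(
                        {"fish_id": f"{label}_{k}", "group": label, "time_bin": bins[s], "value": mat[k, s]}
                    )
        return cls(pd.DataFrame(rows))

    def group_matrices(self) -> tuple[list[str], list[np.ndarray]]:
        """Per-group value matrices ``(n_fish, n_bins)`` in group / bin order."""
        mats = []
        for g in self.groups:
            sub = self.frame[self.frame["group"] == g]
            pivot = sub.pivot(index="fish_id", columns="time_bin", values="value")
            pivot = pivot.reindex(columns=self.time_bins)
            if pivot.isna().any().any():
                bad_bins = pivot.columns[pivot.isna().any()].tolist()
                raise EstimationError(f"empty or incomplete cell(s) in group {g!r}, bins {bad_bins}")
            mats.append(pivot.to_numpy(dtype=float))
        return list(self.groups), mats

    def subset_groups(self, labels: Sequence[str]) -> "LongitudinalDataset":
        unknown = set(labels) - set(self.groups)
        if unknown:
            raise InputError(f"unknown group label(s): {sorted(unknown)}")
        return LongitudinalDataset(self.frame[self.frame["group"].isin(labels)])

    def subset_bins(self, bins: Sequence) -> "LongitudinalDataset":
        bins = list(bins)
        if not bins:
            raise InputError("bin subset must be non-empty")
        unknown = set(bins) - set(self.time_bins.tolist())
        if unknown:
            raise InputError(f"unknown time bin(s): {sorted(unknown)}")
        return LongitudinalDataset(self.frame[self.frame["time_bin"].isin(bins)])


@dataclass(frozen=True)
class ATSResult:
    """ANOVA-type test of one factorial effect."""

    effect: Effect
    statistic: float
    df1: float
    df2: float  # inf for within-subject effects
    pvalue: float


@dataclass(frozen=True)
class RankModelResult:
    """Relative effects plus the three factorial ATS tests."""

    relative_effects: pd.DataFrame  # groups x time bins
    group: ATSResult
    time: ATSResult
    interaction: ATSResult
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2,
                "pvalue": r.pvalue,
                f"significant(alpha={self.alpha})": r.pvalue < self.alpha,
            }
            for r in (self.group, self.time, self.interaction)
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# core computations on per-group matrices
# --------------------------------------------------------------------------


def _rank_matrices(mats: Sequence[np.ndarray]) -> tuple[list[np.ndarray], int]:
    """Pooled mid-ranks, reshaped back to per-group (n_i, t) matrices."""
    pooled = np.concatenate([m.ravel() for m in mats])
    ranks = stats.rankdata(pooled, method="average")
    out, pos = [], 0
    for m in mats:
        out.append(ranks[pos : pos + m.size].reshape(m.shape))
        pos += m.size
    return out, pooled.size


def _relative_effect_matrix(mats: Sequence[np.ndarray]) -> np.ndarray:
    ranked, total = _rank_matrices(mats)
    return np.vstack([(r.mean(axis=0) - 0.5) / total for r in ranked])


def _contrast(effect: Effect, a: int, t: int) -> np.ndarray:
    P = lambda d: np.eye(d) - np.full((d, d), 1.0 / d)
    J = lambda d: np.full((d, d), 1.0 / d)
    if effect == "group":
        return np.kron(P(a), J(t))
    if effect == "time":
        return np.kron(J(a), P(t))
    if effect == "interaction":
        return np.kron(P(a), P(t))
    raise InputError(f"unknown effect {effect!r}")


def _ats_from_matrices(mats: Sequence[np.ndarray], effect: Effect) -> ATSResult:
    a = len(mats)
    t = mats[0].shape[1]
    n_i = np.array([m.shape[0] for m in mats])
    if np.any(n_i < MIN_FISH_PER_GROUP):
        raise EstimationError(
            f"per-fish covariance not estimable: every group needs at least "
            f"{MIN_FISH_PER_GROUP} fish (recommended >= {RECOMMENDED_MIN_FISH}); got {n_i.tolist()}"
        )
    if a < 2 and t < 2:
        raise EstimationError("need at least two groups or two time bins")
    ranked, total = _rank_matrices(mats)
    n_subj = int(n_i.sum())
    p_hat = np.concatenate([(r.mean(axis=0) - 0.5) / total for r in ranked])
    # block-diagonal covariance of sqrt(n_subj) * p_hat
    V = np.zeros((a * t, a * t))
    blocks = []
    for i, r in enumerate(ranked):
        S = np.cov(r / total, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        block = (n_subj / n_i[i]) * S
        blocks.append(block)
        V[i * t : (i + 1) * t, i * t : (i + 1) * t] = block
    T = _contrast(effect, a, t)
    TV = T @ V
    trace_TV = float(np.trace(TV))
    if trace_TV <= 0:
        # degenerate data (e.g. all values tied): no evidence against the null
        return ATSResult(effect, 0.0, np.nan, np.nan, 1.0)
    statistic = n_subj * float(p_hat @ T @ p_hat) / trace_TV
    df1 = trace_TV**2 / float(np.trace(TV @ TV))
    if effect == "group":
        denom = 0.0
        for i in range(a):
            Ti = T[i * t : (i + 1) * t, i * t : (i + 1) * t]
            denom += float(np.trace(Ti @ blocks[i])) ** 2 / (n_i[i] - 1)
        df2 = trace_TV**2 / denom if denom > 0 else np.inf
        pvalue = float(stats.f.sf(statistic, df1, df2))
    else:
        df2 = np.inf
        pvalue = float(stats.chi2.sf(df1 * statistic, df1))
    return ATSResult(effect, float(statistic), float(df1), float(df2), pvalue)


# --------------------------------------------------------------------------
# public API on datasets
# --------------------------------------------------------------------------


def relative_effects(data: LongitudinalDataset) -> pd.DataFrame:
    """Relative treatment effects per (group, time bin) cell, in (0, 1).

    For a balanced complete design the unweighted average of all cell
    effects equals 0.5 exactly.
    """
    labels, mats = data.group_matrices()
    eff = _relative_effect_matrix(mats)
    return pd.DataFrame(eff, index=labels, columns=data.time_bins)


def ats_test(data: LongitudinalDataset, effect: Effect) -> ATSResult:
    """ANOVA-type test of the group, time, or group x time interaction effect."""
    _, mats = data.group_matrices()
    return _ats_from_matrices(mats, effect)


def pairwise_group_test(data: LongitudinalDataset, group_a: str, group_b: str) -> ATSResult:
    """Group-effect ATS restricted to two groups (unadjusted comparison)."""
    if group_a == group_b:
        raise InputError(f"cannot compare group {group_a!r} with itself")
    return ats_test(data.subset_groups([group_a, group_b]), "group")


def window_subset_test(
    data: LongitudinalDataset, bins: Sequence, effect: Effect = "group"
) -> ATSResult:
    """ATS on a subset of recording periods (e.g. only the late bins).

    With a single bin the group test reduces to a two-sample rank test.
    """
    return ats_test(data.subset_bins(bins), effect)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (optional for the pairwise contrasts)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def fit_rank_model(data: LongitudinalDataset, alpha: float = 0.05) -> RankModelResult:
    """Relative effects plus all three factorial ATS tests in one result."""
    labels, mats = data.group_matrices()
    eff = pd.DataFrame(_relative_effect_matrix(mats), index=labels, columns=data.time_bins)
    return RankModelResult(
        relative_effects=eff,
        group=_ats_from_matrices(mats, "group"),
        time=_ats_from_matrices(mats, "time"),
        interaction=_ats_from_matrices(mats, "interaction"),
        alpha=alpha,
    )
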