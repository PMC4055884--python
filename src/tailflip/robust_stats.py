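"""20% Winsorized location summaries with standard errors.

Behavioural activity data carry extreme values (high-activity bursts in short
windows), so group summaries use the 20% Winsorized mean: with
``gamma_per_tail = 0.10``, the ``g = floor(0.10 * n)`` smallest values are
replaced by the (g+1)-th smallest and the ``g`` largest by the (g+1)-th
largest before averaging.  The standard error follows the Tukey-McLaughlin
form

    se = s_w / ((1 - 2 * g/n) * sqrt(n)),

where ``s_w`` is the sample standard deviation (divisor ``n - 1``) of the
winsorized sample; at ``gamma = 0`` this reduces to the classical ``s/sqrt(n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

__all__ = ["WinsorSummary", "winsorize", "winsorized_mean", "winsorized_se", "summarize"]


def _check(x, gamma_per_tail: float, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise InputError(f"need at least {min_n} value(s), got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputError("values must be finite")
    if not (0.0 <= gamma_per_tail < 0.5):
        raise ParameterError(f"gamma_per_tail must lie in [0, 0.5), got {gamma_per_tail}")
    return arr


@dataclass(frozen=True)
class WinsorSummary:
    """Winsorized location summary of one cell (group x recording period)."""

    mean: float
    se: float
    n: int
    gamma_per_tail: float = 0.10


def winsorize(x, gamma_per_tail: float = 0.10) -> np.ndarray:
    """Replace the ``g = floor(gamma * n)`` most extreme values in each tail.

    Returns an array of the same size with the ``g`` smallest values set to
    the (g+1)-th smallest and the ``g`` largest to the (g+1)-th largest
    (element order preserved).
    """
    arr = _check(x, gamma_per_tail)
    g = int(math.floor(gamma_per_tail * arr.size))
    if g == 0:
        return arr.copy()
    srt = np.sort(arr)
    return np.clip(arr, srt[g], srt[arr.size - g - 1])


def winsorized_mean(x, gamma_per_tail: float = 0.10) -> float:
    """Arithmetic mean of the winsorized sample."""
    return float(np.mean(winsorize(x, gamma_per_tail)))


def winsorized_se(x, gamma_per_tail: float = 0.10) -> float:
    """Standard error of the winsorized mean (Tukey-McLaughlin form)."""
    arr = _check(x, gamma_per_tail, min_n=2)
    g = int(math.floor(gamma_per_tail * arr.size))
    w = winsorize(arr, gamma_per_tail)
    s_w = float(np.std(w, ddof=1))
    gamma_eff = g / arr.size
    return s_w / ((1.0 - 2.0 * gamma_eff) * math.sqrt(arr.size))


def summarize(x, gamma_per_tail: float = 0.10) -> WinsorSummary:
    """Winsorized mean, its standard error and the sample size in one record."""
    arr = _check(x, gamma_per_tail, min_n=2)
    return WinsorSummary(
        mean=winsorized_mean(arr, gamma_per_tail),
        se=winsorized_se(arr, gamma_per_tail),
        n=int(arr.size),
        gamma_per_tail=gamma_per_tail,
    )
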