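"""Growth, generation-count and reversion calculators.

Doubling time follows the standard exponential relation
``DT = ln2 * (t2 - t1) / ln(m2 / m1)`` for two measurements, or a
log-linear least-squares fit over a growth window for a time series.
Generations elapsed between two population counts are
``log2(final / initial)``; cumulative generations across passages are the
sum of per-passage values. A reversion curve tracks the suspension
survival of an adapted resistant population during unstressed attached
growth; the reversion duration is the first cumulative generation count
at which survival re-crosses the sensitive baseline (linear interpolation
between measured passages).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "NOT_REACHED",
    "GrowthMetricError",
    "NonGrowthWarning",
    "NegativeFluorescenceWarning",
    "GrowthSeries",
    "ReversionCurve",
    "doubling_time",
    "doubling_time_series",
    "generations_elapsed",
    "reversion_generations",
    "ctcf",
]

#: Sentinel returned when a reversion curve never re-crosses the baseline.
NOT_REACHED = math.inf


class GrowthMetricError(ValueError):
    """Invalid input to a growth calculator."""


class NonGrowthWarning(UserWarning):
    """The measurements do not increase: the doubling time is not a finite
    positive number."""


class NegativeFluorescenceWarning(UserWarning):
    """Background subtraction produced a negative corrected fluorescence."""


@dataclass(frozen=True)
class GrowthSeries:
    """A growth time series (cell counts or optical density vs hours)."""

    times: tuple[float, ...]
    measurements: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.measurements, dtype=float)
        if t.size != m.size:
            raise GrowthMetricError("times and measurements differ in length")
        if t.size < 2:
            raise GrowthMetricError("a growth series needs >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise GrowthMetricError("times must be strictly increasing")
        if np.any(m <= 0):
            raise GrowthMetricError("measurements must be positive")


@dataclass(frozen=True)
class ReversionCurve:
    """Suspension survival of an adapted resistant population vs cumulative
    generations of unstressed attached growth."""

    cumulative_generations: tuple[float, ...]
    survival_fractions: tuple[float, ...]
    baseline_sensitive_fraction: float

    def __post_init__(self) -> None:
        g = np.asarray(self.cumulative_generations, dtype=float)
        s = np.asarray(self.survival_fractions, dtype=float)
        if g.size != s.size:
            raise GrowthMetricError(
                "generations and survival fractions differ in length"
            )
        if g.size < 1:
            raise GrowthMetricError("a reversion curve needs >= 1 point")
        if np.any(np.diff(g) < 0):
            raise GrowthMetricError("cumulative generations must be non-decreasing")


def doubling_time(t1: float, t2: float, m1: float, m2: float) -> float:
    """Two-point doubling time ``ln2 * (t2 - t1) / ln(m2 / m1)`` in hours.

    If the culture did not grow (``m2 <= m1``) the value is still returned
    (negative or infinite) but a :class:`NonGrowthWarning` is issued.
    """
    if t2 <= t1:
        raise GrowthMetricError(f"t2 must exceed t1; got t1={t1!r}, t2={t2!r}")
    if m1 <= 0 or m2 <= 0:
        raise GrowthMetricError("measurements must be positive")
    if m2 <= m1:
        warnings.warn(
            f"no growth between t={t1} h and t={t2} h "
            f"(m1={m1}, m2={m2}): doubling time is not a finite positive number",
            NonGrowthWarning,
            stacklevel=2,
        )
        if m2 == m1:
            return math.inf
    return math.log(2.0) * (t2 - t1) / math.log(m2 / m1)


def _growth_phase_window(log_m: np.ndarray) -> slice:
    """Longest contiguous run of points with positive successive log-slope
    (earliest run wins ties)."""
    rising = np.diff(log_m) > 0
    best_start, best_len = 0, 0
    start, length = 0, 0
    for i, up in enumerate(rising):
        if up:
            if length == 0:
                start = i
            length += 1
            if length > best_len:
                best_start, best_len = start, length
        else:
            length = 0
    if best_len == 0:
        raise GrowthMetricError("no growing window found in the series")
    return slice(best_start, best_start + best_len + 1)


def doubling_time_series(
    series: GrowthSeries,
    window: Literal["growth_phase", "all"] = "growth_phase",
) -> float:
    """Doubling time from a log-linear least-squares fit of ln(measurement)
    against time.

    With ``window="growth_phase"`` the fit uses the longest contiguous run
    of increasing measurements, excluding lag and plateau phases; with
    ``window="all"`` every point is used.
    """
    t = np.asarray(series.times, dtype=float)
    log_m = np.log(np.asarray(series.measurements, dtype=float))
    if window == "growth_phase":
        sel = _growth_phase_window(log_m)
        t, log_m = t[sel], log_m[sel]
    elif window != "all":
        raise GrowthMetricError(f"unknown window {window!r}")
    slope = np.polyfit(t, log_m, 1)[0]
    if slope <= 0:
        raise GrowthMetricError(
            f"fitted growth rate is not positive ({slope:.3g}/h): "
            "no doubling time"
        )
    return math.log(2.0) / slope


def generations_elapsed(initial_count: float, final_count: float) -> float:
    """Generations between two population counts, ``log2(final / initial)``."""
    if initial_count <= 0 or final_count <= 0:
        raise GrowthMetricError("cell counts must be positive")
    return math.log2(final_count / initial_count)


def reversion_generations(curve: ReversionCurve, tolerance: float = 0.05) -> float:
    """Generations of attached growth needed for an adapted resistant
    population to regain baseline sensitivity.

    Returns the smallest cumulative generation count at which survival
    drops to ``baseline_sensitive_fraction + tolerance``, linearly
    interpolating between bracketing measurements, or :data:`NOT_REACHED`
    if the curve never crosses.
    """
    if tolerance < 0:
        raise GrowthMetricError(f"tolerance must be >= 0; got {tolerance!r}")
    g = np.asarray(curve.cumulative_generations, dtype=float)
    s = np.asarray(curve.survival_fractions, dtype=float)
    if curve.baseline_sensitive_fraction >= s[0]:
        raise GrowthMetricError(
            "curve must start above the sensitive baseline "
            f"(first survival {s[0]!r} <= baseline "
            f"{curve.baseline_sensitive_fraction!r})"
        )
    threshold = curve.baseline_sensitive_fraction + tolerance
    below = np.nonzero(s <= threshold)[0]
    if below.size == 0:
        return NOT_REACHED
    i = int(below[0])
    if i == 0:
        return float(g[0])
    # interpolate between the bracketing measurements
    g0, g1 = g[i - 1], g[i]
    s0, s1 = s[i - 1], s[i]
    if s0 == s1 or g0 == g1:
        return float(g1)
    return float(g0 + (s0 - threshold) / (s0 - s1) * (g1 - g0))


def ctcf(
    integrated_density: float, area: float, mean_background: float
) -> float:
    """Corrected total cell fluorescence:
    ``integrated_density - area * mean_background``.

    May be negative when the background estimate exceeds the signal; a
    :class:`NegativeFluorescenceWarning` flags that case.
    """
    if area < 0:
        raise GrowthMetricError(f"area must be >= 0; got {area!r}")
    value = integrated_density - area * mean_background
    if value < 0:
        warnings.warn(
            f"corrected fluorescence is negative ({value:g}): background "
            "exceeds signal",
            NegativeFluorescenceWarning,
            stacklevel=2,
        )
    return value
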