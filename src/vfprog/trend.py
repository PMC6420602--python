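"""Trend-based progression predictors.

Per eye:

* **GI** -- regress the per-test mean sensitivity (over all 52 locations) on
  time; the slope, its two-sided p-value, and their product are the
  predictors.
* **PLR / P1-P4** -- ordinary least squares of each location's sensitivity
  on time with ONE-SIDED p-values for deterioration (slope < 0); the four
  smallest p-values, in order, are the predictors.
* **MS** -- mean of the location slopes whose p-value is below 0.01
  (0 when no location qualifies).
* **PoPLR** -- S = sum of -ln(p) over locations with p < 0.05, calibrated by
  permuting the order of the visits (whole test fields are permuted jointly,
  preserving within-test spatial correlation); exact enumeration when the
  number of orderings does not exceed the permutation budget.

Degenerate regressions follow fixed conventions so predictors stay defined
on short truncated series: fewer than 3 time points gives slope 0 / p 1;
an exact fit (zero residual variance) gives p 0 for a deteriorating slope
and p 1 otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .io import VFSeries

__all__ = [
    "PointwiseFit",
    "TrendPredictors",
    "global_index",
    "pointwise_regressions",
    "plr_order_stats",
    "mean_slope",
    "poplr",
    "poplr_statistic",
    "trend_predictors",
]

_EXACT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class PointwiseFit:
    """Per-location OLS results: slopes (dB/year) and one-sided p-values."""

    slope: np.ndarray
    slope_p: np.ndarray
    n_points: int


@dataclass(frozen=True)
class TrendPredictors:
    """The full set of per-eye trend predictors (NaN where undefined)."""

    gi_slope: float
    gi_p: float
    gi_interaction: float
    p1: float
    p2: float
    p3: float
    p4: float
    ms: float
    poplr_s: float
    poplr_p: float


def _ols_1d(t: np.ndarray, y: np.ndarray, sided: str) -> tuple[float, float]:
    """Slope and p-value of OLS y ~ time with the degenerate conventions.

    sided="less": one-sided p for slope < 0; sided="two": two-sided.
    """
    slopes, ps = _ols_columns(t, y[:, None], sided)
    return float(slopes[0]), float(ps[0])


def _ols_columns(t: np.ndarray, Y: np.ndarray, sided: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column OLS of Y (T, L) on t with slope p-values."""
    T = len(t)
    if T < 3:
        L = Y.shape[1]
        return np.zeros(L), np.ones(L)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slopes = (tc @ Y) / sxx
    fitted = Y.mean(axis=0) + np.outer(tc, slopes)
    sse = ((Y - fitted) ** 2).sum(axis=0)
    df = T - 2
    scale = np.maximum((Y - Y.mean(axis=0)) ** 2, 1.0).sum(axis=0)
    exact = sse <= _EXACT_FIT_TOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        tstat = slopes / se
    if sided == "less":
        p = stats.t.cdf(tstat, df)
        p[exact & (slopes < 0)] = 0.0
        p[exact & (slopes >= 0)] = 1.0
    elif sided == "two":
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        p[exact & (slopes != 0)] = 0.0
        p[exact & (slopes == 0)] = 1.0
    else:  # pragma: no cover
        raise ValueError(sided)
    return slopes, np.clip(p, 0.0, 1.0)


def global_index(series: VFSeries, sided: str = "two") -> tuple[float, float, float]:
    """GI: slope, its p-value, and slope*p of mean sensitivity vs time.

    ``sided`` is "two" (default: the slope's sign enters separately through
    the slope itself) or "less" (one-sided for deterioration).  Needs at
    least 3 tests; with exactly 2 the predictors are NaN (warned).
    """
    if series.n_tests < 2:
        raise ValueError(f"eye {series.eye_id}: GI needs at least 2 tests")
    if series.n_tests == 2:
        warnings.warn(
            f"eye {series.eye_id}: only 2 tests; GI predictors undefined", UserWarning
        )
        return math.nan, math.nan, math.nan
    means = series.matrix.mean(axis=1)
    slope, p = _ols_1d(series.times, means, sided=sided)
    return slope, p, slope * p


def pointwise_regressions(series: VFSeries, sided: str = "less") -> PointwiseFit:
    """Per-location OLS; default one-sided (deterioration) p-values."""
    if series.n_tests < 2:
        raise ValueError(f"eye {series.eye_id}: PLR needs at least 2 tests")
    slopes, ps = _ols_columns(series.times, series.matrix, sided=sided)
    return PointwiseFit(slope=slopes, slope_p=ps, n_points=series.n_tests)


def plr_order_stats(fit: PointwiseFit) -> tuple[float, float, float, float]:
    """The four smallest location p-values, nondecreasing."""
    if len(fit.slope_p) < 4:
        raise ValueError("need at least 4 locations for P1-P4")
    smallest = np.partition(fit.slope_p, 3)[:4]
    p1, p2, p3, p4 = np.sort(smallest)
    return float(p1), float(p2), float(p3), float(p4)


def mean_slope(fit: PointwiseFit) -> float:
    """Mean of slopes at locations with p < 0.01; 0 when none qualify."""
    mask = fit.slope_p < 0.01
    if not mask.any():
        return 0.0
    return float(fit.slope[mask].mean())


def poplr_statistic(ps: np.ndarray) -> float:
    """S = sum of -ln(p) over p-values below 0.05 (0 when none qualify)."""
    ps = np.asarray(ps, dtype=float)
    small = ps[ps < 0.05]
    if len(small) == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(-np.log(small).sum())


def poplr(series: VFSeries, n_perm: int = 1999, seed: int = 0) -> tuple[float, float]:
    """PoPLR statistic S and its permutation p-value.

    The null reorders the visit sequence jointly across locations: times
    stay fixed, whole test fields are permuted.  With T! <= n_perm all T!
    orderings are enumerated and p = #{S_perm >= S_obs} / T!; otherwise
    p = (1 + #{S_perm >= S_obs}) / (n_perm + 1) over random permutations.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if series.n_tests < 3:
        warnings.warn(
            f"eye {series.eye_id}: fewer than 3 tests; PoPLR undefined", UserWarning
        )
        return math.nan, math.nan
    t = series.times
    Y = series.matrix
    _, ps = _ols_columns(t, Y, sided="less")
    s_obs = poplr_statistic(ps)

    T = len(t)
    if math.factorial(T) <= n_perm:
        count = 0
        total = 0
        for perm in permutations(range(T)):
            _, pp = _ols_columns(t, Y[list(perm)], sided="less")
            count += poplr_statistic(pp) >= s_obs - 1e-12
            total += 1
        return s_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(T)
        _, pp = _ols_columns(t, Y[order], sided="less")
        count += poplr_statistic(pp) >= s_obs - 1e-12
    return s_obs, (1 + count) / (n_perm + 1)


def trend_predictors(series: VFSeries, n_perm: int = 1999, seed: int = 0) -> TrendPredictors:
    """All trend predictors for one eye; NaN where the series is too short."""
    gi_slope, gi_p, gi_inter = global_index(series)
    fit = pointwise_regressions(series)
    p1, p2, p3, p4 = plr_order_stats(fit)
    ms = mean_slope(fit)
    s, p = poplr(series, n_perm=n_perm, seed=seed) if series.n_tests >= 3 else (math.nan, math.nan)
    return TrendPredictors(
        gi_slope=gi_slope,
        gi_p=gi_p,
        gi_interaction=gi_inter,
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        ms=ms,
        poplr_s=s,
        poplr_p=p,
    )
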