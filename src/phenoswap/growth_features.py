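"""Growth-curve feature extraction from ln-transformed OD series.

The features follow the micro-cultivation phenomics convention: the maximal
specific growth rate µmax is the steepest log-linear slope that is *stable*
— a single ordinary-least-squares fit over a contiguous window of at least
4 h reaching r² > 0.995; the lag phase is the time-intercept of that
steepest-slope tangent with the starting density level; the endpoint
(stationary phase entry) is where the local rate first drops below
0.025 h⁻¹ (doubling time 27.7 h) after the µmax window; on rich medium,
where cultures do not reach stationary phase within the observation window,
the OD at the diauxic shift (local rate dropping below 0.07 h⁻¹) is used
instead. All rates are natural-log per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import GrowthConfig
from .plate_io import CorrectedSeries

__all__ = [
    "RateSeries",
    "MaxRateFit",
    "GrowthParameters",
    "rolling_log_slope",
    "fit_max_growth_rate",
    "lag_time",
    "detect_endpoint",
    "detect_diauxic_shift",
    "count_generations",
    "doubling_time",
    "profile_well",
    "parameters_table",
]

_EPS = 1e-9


@dataclass
class RateSeries:
    """Local slope of log-OD from a centered rolling OLS window.

    ``times`` are window centers (hours), ``rate`` the window slope in
    natural-log units per hour, ``r2`` the window fit quality. Windows
    containing undefined log-OD yield NaN.
    """

    times: np.ndarray
    rate: np.ndarray
    r2: np.ndarray
    window_h: float

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.rate) == len(self.r2)):
            raise ValueError("RateSeries arrays must have equal length")


@dataclass(frozen=True)
class MaxRateFit:
    """Result of the steepest-stable-window search.

    ``mu`` is None when no window passed the stability gate; ``message``
    then carries a diagnostic. ``start``/``end`` are sample indices of the
    winning window (inclusive).
    """

    mu: float | None
    window: tuple[float, float] | None
    r2: float | None
    start: int | None = None
    end: int | None = None
    n_candidates: int = 0
    message: str = ""


@dataclass
class GrowthParameters:
    """Extracted features of one well; None marks an undefined feature."""

    well_id: str = ""
    strain: str = ""
    condition: str = ""
    replicate: int = 1
    mu_max: float | None = None
    mu_window: tuple[float, float] | None = None
    mu_r2: float | None = None
    lag: float | None = None
    endpoint_time: float | None = None
    endpoint_od: float | None = None
    diauxic_time: float | None = None
    diauxic_od: float | None = None
    generations: float | None = None


class _WindowOLS:
    """O(1) per-window OLS statistics via prefix sums.

    Windows that contain any non-finite y are reported invalid. For a
    zero-variance (exactly constant) window the fit is exact, so r² is
    defined as 1 and the slope as 0.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        ok = np.isfinite(y)
        y0 = np.where(ok, y, 0.0)
        z = np.zeros(1)
        self.x = x
        self.nbad = np.concatenate([z, np.cumsum(~ok)])
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.sy = np.concatenate([z, np.cumsum(y0)])
        self.syy = np.concatenate([z, np.cumsum(y0 * y0)])
        self.sxy = np.concatenate([z, np.cumsum(x * y0)])

    def stats(self, i, j):
        """Slope, intercept, r2, valid for inclusive index windows [i, j]."""
        i = np.asarray(i)
        j = np.asarray(j)
        n = (j - i + 1).astype(float)
        valid = (self.nbad[j + 1] - self.nbad[i]) == 0
        sx = self.sx[j + 1] - self.sx[i]
        sy = self.sy[j + 1] - self.sy[i]
        sxx = self.sxx[j + 1] - self.sxx[i]
        syy = self.syy[j + 1] - self.syy[i]
        sxy = self.sxy[j + 1] - self.sxy[i]
        sxx_c = sxx - sx * sx / n
        syy_c = np.maximum(syy - sy * sy / n, 0.0)
        sxy_c = sxy - sx * sy / n
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = sxy_c / sxx_c
            r2 = np.where(syy_c > 0, sxy_c * sxy_c / (sxx_c * syy_c), 1.0)
        intercept = (sy - slope * sx) / n
        return slope, intercept, np.clip(r2, 0.0, 1.0), valid


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Plain two-pass OLS: slope, intercept, r² (r²=1 for an exact fit)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    syy = np.sum((y - ym) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    r2 = 1.0 if syy <= 0 else min(1.0, (sxy * sxy) / (sxx * syy))
    return float(slope), float(ym - slope * xm), float(r2)


def rolling_log_slope(series: CorrectedSeries, window_h: float = 4.0) -> RateSeries:
    """Rolling OLS slope (and r²) of log-OD over a fixed-length window.

    The window spans ``window_h`` hours on the (uniform) sampling grid and
    the slope is reported at the window center.
    """
    t = series.times
    dt = series.interval
    n_w = int(round(window_h / dt)) + 1
    if n_w < 2:
        raise ValueError("window shorter than the sampling interval")
    if len(t) < n_w:
        raise ValueError(
            f"series of {len(t)} points is shorter than one {window_h} h window"
        )
    reg = _WindowOLS(t, series.log_od)
    starts = np.arange(len(t) - n_w + 1)
    ends = starts + n_w - 1
    slope, _, r2, valid = reg.stats(starts, ends)
    slope = np.where(valid, slope, np.nan)
    r2 = np.where(valid, r2, np.nan)
    centers = (t[starts] + t[ends]) / 2.0
    return RateSeries(times=centers, rate=slope, r2=r2, window_h=window_h)


def fit_max_growth_rate(
    series: CorrectedSeries,
    min_window_h: float = 4.0,
    r2_min: float = 0.995,
    max_window_h: float = 8.0,
    full_enumeration: bool = False,
) -> MaxRateFit:
    """Steepest stable log-linear slope: max OLS slope over qualifying windows.

    Candidate windows are every contiguous stretch of samples spanning at
    least ``min_window_h`` hours (and at most ``max_window_h`` unless
    ``full_enumeration``); a window qualifies when its single log-linear fit
    reaches r² > ``r2_min``. Ties break to the earliest window. When no
    window qualifies the result carries ``mu=None`` and a diagnostic.
    """
    t = series.times
    n = len(t)
    if t[-1] - t[0] < min_window_h - _EPS:
        return MaxRateFit(None, None, None, message="series shorter than one window")
    reg = _WindowOLS(t, series.log_od)
    best_slope = -np.inf
    best: tuple[int, int, float, float] | None = None
    n_candidates = 0
    for i in range(n):
        lo = np.searchsorted(t, t[i] + min_window_h - _EPS)
        if lo >= n:
            break
        if full_enumeration:
            hi = n - 1
        else:
            hi = int(np.searchsorted(t, t[i] + max_window_h + _EPS, side="right")) - 1
            if hi < lo:
                continue
        ends = np.arange(lo, hi + 1)
        slope, _, r2, valid = reg.stats(np.full_like(ends, i), ends)
        good = valid & (r2 > r2_min)
        n_candidates += int(len(ends))
        if not np.any(good):
            continue
        k = int(np.argmax(np.where(good, slope, -np.inf)))
        if good[k] and slope[k] > best_slope:
            best_slope = float(slope[k])
            best = (i, int(ends[k]), float(slope[k]), float(r2[k]))
    if best is None:
        return MaxRateFit(
            None,
            None,
            None,
            n_candidates=n_candidates,
            message=f"no window of >= {min_window_h} h reached r^2 > {r2_min}",
        )
    i, j, slope, r2 = best
    return MaxRateFit(
        mu=slope,
        window=(float(t[i]), float(t[j])),
        r2=r2,
        start=i,
        end=j,
        n_candidates=n_candidates,
    )


def lag_time(
    series: CorrectedSeries,
    fit: MaxRateFit,
    baseline: float | None = None,
    baseline_points: int = 3,
    intercept: str = "baseline",
) -> float | None:
    """Lag phase: time-intercept of the steepest-slope tangent.

    The tangent is the OLS line fitted over the µmax window. In the default
    ``"baseline"`` convention the lag is where that line crosses the starting
    log-OD level (mean of the first ``baseline_points`` samples, or an
    explicit ``baseline``); the ``"time-axis"`` alternative intersects
    ln(OD) = 0. Negative intersections clip to 0. Undefined (None) when µmax
    is undefined or non-positive.
    """
    if fit.mu is None or fit.mu <= 0:
        return None
    slope, icpt, _ = _ols(
        series.times[fit.start : fit.end + 1], series.log_od[fit.start : fit.end + 1]
    )
    if intercept == "time-axis":
        level = 0.0
    elif intercept == "baseline":
        if baseline is None:
            head = series.log_od[:baseline_points]
            head = head[np.isfinite(head)]
            if len(head) == 0:
                return None
            level = float(np.mean(head))
        else:
            level = float(baseline)
    else:
        raise ValueError(f"unknown lag intercept convention {intercept!r}")
    return max(0.0, (level - icpt) / slope)


def _first_rate_drop(
    rates: RateSeries, after_time: float, threshold: float
) -> float | None:
    """Time of the first drop of the local rate below ``threshold`` after
    ``after_time``, interpolated linearly between adjacent window centers."""
    ok = np.isfinite(rates.rate)
    idx = np.nonzero(ok & (rates.times > after_time))[0]
    for k in idx:
        if rates.rate[k] < threshold:
            prev = k - 1
            while prev >= 0 and not np.isfinite(rates.rate[prev]):
                prev -= 1
            if prev >= 0 and rates.rate[prev] >= threshold:
                t0, t1 = rates.times[prev], rates.times[k]
                r0, r1 = rates.rate[prev], rates.rate[k]
                return float(t0 + (threshold - r0) * (t1 - t0) / (r1 - r0))
            return float(rates.times[k])
    return None


def detect_endpoint(
    series: CorrectedSeries,
    rates: RateSeries,
    fit: MaxRateFit,
    threshold: float = 0.025,
) -> tuple[float, float] | None:
    """Endpoint (stationary-phase entry): first time after the µmax window
    at which the local rate drops below ``threshold``; returns (time, OD)
    there, or None ("n.d.") if the culture never slows down that far within
    the observation window."""
    if fit.mu is None:
        return None
    t_cross = _first_rate_drop(rates, fit.window[1], threshold)
    if t_cross is None:
        return None
    od = float(np.interp(t_cross, series.times, series.od_corr))
    return t_cross, od


def detect_diauxic_shift(
    series: CorrectedSeries,
    rates: RateSeries,
    fit: MaxRateFit,
    threshold: float = 0.07,
) -> tuple[float, float] | None:
    """Diauxic shift: first downward crossing of ``threshold`` by the local
    rate after the µmax window, provided the culture grew above the
    threshold to begin with; returns (time, OD) or None."""
    if fit.mu is None or fit.mu <= threshold:
        return None
    t_cross = _first_rate_drop(rates, fit.window[1], threshold)
    if t_cross is None:
        return None
    od = float(np.interp(t_cross, series.times, series.od_corr))
    return t_cross, od


def count_generations(series: CorrectedSeries) -> float:
    """Population doublings over the series: log2 of the corrected-OD fold
    expansion between the first and last retained points."""
    first, last = series.od_corr[0], series.od_corr[-1]
    if first <= 0 or last <= 0:
        raise ValueError(
            f"well {series.well_id}: nonpositive corrected OD at series endpoints"
        )
    return float(np.log2(last / first))


def doubling_time(mu: float) -> float:
    """Doubling time ln(2)/µ in hours for a natural-log rate µ (h⁻¹)."""
    if mu <= 0:
        raise ValueError("doubling time requires a positive growth rate")
    return math.log(2.0) / mu


def profile_well(
    series: CorrectedSeries,
    cfg: GrowthConfig = GrowthConfig(),
    rich_medium: bool | None = None,
) -> GrowthParameters:
    """Extract all growth features of one well into a GrowthParameters record.

    On rich/complex medium (flagged explicitly or via the condition label in
    the config) the endpoint fields are replaced by the diauxic-shift values,
    because such cultures do not reach stationary phase within the
    observation window. A well with no detectable growth (no stable window
    with a positive slope) yields a record with every rate-derived feature
    undefined rather than an error.
    """
    out = GrowthParameters(
        well_id=series.well_id,
        strain=series.strain,
        condition=series.condition,
        replicate=series.replicate,
    )
    if rich_medium is None:
        rich_medium = series.condition in cfg.rich_medium_conditions
    try:
        out.generations = count_generations(series)
    except ValueError:
        out.generations = None

    try:
        rates = rolling_log_slope(series, cfg.min_window_h)
    except ValueError:
        return out
    fit = fit_max_growth_rate(
        series,
        min_window_h=cfg.min_window_h,
        r2_min=cfg.r2_min,
        max_window_h=cfg.max_window_h,
        full_enumeration=cfg.full_enumeration,
    )
    if fit.mu is None or fit.mu <= 0:
        return out
    out.mu_max = fit.mu
    out.mu_window = fit.window
    out.mu_r2 = fit.r2
    out.lag = lag_time(
        series,
        fit,
        baseline_points=cfg.baseline_points,
        intercept=cfg.lag_intercept,
    )
    diauxic = detect_diauxic_shift(series, rates, fit, cfg.diauxic_rate_threshold)
    if diauxic is not None:
        out.diauxic_time, out.diauxic_od = diauxic
    if rich_medium:
        out.endpoint_time, out.endpoint_od = out.diauxic_time, out.diauxic_od
    else:
        endpoint = detect_endpoint(series, rates, fit, cfg.endpoint_rate_threshold)
        if endpoint is not None:
            out.endpoint_time, out.endpoint_od = endpoint
    return out


def parameters_table(params: Sequence[GrowthParameters]) -> pd.DataFrame:
    """Tidy table of growth parameters, one row per well; undefined features
    are written as the "n.d." literal."""

    def nd(v, fmt=lambda x: x):
        return "n.d." if v is None else fmt(v)

    rows = []
    for p in params:
        rows.append(
            {
                "well": p.well_id,
                "strain": p.strain,
                "condition": p.condition,
                "replicate": p.replicate,
                "mu_max": nd(p.mu_max),
                "mu_window_start": nd(p.mu_window, lambda w: w[0]),
                "mu_window_end": nd(p.mu_window, lambda w: w[1]),
                "mu_r2": nd(p.mu_r2),
                "lag": nd(p.lag),
                "endpoint_time": nd(p.endpoint_time),
                "endpoint_od": nd(p.endpoint_od),
                "diauxic_time": nd(p.diauxic_time),
                "diauxic_od": nd(p.diauxic_od),
                "generations": nd(p.generations),
            }
        )
    return pd.DataFrame(rows)
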