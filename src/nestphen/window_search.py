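"""Sliding-window selection of the SST predictor of annual phenology.

An annual phenology metric (e.g. population first nest date) is regressed on
the mean sea surface temperature over every candidate day-of-year window that
precedes the nesting season. Candidate windows are enumerated exhaustively
and ranked by AICc of the simple linear model ``metric ~ window mean``; the
intercept-only null model provides the reference AICc, so a strongly negative
``delta_aicc_vs_null`` flags a window whose temperature signal genuinely
predicts the response.

Windows are defined on the day-of-year grid of a 365-day (non-leap) calendar.
In leap years, dates from 1 March onwards are shifted back by one day so that
29 February shares slot 60 with 1 March; this keeps a window such as
29 March – 29 April (doy 88–119) aligned across years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: number of parameters of the slope model (intercept, slope, residual variance)
_K_SLOPE = 3
_K_NULL = 2


@dataclass(frozen=True)
class WindowSpec:
    """Inclusive day-of-year bounds of an averaging window (non-leap calendar)."""

    open_doy: int
    close_doy: int

    def __post_init__(self) -> None:
        if not 1 <= self.open_doy <= self.close_doy <= 365:
            raise ValueError("require 1 <= open_doy <= close_doy <= 365")

    @property
    def width(self) -> int:
        return self.close_doy - self.open_doy + 1


@dataclass(frozen=True)
class WindowResult:
    """One candidate window with its annual means and model score."""

    window: WindowSpec
    annual_means: tuple[tuple[int, float], ...]
    slope: float
    slope_se: float
    aicc: float
    null_aicc: float

    @property
    def delta_aicc_vs_null(self) -> float:
        return self.aicc - self.null_aicc


def _noleap_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map calendar dates onto the 365-day doy grid (29 Feb -> slot 60)."""
    doy = dates.dayofyear.to_numpy().copy()
    leap = dates.is_leap_year
    doy[leap & (doy > 60)] -= 1
    return doy


def _series_frame(series: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Normalize a daily series to columns year / doy / value."""
    if isinstance(series, pd.Series):
        dates = pd.DatetimeIndex(series.index)
        values = series.to_numpy(dtype=float)
    else:
        cols = list(series.columns)
        if len(cols) < 2:
            raise ValueError("daily series needs date and value columns")
        dates = pd.DatetimeIndex(pd.to_datetime(series[cols[0]]))
        values = series[cols[1]].to_numpy(dtype=float)
    if dates.has_duplicates:
        raise ValueError("daily series has duplicate dates")
    if not dates.is_monotonic_increasing:
        order = np.argsort(dates.to_numpy())
        dates, values = dates[order], values[order]
    if not np.all(np.isfinite(values)):
        raise ValueError("daily series values must be finite")
    return pd.DataFrame(
        {"year": dates.year.to_numpy(), "doy": _noleap_doy(dates), "value": values}
    )


def _year_doy_grids(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(years, sum grid, count grid) with one row per year, 365 doy columns."""
    years = np.unique(df["year"].to_numpy())
    year_idx = np.searchsorted(years, df["year"].to_numpy())
    sums = np.zeros((len(years), 365))
    counts = np.zeros((len(years), 365))
    np.add.at(sums, (year_idx, df["doy"].to_numpy() - 1), df["value"].to_numpy())
    np.add.at(counts, (year_idx, df["doy"].to_numpy() - 1), 1.0)
    return years, sums, counts


def window_mean(
    series: pd.DataFrame | pd.Series,
    window: WindowSpec,
    year: int,
    min_completeness: float = 0.5,
) -> float:
    """Mean of the daily values falling in ``window`` for ``year``.

    Returns NaN (and logs) when fewer than ``min_completeness`` of the
    window's days carry a value.
    """
    df = _series_frame(series)
    sel = df[
        (df["year"] == year)
        & (df["doy"] >= window.open_doy)
        & (df["doy"] <= window.close_doy)
    ]
    if len(sel) < min_completeness * window.width:
        log.warning(
            "window %d-%d in %d has %d/%d days; below completeness %.0f%%",
            window.open_doy, window.close_doy, year, len(sel), window.width,
            100 * min_completeness,
        )
        return float("nan")
    return float(sel["value"].mean())


def annual_window_means(
    series: pd.DataFrame | pd.Series,
    window: WindowSpec,
    min_completeness: float = 0.5,
) -> pd.Series:
    """Window mean for every year present in the series (NaN if incomplete)."""
    df = _series_frame(series)
    years, sums, counts = _year_doy_grids(df)
    lo, hi = window.open_doy - 1, window.close_doy
    s = sums[:, lo:hi].sum(axis=1)
    c = counts[:, lo:hi].sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(c >= min_completeness * window.width, s / c, np.nan)
    return pd.Series(means, index=years, name="window_mean")


def _ols_lines(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, slope se, max log-likelihood) of y ~ 1 + x."""
    n = len(y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - slope * xc
    rss = float(resid @ resid)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    se = np.sqrt(rss / (n - 2) / sxx)
    return slope, se, ll


def _aicc(ll: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return float("inf")
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def search_windows(
    series: pd.DataFrame | pd.Series,
    response: pd.DataFrame,
    candidate_range: tuple[int, int] = (1, 140),
    min_width: int = 7,
    min_completeness: float = 0.5,
) -> list[WindowResult]:
    """Exhaustive window search, ranked by AICc (best first).

    ``response`` has columns year / value, one row per year. Years whose
    response is missing, or for which any candidate window is incomplete, are
    dropped from the whole search so every window is scored on the same year
    set (a requirement for AICc comparability). Requires >= 5 paired years.
    Ties in AICc break towards narrower, earlier windows.
    """
    lo, hi = candidate_range
    if not 1 <= lo <= hi <= 365:
        raise ValueError("candidate_range must lie within doy 1..365")
    if min_width < 1 or lo + min_width - 1 > hi:
        raise ValueError("min_width does not fit in candidate_range")

    rcols = list(response.columns)
    resp = (
        response.rename(columns={rcols[0]: "year", rcols[1]: "value"})
        .dropna()
        .astype({"year": int})
    )
    df = _series_frame(series)
    years, sums, counts = _year_doy_grids(df)

    # cumulative sums over doy -> O(1) range means per (window, year)
    csum = np.concatenate([np.zeros((len(years), 1)), sums.cumsum(axis=1)], axis=1)
    ccnt = np.concatenate([np.zeros((len(years), 1)), counts.cumsum(axis=1)], axis=1)

    opens, closes = [], []
    for o in range(lo, hi - min_width + 2):
        for c in range(o + min_width - 1, hi + 1):
            opens.append(o)
            closes.append(c)
    opens = np.array(opens)
    closes = np.array(closes)
    widths = closes - opens + 1

    # (n_windows, n_years) sums/counts
    wsum = csum[:, closes].T - csum[:, opens - 1].T
    wcnt = ccnt[:, closes].T - ccnt[:, opens - 1].T
    complete = wcnt >= min_completeness * widths[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = np.where(complete, wsum / wcnt, np.nan)

    # common year set: response years with every window complete
    resp = resp[resp["year"].isin(years)]
    yidx = np.searchsorted(years, resp["year"].to_numpy())
    ok = complete[:, yidx].all(axis=0)
    if not ok.all():
        dropped = resp["year"].to_numpy()[~ok]
        log.warning("dropping years with incomplete SST coverage: %s", list(dropped))
    resp = resp[ok]
    yidx = yidx[ok]
    n = len(resp)
    if n < 5:
        raise ValueError(f"only {n} paired years; need at least 5")

    y = resp["value"].to_numpy(dtype=float)
    X = wmean[:, yidx]  # (n_windows, n)

    # vectorized per-window OLS
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=1)
    slope = (xc @ yc) / sxx
    rss = float(yc @ yc) - slope**2 * sxx
    rss = np.maximum(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    se = np.sqrt(rss / (n - 2) / sxx)
    aicc = _aicc_vec(ll, _K_SLOPE, n)

    null_rss = float(yc @ yc)
    null_ll = -0.5 * n * (np.log(2 * np.pi * null_rss / n) + 1)
    null_aicc = _aicc(null_ll, _K_NULL, n)

    order = np.lexsort((opens, widths, aicc))
    results = []
    resp_years = resp["year"].to_numpy()
    for i in order:
        results.append(
            WindowResult(
                window=WindowSpec(int(opens[i]), int(closes[i])),
                annual_means=tuple(zip(resp_years.tolist(), X[i].tolist())),
                slope=float(slope[i]),
                slope_se=float(se[i]),
                aicc=float(aicc[i]),
                null_aicc=null_aicc,
            )
        )
    return results


def _aicc_vec(ll: np.ndarray, k: int, n: int) -> np.ndarray:
    if n - k - 1 <= 0:
        return np.full_like(ll, np.inf)
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def permutation_check(
    series: pd.DataFrame | pd.Series,
    response: pd.DataFrame,
    candidate_range: tuple[int, int] = (1, 140),
    min_width: int = 7,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Best delta-AICc under response-year shuffling (overfitting gauge).

    Re-runs the full search ``n_permutations`` times with the response values
    permuted across years, returning the best (most negative) delta AICc of
    each permutation. A real signal should beat this null distribution.
    """
    rng = np.random.default_rng(seed)
    rcols = list(response.columns)
    resp = response.rename(columns={rcols[0]: "year", rcols[1]: "value"}).dropna()
    best = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = resp.copy()
        shuffled["value"] = rng.permutation(shuffled["value"].to_numpy())
        res = search_windows(series, shuffled, candidate_range, min_width)
        best[i] = res[0].delta_aicc_vs_null
    return best


def results_to_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.window.open_doy,
                r.window.close_doy,
                r.slope,
                r.slope_se,
                r.aicc,
                r.delta_aicc_vs_null,
            )
            for r in results
        ],
        columns=["open_doy", "close_doy", "slope", "slope_se", "aicc", "delta_aicc_vs_null"],
    )
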