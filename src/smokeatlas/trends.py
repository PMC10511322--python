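"""Linear trend estimation for annual series and annual rasters.

Trends are plain OLS of the annual value on calendar year, with the
two-sided t-test on the slope; slopes are reported both per year and per
decade (the conventional reporting unit for long-term air-quality change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fields import DailyField
from .grids import GridSpec

MIN_YEARS = 3
ANNUAL_COMPLETENESS = 0.75


@dataclass
class TrendFit:
    """OLS trend of an annual series on year."""

    slope_per_year: float
    intercept: float
    p_value: float
    n_years: int
    stderr: float

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.slope_per_year

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.n_years - 2)
        return (self.slope_per_year - t * self.stderr,
                self.slope_per_year + t * self.stderr)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return "\n".join([
            "Linear trend (OLS on year)",
            "=" * 40,
            f"years:            {self.n_years}",
            f"slope per year:   {self.slope_per_year:.6g}",
            f"slope per decade: {self.slope_per_decade:.6g}",
            f"95% CI (per yr):  [{lo:.6g}, {hi:.6g}]",
            f"p-value:          {self.p_value:.4g}"
            + ("  (significant at 0.05)" if self.significant else ""),
        ])


def fit_trend(values, years=None) -> TrendFit:
    """OLS of annual values on year; p from the two-sided slope t-test.

    ``values`` may be a Series indexed by year or an array with ``years``
    given separately; NaN years are dropped.  At least 3 non-missing years
    are required.
    """
    if isinstance(values, pd.Series):
        years = values.index.to_numpy(float)
        values = values.to_numpy(float)
    else:
        values = np.asarray(values, dtype=float)
        years = (np.asarray(years, dtype=float) if years is not None
                 else np.arange(len(values), dtype=float))
    ok = np.isfinite(values) & np.isfinite(years)
    values, years = values[ok], years[ok]
    if len(values) < MIN_YEARS:
        raise ValueError(f"at least {MIN_YEARS} annual values required")
    if np.ptp(years) == 0:
        raise ValueError("year has zero variance")
    res = stats.linregress(years, values)
    return TrendFit(slope_per_year=float(res.slope), intercept=float(res.intercept),
                    p_value=float(res.pvalue), n_years=len(values),
                    stderr=float(res.stderr))


def annual_means(field: DailyField, completeness: float = ANNUAL_COMPLETENESS):
    """Calendar-year mean of a daily field per cell.

    A cell-year with less than ``completeness`` of its days non-missing is
    NaN.  Returns (years array, values array (year, lat, lon)).
    """
    years = np.array(sorted(set(field.dates.year)))
    out = np.full((len(years),) + field.grid.shape, np.nan)
    for yi, y in enumerate(years):
        sel = field.dates.year == y
        block = field.values[sel]
        n_days = sel.sum()
        good = np.isfinite(block).sum(axis=0)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(block, axis=0)
        out[yi] = np.where(good >= completeness * n_days, m, np.nan)
    return years, out


def grid_trends(years: np.ndarray, annual: np.ndarray,
                grid: GridSpec | None = None):
    """Cell-wise OLS trend of annual rasters; vectorized closed form.

    ``annual`` is (year, lat, lon); cells with fewer than 3 non-missing
    years give NaN slope and p.  Returns (slope_per_year, p_value) rasters.
    """
    years = np.asarray(years, dtype=float)
    nt = len(years)
    vals = np.asarray(annual, dtype=float).reshape(nt, -1)
    mask = np.isfinite(vals)
    n = mask.sum(axis=0)

    yr = np.where(mask, years[:, None], np.nan)
    v = np.where(mask, vals, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ym = np.nanmean(yr, axis=0)
        vm = np.nanmean(v, axis=0)
        sxy = np.nansum((yr - ym) * (v - vm), axis=0)
        sxx = np.nansum((yr - ym) ** 2, axis=0)
        slope = sxy / sxx
        resid = v - (vm + slope * (yr - ym))
        sse = np.nansum(resid ** 2, axis=0)
        dof = n - 2
        sigma2 = sse / np.maximum(dof, 1)
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(dof, 1))
    bad = (n < MIN_YEARS) | (sxx == 0)
    slope[bad] = np.nan
    p[bad] = np.nan
    # exact-fit cells: zero residual variance makes t infinite -> p = 0
    p[np.isfinite(slope) & (se == 0)] = 0.0
    shape = annual.shape[1:]
    return slope.reshape(shape), p.reshape(shape)


def field_trends(field: DailyField, completeness: float = ANNUAL_COMPLETENESS):
    """Annual-mean trend rasters straight from a daily field."""
    years, annual = annual_means(field, completeness)
    return grid_trends(years, annual, field.grid)
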