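"""Unit conversion and meteorological covariate derivation.

Daily covariates are aggregated in each grid cell's *local* day, with the
time zone approximated as UTC + round(lon / 15°) hours — reproducible
without a timezone database.  A local day with fewer than 75% of its hourly
values present aggregates to NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .fields import DailyField
from .grids import GridSpec

# ideal-gas conversion for ozone at 25.5 degC and standard pressure
MW_O3 = 48.00          # g / mol
T_REF_K = 298.65       # K  (25.5 degC)
P_REF_KPA = 101.325    # kPa
R_GAS = 8.314462618    # J / (mol K)

#: µg m-3 per ppb for ozone; rounds to the conventional 1.96
OZONE_PPB_FACTOR = MW_O3 * P_REF_KPA / (R_GAS * T_REF_K)

MIN_HOURS_PER_DAY = 18          # 75% of 24
MDA8_MIN_HOURS_PER_WINDOW = 6   # of 8
MDA8_MIN_WINDOWS = 18           # of 24


def ppb_to_ugm3(value_ppb):
    """Convert an ozone mixing ratio in ppb to µg m-3 (1 ppb ≈ 1.96 µg m-3)."""
    return np.asarray(value_ppb, dtype=float) * OZONE_PPB_FACTOR


def relative_humidity(t_mean_c, t_dew_c):
    """Daily mean relative humidity (%) from mean and dew-point temperature.

    Uses the Magnus form e(T) = exp(17.625 T / (243.04 + T)); RH is the ratio
    of vapour pressure at the dew point to saturation vapour pressure,
    clipped into (0, 100].  A dew point above the air temperature is
    physically saturated air and clips to 100 with a warning.
    """
    t = np.asarray(t_mean_c, dtype=float)
    td = np.asarray(t_dew_c, dtype=float)
    if np.any(td > t + 1e-9):
        warnings.warn("dew point above air temperature; RH clipped to 100%",
                      stacklevel=2)
    rh = 100.0 * np.exp(17.625 * td / (243.04 + td)) / np.exp(17.625 * t / (243.04 + t))
    rh = np.minimum(rh, 100.0)
    return rh if rh.ndim else float(rh)


def local_utc_offset_hours(lon) -> np.ndarray:
    """Grid-cell time zone: whole hours, UTC + round(lon / 15)."""
    lon = np.asarray(lon, dtype=float)
    off = np.round(lon / 15.0).astype(int)
    return off


def _daily_reduce(frame: pd.DataFrame, how: str) -> pd.DataFrame:
    grouped = frame.groupby(frame.index.floor("D"))
    counts = grouped.count()
    if how == "mean":
        out = grouped.mean()
    elif how == "min":
        out = grouped.min()
    elif how == "max":
        out = grouped.max()
    elif how == "std":
        out = grouped.std(ddof=1)
    elif how == "sum":
        out = grouped.sum()
    else:  # pragma: no cover
        raise ValueError(how)
    return out.where(counts >= MIN_HOURS_PER_DAY)


_AGGREGATIONS = {
    "Tmean": ("temp", "mean"),
    "Tmin": ("temp", "min"),
    "Tmax": ("temp", "max"),
    "TV": ("temp", "std"),
    "Tdew_mean": ("dewpoint", "mean"),
    "Wind_u": ("wind_u", "mean"),
    "Wind_v": ("wind_v", "mean"),
    "Precip": ("precip", "sum"),
    "Pressure": ("pressure", "mean"),
    "UV": ("uv", "mean"),
}

_UNITS = {"Tmean": "degC", "Tmin": "degC", "Tmax": "degC", "TV": "degC",
          "RH": "%", "Wind_u": "m s-1", "Wind_v": "m s-1", "Precip": "mm",
          "Pressure": "kPa", "UV": "W m-2"}


def daily_met_from_hourly(hourly: xr.Dataset, grid: GridSpec) -> dict[str, DailyField]:
    """Aggregate hourly meteorology to local-day covariate fields.

    Parameters
    ----------
    hourly : xarray.Dataset
        Dimensions (time, lat, lon) with hourly UTC timestamps and any of
        the variables ``temp``/``dewpoint`` (degC), ``wind_u``/``wind_v``
        (m/s), ``precip`` (mm), ``pressure`` (kPa), ``uv`` (W/m2).
    grid : GridSpec
        Output grid; must match the dataset's lat/lon coordinates.

    Returns
    -------
    dict of name -> DailyField
        Tmean/Tmin/Tmax/TV (and RH when dewpoint is present) plus daily
        means of the remaining variables, restricted to local days with at
        least 75% hourly coverage in every cell reported.
    """
    times = pd.DatetimeIndex(hourly.time.values)
    nlat, nlon = grid.nlat, grid.nlon
    offsets = local_utc_offset_hours(grid.lons)

    per_var_frames: dict[str, list[pd.DataFrame]] = {}
    columns: list[tuple[int, int]] = []
    for j in range(nlon):
        columns.extend((i, j) for i in range(nlat))

    for name, (src, how) in _AGGREGATIONS.items():
        if src not in hourly:
            continue
        arr = hourly[src].transpose("time", "lat", "lon").values.astype(float)
        pieces = []
        for off in np.unique(offsets):
            jsel = np.where(offsets == off)[0]
            local_times = times + pd.Timedelta(hours=int(off))
            block = arr[:, :, jsel].reshape(len(times), -1)
            frame = pd.DataFrame(block, index=local_times)
            frame.columns = pd.MultiIndex.from_product([jsel, range(nlat)])
            pieces.append(_daily_reduce(frame, how))
        combined = pd.concat(pieces, axis=1)
        per_var_frames[name] = combined

    # day axis: union of local days, trimmed of the partial edge days that
    # no cell completes; interior incomplete cell-days stay as NaN rows
    union = None
    for frame in per_var_frames.values():
        union = frame.index if union is None else union.union(frame.index)
    if union is None or len(union) == 0:
        raise ValueError("no local day in the hourly record")
    any_data = np.zeros(len(union), dtype=bool)
    for frame in per_var_frames.values():
        any_data |= frame.reindex(union).notna().any(axis=1).to_numpy()
    if not any_data.any():
        raise ValueError("no complete local day in the hourly record")
    first, last = np.where(any_data)[0][[0, -1]]
    all_days = union[first:last + 1]

    out: dict[str, DailyField] = {}
    for name, frame in per_var_frames.items():
        frame = frame.reindex(all_days)
        vals = np.full((len(all_days), nlat, nlon), np.nan)
        for (j, i) in frame.columns:
            vals[:, i, j] = frame[(j, i)].to_numpy()
        out[name] = DailyField(grid, all_days, vals, name=name,
                               units=_UNITS.get(name, ""))

    if "Tmean" in out and "Tdew_mean" in out:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rh = relative_humidity(out["Tmean"].values, out["Tdew_mean"].values)
        out["RH"] = DailyField(grid, all_days, rh, name="RH", units="%")
    return out


def mda8(hourly_o3) -> float:
    """Daily maximum 8-hour running-mean ozone.

    ``hourly_o3`` holds the 24 hours of one local day optionally followed by
    up to 7 hours of the next day (31 values); shorter inputs are padded
    with NaN.  Each of the 24 windows starting at local hours 0..23 is
    computable when at least 6 of its 8 hours are present; the day needs at
    least 18 computable windows, else NaN.
    """
    x = np.asarray(hourly_o3, dtype=float).ravel()
    if len(x) > 31:
        raise ValueError("at most 24 + 7 hourly values expected")
    x = np.concatenate([x, np.full(31 - len(x), np.nan)])
    means = np.full(24, np.nan)
    for h in range(24):
        win = x[h:h + 8]
        if np.isfinite(win).sum() >= MDA8_MIN_HOURS_PER_WINDOW:
            means[h] = np.nanmean(win)
    if np.isfinite(means).sum() < MDA8_MIN_WINDOWS:
        return float("nan")
    return float(np.nanmax(means))
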