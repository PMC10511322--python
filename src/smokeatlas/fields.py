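"""Daily gridded fields, station series and population rasters, with file I/O.

NetCDF I/O follows CF conventions (``time``/``lat``/``lon`` dimensions with a
``units`` attribute on data variables) and goes through xarray.  Files with
descending latitudes are reordered to the package's ascending-latitude
convention on read.  Station tables are plain CSV with columns
``station_id, lon, lat, date, pollutant, value_ugm3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, locate_cell, normalize_lon


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


_NONNEG_HINTS = ("pm25", "o3", "precip", "uv", "population")


@dataclass
class DailyField:
    """A daily time-stack of one variable on a regular lat/lon grid.

    ``values`` is a float array indexed (date, lat, lon); missing data are
    NaN.  Concentration variables are expected to be non-negative.
    """

    grid: GridSpec
    dates: pd.DatetimeIndex
    values: np.ndarray
    name: str = "field"
    units: str = "ug m-3"

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dates), self.grid.nlat, self.grid.nlon)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def ndates(self) -> int:
        return len(self.dates)

    def copy_with(self, **kw) -> "DailyField":
        if "values" in kw:
            kw.setdefault("grid", self.grid)
            kw.setdefault("dates", self.dates)
            return DailyField(kw["grid"], kw["dates"], kw["values"],
                              kw.get("name", self.name), kw.get("units", self.units))
        return replace(self, **kw)

    def sample(self, lon: float, lat: float) -> np.ndarray:
        """Per-date series at the cell containing a point."""
        i, j = locate_cell(self.grid, lon, lat)
        return self.values[:, i, j]

    def to_xarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.dates, "lat": self.grid.lats, "lon": self.grid.lons},
            name=self.name,
            attrs={"units": self.units},
        )

    def aligned_with(self, other: "DailyField") -> bool:
        return self.grid == other.grid and self.dates.equals(other.dates)


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> GridSpec:
    for name, c in (("lat", lat), ("lon", lon)):
        if len(c) > 1:
            steps = np.diff(c)
            if np.max(np.abs(steps - steps[0])) > 1e-6:
                raise FormatError(f"irregular {name} spacing")
    dlat = float(lat[1] - lat[0]) if len(lat) > 1 else 1.0
    dlon = float(lon[1] - lon[0]) if len(lon) > 1 else 1.0
    return GridSpec(lat0=float(lat[0]), lon0=float(lon[0]), dlat=dlat, dlon=dlon,
                    nlat=len(lat), nlon=len(lon))


def read_field(path, variable: str | None = None) -> DailyField:
    """Read one variable of a CF-style NetCDF file as a :class:`DailyField`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        for dim in ("time", "lat", "lon"):
            if dim not in ds.coords:
                raise FormatError(f"missing coordinate variable {dim!r}")
        if variable is None:
            candidates = [v for v in ds.data_vars if set(ds[v].dims) == {"time", "lat", "lon"}]
            if len(candidates) != 1:
                raise FormatError("variable must be named when the file holds several")
            variable = candidates[0]
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not in file")
        da = ds[variable].transpose("time", "lat", "lon")
        lat = da.lat.values.astype(float)
        if len(lat) > 1 and lat[1] < lat[0]:      # descending-lat files
            da = da.isel(lat=slice(None, None, -1))
            lat = da.lat.values.astype(float)
        grid = _grid_from_coords(lat, da.lon.values.astype(float))
        return DailyField(grid=grid, dates=pd.DatetimeIndex(da.time.values),
                          values=da.values.astype(float), name=variable,
                          units=str(da.attrs.get("units", "")))


def write_field(fld: DailyField, path) -> None:
    fld.to_xarray().to_dataset().to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# stations

@dataclass
class StationSeries:
    """Daily observations of one pollutant at a set of point stations.

    ``table`` holds one row per station-date with columns
    ``station_id, lon, lat, date, value_ugm3``; ``pollutant`` is either
    ``"pm25"`` (daily mean) or ``"o3"`` (daily max 8 h).
    """

    pollutant: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        req = {"station_id", "lon", "lat", "date", "value_ugm3"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"station table missing columns {sorted(missing)}")
        t = self.table.copy()
        t["date"] = pd.to_datetime(t["date"])
        t["lon"] = normalize_lon(t["lon"].to_numpy(float))
        if t.duplicated(["station_id", "date"]).any():
            raise ValueError("one record per station-date required")
        vals = t["value_ugm3"].to_numpy(float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("concentrations must be >= 0 or NaN")
        self.table = t.reset_index(drop=True)

    @property
    def station_ids(self) -> np.ndarray:
        return np.sort(self.table["station_id"].unique())

    def coordinates(self) -> pd.DataFrame:
        """One row per station: station_id, lon, lat."""
        return (self.table.groupby("station_id", as_index=False)[["lon", "lat"]]
                .first().sort_values("station_id").reset_index(drop=True))

    def series(self, station_id) -> pd.Series:
        sub = self.table[self.table["station_id"] == station_id]
        if sub.empty:
            raise KeyError(f"unknown station {station_id!r}")
        return sub.set_index("date")["value_ugm3"].sort_index()


def read_stations(path, pollutant: str | None = None) -> StationSeries:
    t = pd.read_csv(path)
    if "pollutant" not in t.columns:
        raise FormatError("station CSV missing 'pollutant' column")
    if pollutant is None:
        polls = t["pollutant"].unique()
        if len(polls) != 1:
            raise FormatError("pollutant must be named for multi-pollutant files")
        pollutant = polls[0]
    t = t[t["pollutant"] == pollutant].drop(columns=["pollutant"])
    return StationSeries(pollutant=pollutant, table=t)


def write_stations(stations: StationSeries, path) -> None:
    t = stations.table.copy()
    t["pollutant"] = stations.pollutant
    t["date"] = t["date"].dt.strftime("%Y-%m-%d")
    t.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# population

@dataclass
class PopulationRaster:
    """Annual per-cell population counts with a country partition.

    ``counts`` is (nlat, nlon) persons per cell; ``country_id`` an integer
    raster (-1 for no-country cells such as ocean); ``reference_totals`` maps
    country_id -> official national total used for rescaling.
    """

    grid: GridSpec
    year: int
    counts: np.ndarray
    country_id: np.ndarray
    reference_totals: dict[int, float]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.country_id = np.asarray(self.country_id, dtype=int)
        if self.counts.shape != self.grid.shape or self.country_id.shape != self.grid.shape:
            raise ValueError("raster shapes must match the grid")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be >= 0")
        if np.any((self.counts > 0) & (self.country_id < 0)):
            raise ValueError("every populated cell needs a country_id")
        present = np.unique(self.country_id[self.country_id >= 0])
        for c in present:
            if self.reference_totals.get(int(c), 0.0) <= 0:
                raise ValueError(f"country {c} lacks a positive reference total")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def country_sums(self) -> dict[int, float]:
        out = {}
        for c in np.unique(self.country_id[self.country_id >= 0]):
            out[int(c)] = float(self.counts[self.country_id == c].sum())
        return out
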