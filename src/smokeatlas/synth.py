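"""Seeded synthetic world generator.

Generates every input the exposure pipeline consumes — a fine-grid "truth"
concentration field (smooth spatio-seasonal baseline plus episodic Gaussian
fire plumes), coarse chemical-transport output (block-mean of truth under a
smooth multiplicative spatial bias plus noise, with a companion fire
field), daily meteorological covariates that truth actually depends on, a
spatially clustered station network observing truth with recorded noise,
and an annual population raster partitioned into contiguous synthetic
countries whose official reference totals deliberately differ from the
raster sums.

Everything is driven by one seed fanned out into named substreams, so a
world is reproducible bit-exactly and each component can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import DailyField, PopulationRaster, StationSeries
from .grids import GridSpec, block_reduce_mean, coarsen_grid, locate_cell

_STREAMS = ("baseline", "covariates", "plumes", "bias", "chem_noise",
            "stations", "station_noise", "population", "countries")

COVARIATE_NAMES = ("Tmean", "Tmax", "Tmin", "TV", "RH", "Wind_u", "Wind_v",
                   "Precip", "Pressure", "UV")


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    The defaults describe the package's reference test world: a 10°×15°
    region on a 0.25° grid (40×60 cells) with a 2.0°×2.5° coarse grid
    (5×6 cells), two years of daily data, 120 stations per pollutant
    clustered with a realistic density imbalance, and 8 contiguous
    countries.
    """

    seed: int = 0
    lat0: float = -4.875
    lon0: float = 20.125
    nlat: int = 40
    nlon: int = 60
    cell_deg: float = 0.25
    block_lat: int = 8            # coarse cell = 8 x 10 fine cells (2.0 x 2.5 deg)
    block_lon: int = 10
    start: str = "2012-01-01"
    n_days: int = 731             # two calendar years
    n_stations_pm: int = 120
    n_stations_o3: int = 120
    n_station_clusters: int = 6
    station_cluster_sd_deg: float = 1.0
    n_countries: int = 8
    fire_events_per_year: float = 30.0
    plume_peak_ugm3: float = 45.0      # lognormal median of plume peak PM2.5
    plume_sigma_deg: tuple = (0.4, 1.2)
    plume_mean_duration_days: float = 6.0
    o3_negative_fraction: float = 0.15  # plumes whose O3 effect is negative
    bias_amplitude: float = 0.3
    bias_order: int = 2                 # spatial harmonics in the bias field
    chem_noise_sd: float = 1.0          # additive, on coarse totals (ug/m3)
    chem_fire_rel_noise: float = 0.1    # relative, on coarse fire fields
    obs_noise_sd_pm: float = 2.0
    obs_noise_sd_o3: float = 4.0
    pop_log_mean: float = 6.5           # log persons per 0.25 deg cell
    pop_log_sd: float = 1.2
    pop_growth_per_year: float = 0.015
    ref_factor_range: tuple = (0.85, 1.3)
    sfap_pm_threshold: float = 15.0
    sfap_o3_threshold: float = 100.0
    sfap_fire_share: float = 0.5

    def __post_init__(self):
        if self.nlat % self.block_lat or self.nlon % self.block_lon:
            raise ValueError("coarse blocks must tile the fine grid exactly")
        for v in (self.bias_amplitude, self.chem_noise_sd, self.obs_noise_sd_pm,
                  self.obs_noise_sd_o3, self.fire_events_per_year):
            if v < 0:
                raise ValueError("rates, amplitudes and SDs must be >= 0")

    @property
    def fine_grid(self) -> GridSpec:
        return GridSpec(self.lat0, self.lon0, self.cell_deg, self.cell_deg,
                        self.nlat, self.nlon)

    @property
    def coarse_grid(self) -> GridSpec:
        return coarsen_grid(self.fine_grid, self.block_lat, self.block_lon)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")


def tiny_config(seed: int = 0, **overrides) -> WorldConfig:
    """An 8×8-cell, 30-day world for unit tests (one coarse block of 4×4)."""
    kw = dict(seed=seed, nlat=8, nlon=8, block_lat=4, block_lon=4, n_days=30,
              n_stations_pm=10, n_stations_o3=10, n_station_clusters=2,
              n_countries=2, fire_events_per_year=60.0)
    kw.update(overrides)
    return WorldConfig(**kw)


@dataclass
class SyntheticWorld:
    """All inputs of the pipeline plus the generator's ground-truth records."""

    config: WorldConfig
    truth_total: dict[str, DailyField]          # pollutant -> fine field
    truth_fire: dict[str, DailyField]
    chem_total: dict[str, DailyField]           # pollutant -> coarse field
    chem_fire: dict[str, DailyField]
    covariates: dict[str, DailyField]
    stations: dict[str, StationSeries]
    station_noise: dict[str, pd.DataFrame] = dc_field(repr=False, default=None)
    population: list[PopulationRaster] = dc_field(default_factory=list)
    truth_exposure: pd.DataFrame | None = None

    @property
    def fine_grid(self) -> GridSpec:
        return self.config.fine_grid

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.config.dates


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _smooth_field(rng: np.random.Generator, grid: GridSpec, order: int = 3,
                  standardize: bool = True) -> np.ndarray:
    """Smooth random surface from low-order Fourier harmonics of lat/lon."""
    la, lo = grid.cell_centers()
    u = (la - la.min()) / max(np.ptp(la), 1e-9)
    v = (lo - lo.min()) / max(np.ptp(lo), 1e-9)
    out = np.zeros(grid.shape)
    for p in range(order + 1):
        for q in range(order + 1):
            if p == 0 and q == 0:
                continue
            amp = rng.normal() / (1.0 + p + q)
            phase = rng.uniform(0, 2 * np.pi)
            out += amp * np.cos(2 * np.pi * (p * u + q * v) + phase)
    if standardize:
        out = (out - out.mean()) / max(out.std(), 1e-9)
    return out


def _seasonal(doy: np.ndarray, phase: float, amplitude: float) -> np.ndarray:
    return 1.0 + amplitude * np.sin(2 * np.pi * doy / 365.25 + phase)


def _make_covariates(rng, grid, dates) -> dict[str, np.ndarray]:
    """Daily meteorology with seasonal structure and day-to-day weather."""
    nt = len(dates)
    doy = dates.dayofyear.to_numpy()
    season = np.sin(2 * np.pi * (doy - 15) / 365.25)

    spatial_t = _smooth_field(rng, grid)           # e.g. latitudinal climate
    weather = rng.normal(size=(nt, 1, 1)) * np.ones(grid.shape)
    weather = 0.6 * weather + 0.4 * rng.normal(size=(nt,) + grid.shape)

    tmean = 16.0 + 9.0 * season[:, None, None] + 3.0 * spatial_t + 2.5 * weather
    trange = 4.0 + 2.0 * np.abs(_smooth_field(rng, grid)) \
        + np.abs(rng.normal(0, 1.0, size=(nt,) + grid.shape))
    tv = trange / np.sqrt(2.0) + np.abs(rng.normal(0, 0.3, size=(nt,) + grid.shape))
    rh = np.clip(65.0 - 8.0 * season[:, None, None] + 6.0 * _smooth_field(rng, grid)
                 + 7.0 * rng.normal(size=(nt,) + grid.shape), 5.0, 100.0)
    wind_u = 1.5 * _smooth_field(rng, grid) + rng.normal(0, 1.5, size=(nt,) + grid.shape)
    wind_v = 1.0 * _smooth_field(rng, grid) + rng.normal(0, 1.5, size=(nt,) + grid.shape)
    precip = np.maximum(rng.gamma(0.6, 4.0, size=(nt,) + grid.shape)
                        * (1.0 + 0.5 * season[:, None, None]) - 1.0, 0.0)
    pressure = 101.0 + 0.4 * _smooth_field(rng, grid) \
        + 0.5 * rng.normal(size=(nt, 1, 1)) * np.ones(grid.shape)
    uv = np.maximum(25.0 + 12.0 * season[:, None, None] + 2.0 * _smooth_field(rng, grid)
                    + 3.0 * rng.normal(size=(nt,) + grid.shape), 0.0)
    return {"Tmean": tmean, "Tmax": tmean + trange / 2.0, "Tmin": tmean - trange / 2.0,
            "TV": tv, "RH": rh, "Wind_u": wind_u, "Wind_v": wind_v,
            "Precip": precip, "Pressure": pressure, "UV": uv}


def _met_modulation(cov: dict[str, np.ndarray], pollutant: str) -> np.ndarray:
    """Smooth nonlinear covariate link with interactions (learnable signal)."""
    if pollutant == "pm25":
        z = (0.30 * np.tanh((cov["Tmean"] - 18.0) / 8.0)
             + 0.20 * (cov["RH"] - 60.0) / 40.0
             - 0.08 * np.sqrt(cov["Wind_u"] ** 2 + cov["Wind_v"] ** 2)
             - 0.04 * cov["Precip"]
             + 0.10 * np.tanh((cov["Tmean"] - 18.0) / 8.0) * (cov["RH"] - 60.0) / 40.0)
    else:
        z = (0.45 * np.tanh((cov["Tmax"] - 22.0) / 8.0)
             + 0.25 * (cov["UV"] - 25.0) / 15.0
             - 0.15 * (cov["RH"] - 60.0) / 40.0
             + 0.08 * np.tanh((cov["Tmax"] - 22.0) / 8.0) * (cov["UV"] - 25.0) / 15.0)
    return np.exp(np.clip(z, -1.2, 1.2))


def _plant_plumes(rng, cfg: WorldConfig):
    """Episodic Gaussian fire plumes; returns PM and O3 fire truth arrays."""
    grid = cfg.fine_grid
    nt = cfg.n_days
    years = nt / 365.25
    n_events = rng.poisson(cfg.fire_events_per_year * years)
    la, lo = grid.cell_centers()
    fire_pm = np.zeros((nt,) + grid.shape)
    fire_o3 = np.zeros((nt,) + grid.shape)
    for _ in range(n_events):
        clat = rng.uniform(grid.lats[0], grid.lats[-1])
        clon = rng.uniform(grid.lons[0], grid.lons[-1])
        t0 = rng.integers(0, nt)
        duration = 1 + rng.poisson(cfg.plume_mean_duration_days - 1)
        sigma = rng.uniform(*cfg.plume_sigma_deg)
        peak = rng.lognormal(np.log(cfg.plume_peak_ugm3), 0.5)
        footprint = peak * np.exp(-((la - clat) ** 2 + (lo - clon) ** 2) / (2 * sigma ** 2))
        t1 = min(t0 + duration, nt)
        tau = max(duration / 2.0, 1.0)
        profile = np.exp(-np.arange(t1 - t0) / tau)
        if rng.uniform() < cfg.o3_negative_fraction:
            o3_scale = -np.abs(rng.normal(0.25, 0.10))
        else:
            o3_scale = np.abs(rng.normal(0.60, 0.20))
        fire_pm[t0:t1] += profile[:, None, None] * footprint
        fire_o3[t0:t1] += o3_scale * profile[:, None, None] * footprint
    return fire_pm, fire_o3


def _truth_exposure_records(cfg: WorldConfig, truth_total, truth_fire,
                            population) -> pd.DataFrame:
    """Independent (per-cell loop) SFAP bookkeeping on the truth fields.

    Serves as the generator's known answer for the exposure module: for
    each calendar year it walks every cell, flags SFAP days from the truth
    fields and the configured thresholds, and accumulates integer
    person-days, the PM-only/O3-only/both split, and the exposed
    population.
    """
    dates = cfg.dates
    years = sorted(set(dates.year))
    pm_t = truth_total["pm25"].values
    pm_f = truth_fire["pm25"].values
    o3_t = truth_total["o3"].values
    o3_f = truth_fire["o3"].values
    pop_by_year = {p.year: p for p in population}
    rows = []
    for year in years:
        sel = np.where(dates.year == year)[0]
        pop = pop_by_year[year]
        pd_total = pd_pm = pd_o3 = pd_both = 0.0
        exposed = 0.0
        for i in range(cfg.nlat):
            for j in range(cfg.nlon):
                n = pop.counts[i, j]
                pm_hit = (pm_t[sel, i, j] > cfg.sfap_pm_threshold) & \
                    (pm_f[sel, i, j] >= cfg.sfap_fire_share * pm_t[sel, i, j])
                o3_hit = (o3_t[sel, i, j] > cfg.sfap_o3_threshold) & \
                    (o3_f[sel, i, j] >= cfg.sfap_fire_share * o3_t[sel, i, j])
                any_hit = pm_hit | o3_hit
                k = int(any_hit.sum())
                pd_total += n * k
                pd_pm += n * int((pm_hit & ~o3_hit).sum())
                pd_o3 += n * int((o3_hit & ~pm_hit).sum())
                pd_both += n * int((pm_hit & o3_hit).sum())
                if k > 0:
                    exposed += n
        total_pop = pop.total
        rows.append({"year": year, "person_days": pd_total,
                     "person_days_pm_only": pd_pm, "person_days_o3_only": pd_o3,
                     "person_days_both": pd_both, "people_exposed": exposed,
                     "days_per_person": pd_total / total_pop if total_pop else np.nan,
                     "total_population": total_pop})
    return pd.DataFrame(rows)


def _place_stations(rng, cfg: WorldConfig, n: int) -> np.ndarray:
    """Clustered station coordinates (lon, lat), mimicking the uneven density
    of real monitoring networks."""
    grid = cfg.fine_grid
    lat_lo, lat_hi = grid.lats[0], grid.lats[-1]
    lon_lo, lon_hi = grid.lons[0], grid.lons[-1]
    centers = np.column_stack([rng.uniform(lon_lo, lon_hi, cfg.n_station_clusters),
                               rng.uniform(lat_lo, lat_hi, cfg.n_station_clusters)])
    weights = rng.dirichlet(np.full(cfg.n_station_clusters, 0.7))
    coords = np.empty((n, 2))
    for s in range(n):
        if rng.uniform() < 0.15:     # sparse background network
            coords[s] = (rng.uniform(lon_lo, lon_hi), rng.uniform(lat_lo, lat_hi))
            continue
        c = rng.choice(cfg.n_station_clusters, p=weights)
        while True:
            pt = centers[c] + rng.normal(0, cfg.station_cluster_sd_deg, 2)
            if lon_lo <= pt[0] <= lon_hi and lat_lo <= pt[1] <= lat_hi:
                coords[s] = pt
                break
    return coords


def make_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate the full synthetic world for a configuration (seeded)."""
    cfg = config or WorldConfig()
    rngs = _streams(cfg.seed)
    grid = cfg.fine_grid
    coarse = cfg.coarse_grid
    dates = cfg.dates
    nt = cfg.n_days

    # --- covariates and non-fire baseline -------------------------------
    cov_arrays = _make_covariates(rngs["covariates"], grid, dates)
    rngb = rngs["baseline"]
    doy = dates.dayofyear.to_numpy()[:, None, None]

    base_pm = 8.0 + 9.0 * (_smooth_field(rngb, grid) * 0.5 + 0.5)
    season_pm = _seasonal(doy, rngb.uniform(0, 2 * np.pi), 0.35)
    micro_pm = np.exp(rngb.normal(0, 0.05, size=(nt,) + grid.shape))
    nonfire_pm = base_pm * season_pm * _met_modulation(cov_arrays, "pm25") * micro_pm

    base_o3 = 55.0 + 30.0 * (_smooth_field(rngb, grid) * 0.5 + 0.5)
    season_o3 = _seasonal(doy, rngb.uniform(0, 2 * np.pi), 0.25)
    micro_o3 = np.exp(rngb.normal(0, 0.04, size=(nt,) + grid.shape))
    nonfire_o3 = base_o3 * season_o3 * _met_modulation(cov_arrays, "o3") * micro_o3

    # --- fire plumes ----------------------------------------------------
    fire_pm, fire_o3 = _plant_plumes(rngs["plumes"], cfg)
    fire_o3 = np.maximum(fire_o3, -0.45 * nonfire_o3)  # keep |fire| <= total
    total_pm = nonfire_pm + fire_pm
    total_o3 = nonfire_o3 + fire_o3

    def _fine(name, arr):
        return DailyField(grid, dates, arr, name=name)

    truth_total = {"pm25": _fine("pm25_truth_total", total_pm),
                   "o3": _fine("o3_truth_total", total_o3)}
    truth_fire = {"pm25": _fine("pm25_truth_fire", fire_pm),
                  "o3": _fine("o3_truth_fire", fire_o3)}

    # --- coarse chemical-transport output -------------------------------
    bias = np.exp(cfg.bias_amplitude *
                  _smooth_field(rngs["bias"], coarse, order=cfg.bias_order))
    rngn = rngs["chem_noise"]
    chem_total, chem_fire = {}, {}
    for pol, tot, fire in (("pm25", total_pm, fire_pm), ("o3", total_o3, fire_o3)):
        bm_tot = block_reduce_mean(tot, cfg.block_lat, cfg.block_lon)
        bm_fire = block_reduce_mean(fire, cfg.block_lat, cfg.block_lon)
        c_tot = bm_tot * bias + rngn.normal(0, 1.0, bm_tot.shape) * cfg.chem_noise_sd
        c_tot = np.maximum(c_tot, 0.0)
        c_fire = bm_fire * bias * (1.0 + cfg.chem_fire_rel_noise
                                   * rngn.normal(0, 1.0, bm_fire.shape))
        if pol == "pm25":
            c_fire = np.clip(c_fire, 0.0, c_tot)
        else:
            c_fire = np.clip(c_fire, -c_tot, c_tot)
        chem_total[pol] = DailyField(coarse, dates, c_tot, name=f"{pol}_chem_total")
        chem_fire[pol] = DailyField(coarse, dates, c_fire, name=f"{pol}_chem_fire")

    # --- stations -------------------------------------------------------
    stations: dict[str, StationSeries] = {}
    station_noise: dict[str, pd.DataFrame] = {}
    spec = (("pm25", cfg.n_stations_pm, cfg.obs_noise_sd_pm, "PM"),
            ("o3", cfg.n_stations_o3, cfg.obs_noise_sd_o3, "O3"))
    rngsn = rngs["station_noise"]
    for pol, n_st, sd, prefix in spec:
        coords = _place_stations(rngs["stations"], cfg, n_st)
        truth = truth_total[pol].values
        recs, noise_recs = [], []
        for s in range(n_st):
            lon, lat = coords[s]
            i, j = locate_cell(grid, lon, lat)
            tser = truth[:, i, j]
            eps = rngsn.normal(0, sd, nt)
            obs = np.maximum(tser + eps, 0.0)
            sid = f"{prefix}{s:03d}"
            recs.append(pd.DataFrame({"station_id": sid, "lon": lon, "lat": lat,
                                      "date": dates, "value_ugm3": obs}))
            noise_recs.append(pd.DataFrame({"station_id": sid, "date": dates,
                                            "noise": obs - tser}))
        stations[pol] = StationSeries(pollutant=pol, table=pd.concat(recs, ignore_index=True))
        station_noise[pol] = pd.concat(noise_recs, ignore_index=True)

    # --- population and countries ---------------------------------------
    rngc = rngs["countries"]
    seeds_ij = np.column_stack([rngc.integers(0, cfg.nlat, cfg.n_countries),
                                rngc.integers(0, cfg.nlon, cfg.n_countries)])
    ii, jj = np.meshgrid(np.arange(cfg.nlat), np.arange(cfg.nlon), indexing="ij")
    d2 = (ii[..., None] - seeds_ij[:, 0]) ** 2 + (jj[..., None] - seeds_ij[:, 1]) ** 2
    country_id = d2.argmin(axis=-1).astype(int)
    ref_factors = rngc.uniform(*cfg.ref_factor_range, cfg.n_countries)

    rngp = rngs["population"]
    base_counts = np.round(rngp.lognormal(cfg.pop_log_mean, cfg.pop_log_sd,
                                          grid.shape))
    population = []
    for y_idx, year in enumerate(sorted(set(dates.year))):
        counts = np.round(base_counts * (1.0 + cfg.pop_growth_per_year) ** y_idx)
        refs = {}
        for c in range(cfg.n_countries):
            s = counts[country_id == c].sum()
            if s > 0:
                refs[c] = float(s * ref_factors[c])
        population.append(PopulationRaster(grid, int(year), counts,
                                           country_id, refs))

    world = SyntheticWorld(
        config=cfg,
        truth_total=truth_total, truth_fire=truth_fire,
        chem_total=chem_total, chem_fire=chem_fire,
        covariates={k: DailyField(grid, dates, v, name=k)
                    for k, v in cov_arrays.items()},
        stations=stations, station_noise=station_noise,
        population=population,
    )
    world.truth_exposure = _truth_exposure_records(cfg, truth_total, truth_fire,
                                                   population)
    return world


def station_truth(world: SyntheticWorld, station_id: str) -> pd.Series:
    """Per-date truth concentration at a station's grid cell."""
    for pol, st in world.stations.items():
        coords = st.coordinates()
        row = coords[coords["station_id"] == station_id]
        if not row.empty:
            lon, lat = float(row["lon"].iloc[0]), float(row["lat"].iloc[0])
            vals = world.truth_total[pol].sample(lon, lat)
            return pd.Series(vals, index=world.dates, name=station_id)
    raise KeyError(f"unknown station {station_id!r}")
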