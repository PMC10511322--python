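# Methods

This note documents the modelling assumptions, numerical choices and known
limitations behind `smokeatlas`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

All grids are regular lat/lon grids, cell-center registered, latitudes
ascending, longitudes normalized to [−180°, 180°). A point maps to the cell
with the nearest center; a point exactly on a shared cell edge maps to the
lower index, so station–grid joins are deterministic. Missing data are NaN
throughout; every aggregation states its completeness rule. Concentrations
are µg m⁻³ everywhere. Gridded fields round-trip through CF-style NetCDF
(time/lat/lon, `units` attributes); files with descending latitudes are
reordered on read.

## Unit conversion and meteorological covariates

* **Ozone ppb → µg m⁻³** uses the ideal gas law with MW = 48.00 g mol⁻¹,
  T = 298.65 K (25.5 °C) and P = 101.325 kPa, giving 1.9587 ≈ 1.96 µg m⁻³
  per ppb — the conventional factor for WHO-guideline work.
* **Local day.** Each cell's time zone is approximated as UTC +
  round(lon/15°) hours. This is reproducible without a timezone database and
  is at most ~30 minutes off solar time; real civil time zones can deviate
  further, which matters only marginally for daily aggregates.
* **Daily aggregation** of hourly data requires ≥ 18 of 24 local hours
  (75%), else the cell-day is NaN. T_mean/T_min/T_max are the mean/min/max of
  the 24 hourly 2 m temperatures, TV their *sample* standard deviation
  (ddof = 1); wind components, pressure and UV are daily means, precipitation
  a daily total.
* **Relative humidity** uses the Magnus–Tetens form with constants 17.625 and
  243.04 °C, RH = 100·e(T_dew)/e(T_mean), clipped to (0, 100]; dew point
  above air temperature is treated as saturation with a warning.
* **MDA8 ozone** is the maximum of the 24 running 8-hour means starting at
  each local hour, borrowing up to 7 hours from the next day. A window is
  computable with ≥ 6 of its 8 hours; the day needs ≥ 18 computable windows.
  These completeness thresholds follow common regulatory practice (they are
  choices of this package, configurable in code).

## Downscaling

Inverse-distance weighting with power 2 over the k = 4 nearest *non-missing*
coarse centers, with great-circle (haversine, R = 6371 km) distances so that
zonal neighbor weighting is correct at high latitude — IDW in raw degree
space would overweight east–west neighbors toward the poles. A fine center
within 10⁻⁶ degrees of a coarse center copies that value exactly. The
interpolator is exact on constants, bounded by the contributing neighbors'
extremes, and monotone in each source value. Missing coarse values are
skipped, never zero-filled; a date with no finite coarse value yields NaN.

## Calibration model

A random forest on 17 predictors (downscaled all-source concentration, ten
meteorological covariates, Year, Month, day-of-week 1–7 Monday-first,
day-of-year 1–366, longitude, latitude), one model per pollutant with its
own seed. Library defaults are 500 trees, minimum leaf 5, and `max_features`
tuned over {3, 5, 7, 9} by tenfold-CV RMSE; all are configurable, and
replicate studies pin smaller values (below). Training rows use station
coordinates for Lon/Lat; full-grid prediction uses cell centers. Predictions
of a tree ensemble are convex combinations of training responses, hence
non-negative for non-negative targets and bounded by the training range —
the calibration cannot extrapolate beyond observed concentrations, a known
property (and limitation) of forest calibration during unprecedented
extremes.

Fire attribution multiplies the calibrated all-source field by the CTM fire
fraction. The fraction is defined as 0 where the CTM total is 0 (no
attributable signal), clipped into [−1, 1] with clip events counted.
Negative fire fractions are retained for ozone — fire emissions can suppress
ozone photochemistry, so with/without-fire CTM differences may be negative —
and the SFAP share rule below never counts them as qualifying. For PM₂.₅ the
generator and the attribution keep 0 ≤ fire ≤ total.

## Exposure metrics

SFAP day: all-source PM₂.₅ *strictly* above 15 µg m⁻³ with fire share
≥ 0.5, and/or all-source MDA8 O₃ strictly above 100 µg m⁻³ with fire share
≥ 0.5. "Exceeded" is read as strict and "at least 50%" as inclusive — the
literal reading; both thresholds and the comparison direction sit in config.
Cell-days with NaN in any needed field are not flagged and are counted as
missing. Metrics per region-year: person-days (Σ flag × cell population),
days per person (person-days / total population), people exposed (population
of cells with ≥ 1 flagged day — gridded data admit no finer rule), and
population-weighted mean concentrations. The PM-only/O₃-only/both categories
are mutually exclusive and partition total person-days exactly. Population
rasters are rescaled per country by reference_total / raster_sum, making
country sums match official totals exactly; the operation is idempotent.

## Synthetic world

The generator emulates the statistical structure the pipeline assumes, not
atmospheric physics:

* **Truth field** = smooth spatial baseline (low-order Fourier harmonics) ×
  seasonal cycle × a smooth nonlinear function of the meteorological
  covariates (with an interaction term, so a flexible regressor genuinely
  outperforms any linear correction) × small lognormal cell-day noise, plus
  episodic fire plumes: Gaussian spatial footprints (σ 0.4–1.2°, lognormal
  peak, median 45 µg m⁻³) with exponential temporal decay over ~6 days,
  ~30 events per year. Ozone plume effects scale the PM footprint by a
  per-plume factor that is negative in 15% of plumes.
* **Coarse CTM output** = block-mean of truth × exp(0.3 × smooth spatial
  field) multiplicative bias + additive noise (SD 1 µg m⁻³); the companion
  fire field shares the same bias with 10% relative noise, keeping the fire
  fraction consistent with the planted plumes (in [0, 1] for PM₂.₅).
* **Stations** (120 per pollutant by default) follow a clustered point
  process — cluster centers with Dirichlet-weighted occupancy plus a 15%
  uniform background — mimicking the density imbalance of real monitoring
  networks. Observations are truth at the station's cell plus Gaussian noise
  (SD 2 µg m⁻³ PM₂.₅, 4 µg m⁻³ O₃), floored at zero with the realized noise
  recorded so tests can verify obs = truth + noise exactly.
* **Population** is integer lognormal per cell (so person-days are integers),
  partitioned into contiguous countries by nearest seed cell, with reference
  totals = raster sums × country factors in [0.85, 1.3] (never 1), and 1.5%
  annual growth.
* **Bookkeeping.** The generator independently recomputes, with explicit
  per-cell loops, the SFAP person-days, category split and exposed population
  implied by its truth fields — the known answer against which the exposure
  module is checked for exact (integer) agreement.

All randomness flows from one seed through named substreams (baseline,
covariates, plumes, bias, chem noise, stations, station noise, population,
countries), so the whole world is bit-reproducible and components can be
varied independently. The default world is 40×60 cells at 0.25° (5×6 coarse
cells of 8×10 blocks), two years daily, 8 countries — small enough for the
full pipeline in minutes on one CPU.

What the generator does *not* emulate: transport and advection (plumes do not
drift), correlated multi-day synoptic weather, instrument drift or station
dropout, coastlines/ocean masks, or realistic population clustering along
rivers and coasts. Passing tests therefore demonstrate correctness and
statistical behavior of the pipeline machinery, not accuracy of any
real-world exposure estimate.

## Evaluation machinery

* CV schemes: random tenfold over rows; spatial tenfold over *stations*
  (fold sizes within one station of equal, a station never straddles folds);
  leave-one-cluster-out over seeded k-means clusters of station (lon, lat)
  with Euclidean distances and 10 restarts. Within-group sum of squares
  decreases monotonically in k, so a "minimum WSS" criterion cannot select
  k; when a k-range is given the elbow rule (maximum second difference of
  WSS) picks it, and k can always be pinned.
* Pooled out-of-fold R² is 1 − SSE/SST against the overall mean; every row
  is predicted exactly once by a model that never saw its fold.
* Within-R² absorbs two fixed-effect groupings (station and year, or coarse
  block and date) by iterated demeaning to 10⁻¹⁰, then regresses demeaned
  observations on demeaned estimates through the origin. This equals the
  dummy-variable OLS partial R² (verified against statsmodels to 10⁻⁸) and
  measures explained *local temporal* variation. An estimate absorbed by the
  fixed effects returns NaN with a warning.
* Per-station R² is computed against each station's own mean, reported as
  the median and 10th percentile; stations with < 30 out-of-fold rows
  (configurable) are excluded and counted.
* Smoke PM₂.₅ observation operator: background = station- and month-specific
  median of non-smoke-day observations over the 3-year window (y−1, y, y+1);
  smoke PM₂.₅ = max(obs − background, 0) on smoke days and 0 on non-smoke
  days. The zero floor is a choice (negative smoke PM is physically
  meaningless); the operator is exactly translation-equivariant.
* Wildfire-event validation selects the station within a radius (default
  100 km, config) maximizing mean(event window) − mean(pre window), ties to
  the smaller station id.

## Trend statistics

Plain OLS of annual values on calendar year with the two-sided slope t-test;
no autocorrelation correction. Slopes are reported per year and per decade
(×10). At least 3 years are required for a fit. Per-cell annual values are
calendar-year means of the daily field requiring ≥ 75% of days, else NaN.
The vectorized raster implementation is checked cell-by-cell against the
scalar fit; exact-fit cells (zero residual variance) report p = 0.

## Replicate-study problem sizes

The standing studies in `smokeatlas.studies` (run by the test suite and the
acceptance script) use the default 40×60 × 2-year world with 120 stations,
and score 20 seeded replicates. Within these studies the forest is pinned to
40 trees, `max_features` 5, minimum leaf 5, and each CV training fold is
subsampled to at most 6,000 rows (seeded). These sizes were chosen so one
replicate completes in well under a minute; the calibrated-versus-raw
ordering that the studies measure is insensitive to forest size because the
gap between the biased coarse field and the calibrated field is much larger
than the forest's own variance. Trend calibration uses 200 replicate 20-year
series (95% CI coverage) and a 1,000-cell null world (type-I error at
p < 0.05).

## Pipeline and reproducibility

One YAML config drives the run; unknown keys are rejected. The global seed
fans out to per-stage substreams, and every artifact is listed in a manifest
with its SHA-256 hash — rerunning with the same config and seed reproduces
identical hashes (NetCDF3-classic output contains no timestamps). SFAP
thresholds default to 15 / 100 / 0.5 when the config omits them, with a log
note.

## Known limitations

* The forest cannot predict above the maximum observed training
  concentration, so extreme plume peaks are understated.
* The attribution inherits the CTM's fire/total split unchanged;
  calibration corrects levels, not source apportionment.
* `people_exposed` counts whole-cell populations; sub-cell heterogeneity is
  invisible at 0.25°.
* The timezone approximation ignores civil time-zone boundaries and daylight
  saving.
* Station QC/cleaning of raw observational feeds is out of scope; the
  package assumes clean station tables.
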