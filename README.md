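# smokeatlas

Population exposure assessment for landscape-fire air pollution.

Landscape fires — wildfires, prescribed burns, agricultural burning — emit
fine particulate matter (PM₂.₅) and ozone precursors whose smoke can travel
hundreds of kilometres, so most of the health burden falls on people far from
any flame and often far from any air-quality monitor. `smokeatlas` implements
the estimation pipeline used to map that exposure globally at daily,
0.25°×0.25° resolution, and a seeded synthetic-world generator so every stage
can be exercised and validated without downloading a single external dataset.
It is written for exposure scientists and environmental epidemiologists who
need fire-sourced concentration surfaces and population exposure metrics, or
who want to test methodological variants of this class of pipeline.

## The method

Starting from paired chemical-transport model (CTM) simulations run with and
without fire emissions on a coarse (2.0°×2.5°) grid, plus station
observations and gridded meteorology:

1. **Downscaling.** Coarse daily fields are interpolated to the 0.25° grid by
   inverse-distance weighting over the k nearest coarse cell centers
   (great-circle distances, w ∝ d⁻ᵖ, defaults p = 2, k = 4).
2. **Calibration.** A random forest is trained to predict station-observed
   all-source concentrations from 17 predictors — the downscaled CTM field,
   ten meteorological covariates (T_mean, T_max, T_min, TV, RH, wind
   components, precipitation, pressure, UV), four calendar terms (year,
   month, day-of-week, day-of-year) and longitude/latitude:

   `obs = f(chem_total, T_mean, …, UV, Year, Month, DOW, DOY, Lon, Lat)`

   Separate models are fitted for daily-mean PM₂.₅ and daily-max-8h O₃.
3. **Attribution.** The calibrated all-source field is scaled by the CTM's
   fire fraction, `est_fire = est_total × (chem_fire / chem_total)`, so the
   source split comes from the CTM while the level comes from observations.
4. **Exposure.** A cell-day is a *substantial fire-sourced air pollution*
   (SFAP) day if all-source PM₂.₅ > 15 µg m⁻³ with fire share ≥ 50%, and/or
   all-source MDA8 O₃ > 100 µg m⁻³ with fire share ≥ 50% (WHO 2021 daily
   guidelines). Combining SFAP flags with UN-adjusted gridded population
   yields person-days, days per person, people exposed, and
   population-weighted mean concentrations, decomposed into PM-only /
   O₃-only / both categories.
5. **Validation & trends.** Random tenfold CV, spatial (station) tenfold CV
   and leave-one-cluster-out CV over k-means station clusters; panel
   fixed-effects within-R²; per-station R² summaries; a background-median
   smoke-PM₂.₅ observation operator; OLS trend tests on annual series and
   per-cell annual rasters.

## Worked example

Two grid cells with populations 100 and 50. On day 1 only cell 1 qualifies as
an SFAP day (PM₂.₅ = 20 µg m⁻³, fire share 75%); on day 2 both qualify:

```python
import numpy as np, pandas as pd
from smokeatlas import (DailyField, GridSpec, PopulationRaster, flag_sfap,
                        person_days, people_exposed, days_per_person)

grid = GridSpec(lat0=0.0, lon0=0.0, dlat=1.0, dlon=1.0, nlat=1, nlon=2)
dates = pd.date_range("2018-01-01", periods=2)
pm_total = DailyField(grid, dates, [[[20.0, 10.0]], [[30.0, 25.0]]])
pm_fire  = DailyField(grid, dates, [[[15.0,  1.0]], [[20.0, 20.0]]])
o3_total = DailyField(grid, dates, np.zeros((2, 1, 2)))
o3_fire  = DailyField(grid, dates, np.zeros((2, 1, 2)))
pop = PopulationRaster(grid, 2018, np.array([[100.0, 50.0]]),
                       np.zeros((1, 2), int), {0: 150.0})

flags = flag_sfap(pm_total, pm_fire, o3_total, o3_fire)
pd_total = person_days(flags, pop)
print("person-days:     ", pd_total)
print("people exposed:  ", people_exposed(flags, pop))
print("days per person: ", round(days_per_person(pd_total, pop), 3))
```

```
person-days:      250.0
people exposed:   150.0
days per person:  1.667
```

Day 1 contributes cell 1's 100 residents, day 2 contributes both cells'
150, giving 250 person-days; all 150 residents saw at least one SFAP day,
an average of 1.667 days each. Fitting a trend to an annual series uses the same
Model/Results idiom as the calibration stage:

```python
years = np.arange(2000, 2020)
print(fit_trend(pd.Series(2.0 + 0.011 * (years - 2000), index=years)).summary())
```

```
Linear trend (OLS on year)
========================================
years:            20
slope per year:   0.011
slope per decade: 0.11
95% CI (per yr):  [0.011, 0.011]
p-value:          2.436e-142  (significant at 0.05)
```

A full synthetic run — world generation through trend rasters, with a hashed
artifact manifest — is one command:

```sh
smokeatlas simulate --seed 7 --tiny --out world/
smokeatlas run --config config.yaml --out out/
```

## Layout

- `smokeatlas.grids`, `smokeatlas.fields` — grid conventions, field/station/
  population containers, NetCDF/CSV I/O
- `smokeatlas.met` — unit conversion, MDA8 ozone, local-day covariates
- `smokeatlas.synth` — the seeded synthetic world generator
- `smokeatlas.downscale`, `smokeatlas.calibrate` — IDW and the calibration
  Model/Results pair, fire-fraction attribution
- `smokeatlas.exposure`, `smokeatlas.evaluate`, `smokeatlas.trends` — SFAP
  metrics, CV machinery, trend fitting
- `smokeatlas.pipeline`, `smokeatlas.cli` — orchestration and the
  `smokeatlas` command

See `docs/methods.md` for the modelling assumptions and numerical choices.
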