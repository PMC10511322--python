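"""Reference experiments on the synthetic world.

These are the package's standing reproducibility studies: seeded,
self-contained experiments that quantify the calibration gain over the raw
downscaled fields, the exact recovery of the generator's exposure
bookkeeping, and the statistical calibration of the trend tests.  They are
run both by the test suite and by the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as ev
from .calibrate import RfHyperParams, assemble_training
from .downscale import idw_downscale
from .exposure import (SfapThresholds, days_per_person, flag_sfap,
                       people_exposed, person_days)
from .synth import WorldConfig, make_world
from .trends import fit_trend, grid_trends

log = logging.getLogger(__name__)

#: forest settings for replicate studies: a deliberately small forest and a
#: per-fold training subsample keep one replicate under half a minute while
#: leaving the calibrated-vs-raw ordering unchanged.
STUDY_HYPERPARAMS = RfHyperParams(n_estimators=40, max_features=5,
                                  min_samples_leaf=5)
STUDY_MAX_TRAIN_ROWS = 6000


def _derive_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


@dataclass
class GainReplicate:
    seed: int
    r2_raw: float
    r2_spatial_cv: float
    r2_cluster_cv: float
    within_r2_spatial_cv: float


def calibration_gain_study(n_replicates: int = 20, base_seed: int = 0,
                           pollutant: str = "pm25",
                           config: WorldConfig | None = None) -> pd.DataFrame:
    """Spatial-CV performance of the calibration vs the raw downscaled field.

    For each seeded replicate world: downscale the coarse all-source field,
    assemble the station training table, and score (a) the raw downscaled
    field against held-out observations, (b) the random forest under
    spatial (station) tenfold CV and (c) under leave-one-cluster-out CV
    with 10 k-means station clusters.  Returns one row per replicate.
    """
    rows = []
    for r in range(n_replicates):
        seed = _derive_seed(base_seed, r)
        cfg = config or WorldConfig(seed=seed)
        if config is not None:
            cfg = WorldConfig(**{**cfg.__dict__, "seed": seed})
        world = make_world(cfg)
        fine = world.fine_grid
        ds = idw_downscale(world.chem_total[pollutant], fine)
        table = assemble_training(world.stations[pollutant], ds, world.covariates)
        obs = table["obs"].to_numpy(float)
        raw = table["chem_total"].to_numpy(float)
        r2_raw = float(1 - np.sum((obs - raw) ** 2)
                       / np.sum((obs - obs.mean()) ** 2))
        fit_fn = ev.rf_fit_fn(STUDY_HYPERPARAMS, seed=seed,
                              max_train_rows=STUDY_MAX_TRAIN_ROWS,
                              pollutant=pollutant)
        part = ev.make_partition(table, "station_tenfold", k=10, seed=seed)
        cv = ev.cross_validate(table, part, fit_fn)
        clusters = ev.kmeans_station_clusters(world.stations[pollutant], 10,
                                              seed=seed)
        cl = ev.cluster_loocv(table, clusters, fit_fn)
        n_years = len(set(world.dates.year))
        rows.append(GainReplicate(
            seed=seed, r2_raw=r2_raw, r2_spatial_cv=cv.pooled_r2,
            r2_cluster_cv=cl.pooled_r2,
            within_r2_spatial_cv=cv.within_r2() if n_years >= 2 else np.nan,
        ).__dict__)
        log.info("gain replicate %d/%d: raw %.3f cv %.3f cluster %.3f",
                 r + 1, n_replicates, r2_raw, cv.pooled_r2, cl.pooled_r2)
    return pd.DataFrame(rows)


def exposure_recovery_study(seed: int = 0,
                            config: WorldConfig | None = None) -> pd.DataFrame:
    """Exposure metrics on truth fields vs the generator's own bookkeeping.

    Applies the exposure module to the world's truth fields and the raw
    integer population raster, and reports both paths side by side; with a
    correct implementation the integer person-day columns agree exactly.
    """
    cfg = config or WorldConfig(seed=seed)
    world = make_world(cfg)
    th = SfapThresholds(cfg.sfap_pm_threshold, cfg.sfap_o3_threshold,
                        cfg.sfap_fire_share)
    flags = flag_sfap(world.truth_total["pm25"], world.truth_fire["pm25"],
                      world.truth_total["o3"], world.truth_fire["o3"], th)
    rows = []
    for pop in world.population:
        yflags = flags.year_slice(pop.year)
        pdays = person_days(yflags, pop)
        rec = world.truth_exposure.set_index("year").loc[pop.year]
        rows.append({
            "year": pop.year,
            "person_days": pdays,
            "person_days_recorded": rec["person_days"],
            "person_days_pm_only": person_days(yflags, pop, "pm_only"),
            "person_days_pm_only_recorded": rec["person_days_pm_only"],
            "person_days_o3_only": person_days(yflags, pop, "o3_only"),
            "person_days_o3_only_recorded": rec["person_days_o3_only"],
            "person_days_both": person_days(yflags, pop, "both"),
            "person_days_both_recorded": rec["person_days_both"],
            "people_exposed": people_exposed(yflags, pop),
            "people_exposed_recorded": rec["people_exposed"],
            "days_per_person": days_per_person(pdays, pop),
            "days_per_person_recorded": rec["days_per_person"],
        })
    return pd.DataFrame(rows)


def trend_recovery_study(n_replicates: int = 200, base_seed: int = 0,
                         n_years: int = 20, slope_per_decade: float = 0.5,
                         noise_sd: float = 0.3) -> pd.DataFrame:
    """Coverage of the 95% CI for a planted trend in annual series.

    Each replicate draws a 20-year annual exposure-metric series with a
    known per-decade slope plus Gaussian year-to-year noise and fits the
    OLS trend; reports whether the planted slope falls in the 95% CI.
    """
    slope = slope_per_decade / 10.0
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(_derive_seed(base_seed, 1000 + r))
        years = np.arange(2000, 2000 + n_years)
        y = 2.0 + slope * (years - years[0]) + rng.normal(0, noise_sd, n_years)
        tf = fit_trend(pd.Series(y, index=years))
        lo, hi = tf.conf_int()
        rows.append({"replicate": r, "slope_per_decade": tf.slope_per_decade,
                     "covered": bool(lo <= slope <= hi), "p_value": tf.p_value})
    return pd.DataFrame(rows)


def null_trend_study(n_cells: int = 1000, n_years: int = 20,
                     seed: int = 0) -> dict:
    """Type-I error of the per-cell trend test under a no-trend null world."""
    rng = np.random.default_rng(_derive_seed(seed, 9999))
    years = np.arange(2000, 2000 + n_years)
    annual = rng.normal(5.0, 1.0, size=(n_years, n_cells, 1))
    slope, p = grid_trends(years, annual)
    frac = float(np.mean(p < 0.05))
    se = float(np.sqrt(0.05 * 0.95 / n_cells))
    return {"fraction_significant": frac, "nominal": 0.05, "se": se,
            "n_cells": n_cells}
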