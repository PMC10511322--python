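"""End-to-end pipeline: one config, seeded stages, hashed artifacts.

Stage order mirrors the estimation procedure: downscale the coarse
chemical-transport fields, calibrate against stations, scale by the fire
fraction, then map exposure, evaluate and fit trends.  Every artifact is
listed in a manifest with its SHA-256 content hash, so a rerun with the
same config and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate, evaluate, exposure, synth, trends
from .downscale import IdwParams, idw_downscale
from .fields import write_field, write_stations

log = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "out_dir", "synthetic", "downscale", "calibrate",
               "sfap", "evaluate", "trends"}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "smokeatlas_out")
    if "synthetic" not in cfg:
        raise ConfigError("config needs a 'synthetic' world block")
    for section, cls in (("downscale", IdwParams),):
        block = cfg.get(section, {})
        bad = set(block) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ConfigError(f"unknown {section} keys: {sorted(bad)}")
    sfap = cfg.get("sfap", {})
    bad = set(sfap) - {"pm_guideline", "o3_guideline", "fire_share"}
    if bad:
        raise ConfigError(f"unknown sfap keys: {sorted(bad)}")
    if not sfap:
        log.info("sfap thresholds not configured; using defaults 15 / 100 / 0.5")
    return cfg


def _stage_seed(seed: int, name: str) -> int:
    h = np.random.SeedSequence([seed, int.from_bytes(name.encode(), "little") % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hyperparams(cfg: dict) -> calibrate.RfHyperParams:
    block = dict(cfg.get("calibrate", {}))
    block.pop("seed", None)
    known = {f.name for f in dataclasses.fields(calibrate.RfHyperParams)}
    bad = set(block) - known
    if bad:
        raise ConfigError(f"unknown calibrate keys: {sorted(bad)}")
    mf = block.get("max_features")
    if isinstance(mf, list):
        block["max_features"] = tuple(mf)
    return calibrate.RfHyperParams(**block)


def run(cfg: dict, out_dir=None) -> dict:
    """Execute the full pipeline; returns the artifact manifest."""
    cfg = validate_config(dict(cfg))
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_field(fld, name):
        p = out / name
        write_field(fld, p)
        artifacts[name] = _sha256(p)

    # --- stage: simulate ------------------------------------------------
    wc = synth.WorldConfig(seed=seed, **cfg["synthetic"])
    world = synth.make_world(wc)
    log.info("simulate: %dx%d fine cells, %d days, seed %d",
             wc.nlat, wc.nlon, wc.n_days, seed)
    for pol in ("pm25", "o3"):
        save_field(world.chem_total[pol], f"chem_total_{pol}.nc")
        save_field(world.chem_fire[pol], f"chem_fire_{pol}.nc")
        p = out / f"stations_{pol}.csv"
        write_stations(world.stations[pol], p)
        artifacts[p.name] = _sha256(p)

    # --- stage: downscale -----------------------------------------------
    idw = IdwParams(**cfg.get("downscale", {}))
    fine = world.fine_grid
    chem_fine = {}
    for pol in ("pm25", "o3"):
        chem_fine[pol] = {
            "total": idw_downscale(world.chem_total[pol], fine, idw),
            "fire": idw_downscale(world.chem_fire[pol], fine, idw),
        }
        save_field(chem_fine[pol]["total"], f"chem_total_{pol}_fine.nc")

    # --- stage: calibrate -----------------------------------------------
    hp = _hyperparams(cfg)
    est_total, est_fire, tables, results = {}, {}, {}, {}
    for pol in ("pm25", "o3"):
        tables[pol] = calibrate.assemble_training(
            world.stations[pol], chem_fine[pol]["total"], world.covariates)
        model = calibrate.CalibrationModel(tables[pol], hp, pollutant=pol)
        res = model.fit(seed=_stage_seed(seed, f"calibrate_{pol}"))
        results[pol] = res
        est_total[pol] = res.predict_field(chem_fine[pol]["total"], world.covariates)
        save_field(est_total[pol], f"est_total_{pol}.nc")

        # --- stage: attribute ---------------------------------------
        frac = calibrate.fire_fraction(chem_fine[pol]["fire"],
                                       chem_fine[pol]["total"])
        est_fire[pol] = calibrate.scale_fire(est_total[pol], frac)
        save_field(est_fire[pol], f"est_fire_{pol}.nc")

    # --- stage: exposure --------------------------------------------
    th = exposure.SfapThresholds(**cfg.get("sfap", {}))
    flags = exposure.flag_sfap(est_total["pm25"], est_fire["pm25"],
                               est_total["o3"], est_fire["o3"], th)
    summaries = []
    for pop in world.population:
        pop_adj = exposure.adjust_to_reference(pop)
        yflags = flags.year_slice(pop.year)
        sel = world.dates.year == pop.year
        pm_y = est_fire["pm25"].copy_with(
            dates=world.dates[sel], values=est_fire["pm25"].values[sel])
        o3_y = est_fire["o3"].copy_with(
            dates=world.dates[sel], values=est_fire["o3"].values[sel])
        summaries.append(exposure.summarize_exposure(
            yflags, pop_adj, pm_y, o3_y, region="world"))
    exp_table = exposure.exposure_table(summaries)
    p = out / "exposure_summary.csv"
    exp_table.to_csv(p, index=False)
    artifacts[p.name] = _sha256(p)

    # --- stage: evaluate --------------------------------------------
    ev = cfg.get("evaluate", {})
    scheme = ev.get("scheme", "station_tenfold")
    k = ev.get("k", 10)
    cv_rows = []
    for pol in ("pm25", "o3"):
        part = evaluate.make_partition(tables[pol], scheme, k=k,
                                       seed=_stage_seed(seed, f"cv_{pol}"))
        fit_fn = evaluate.rf_fit_fn(hp, seed=_stage_seed(seed, f"cvfit_{pol}"),
                                    pollutant=pol)
        res = evaluate.cross_validate(tables[pol], part, fit_fn)
        # year fixed effects need at least two calendar years
        wr2 = (res.within_r2() if len(set(world.dates.year)) >= 2 else float("nan"))
        cv_rows.append({"pollutant": pol, "scheme": scheme,
                        "pooled_r2": res.pooled_r2, "rmse": res.rmse,
                        "within_r2": wr2})
    p = out / "cv_report.csv"
    pd.DataFrame(cv_rows).to_csv(p, index=False)
    artifacts[p.name] = _sha256(p)

    # --- stage: trends ----------------------------------------------
    if len(set(world.dates.year)) >= trends.MIN_YEARS:
        for pol in ("pm25", "o3"):
            slope, pval = trends.field_trends(est_fire[pol])
            tf = est_fire[pol].copy_with(
                dates=pd.DatetimeIndex([world.dates[0]]),
                values=slope[None], name=f"{pol}_fire_trend")
            save_field(tf, f"trend_slope_{pol}.nc")
    else:
        log.info("trends: fewer than %d years; stage skipped", trends.MIN_YEARS)

    manifest = {"seed": seed, "config": cfg, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_example_config(path) -> None:
    cfg = {
        "seed": 0,
        "out_dir": "smokeatlas_out",
        "synthetic": {"nlat": 8, "nlon": 8, "block_lat": 4, "block_lon": 4,
                      "n_days": 30, "n_stations_pm": 10, "n_stations_o3": 10,
                      "n_station_clusters": 2, "n_countries": 2},
        "downscale": {"power": 2.0, "k": 4},
        "calibrate": {"n_estimators": 100, "max_features": 5,
                      "min_samples_leaf": 5},
        "sfap": {"pm_guideline": 15.0, "o3_guideline": 100.0, "fire_share": 0.5},
        "evaluate": {"scheme": "station_tenfold", "k": 5},
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
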