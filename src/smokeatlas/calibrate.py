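"""Station calibration of downscaled fields and fire-source attribution.

The calibration model is a random forest regressed on the downscaled
all-source concentration, ten meteorological covariates, four calendar
terms and the coordinates — 17 predictors in all:

    obs = f(chem_total, Tmean, Tmax, Tmin, TV, RH, Wind_u, Wind_v,
            Precip, Pressure, UV, Year, Month, DOW, DOY, Lon, Lat)

Fire-sourced concentrations are then the calibrated all-source field
scaled by the chemical-transport model's fire fraction:

    est_fire = est_total * (chem_fire / chem_total)

so the attribution inherits the CTM's source split but the absolute level
comes from the station-calibrated field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .fields import DailyField, StationSeries
from .grids import GridSpec, OutOfDomainError, locate_cell

log = logging.getLogger(__name__)

#: Ordered predictor list of the calibration model (17 features).
PREDICTORS = ("chem_total", "Tmean", "Tmax", "Tmin", "TV", "RH", "Wind_u",
              "Wind_v", "Precip", "Pressure", "UV", "Year", "Month", "DOW",
              "DOY", "Lon", "Lat")

COVARIATE_PREDICTORS = PREDICTORS[1:11]


def _calendar_frame(dates: pd.DatetimeIndex) -> pd.DataFrame:
    return pd.DataFrame({
        "Year": dates.year.astype(float),
        "Month": dates.month.astype(float),
        "DOW": dates.dayofweek.to_numpy() + 1.0,   # Monday=1 .. Sunday=7
        "DOY": dates.dayofyear.astype(float),
    }, index=dates)


def assemble_training(stations: StationSeries, chem_total_fine: DailyField,
                      covariates: dict[str, DailyField]) -> pd.DataFrame:
    """Station-day training table: response plus the 17 predictors.

    Each station is linked to its grid cell by coordinates; predictors are
    sampled at that cell, calendar terms derived from the date, and Lon/Lat
    taken as the station coordinates.  Rows with a missing response or any
    missing predictor are dropped; stations outside the grid are excluded
    with a warning.
    """
    for name in COVARIATE_PREDICTORS:
        if name not in covariates:
            raise ValueError(f"missing covariate field {name!r}")
        if not covariates[name].aligned_with(chem_total_fine):
            raise ValueError(f"covariate {name!r} not aligned with chem field")
    grid = chem_total_fine.grid
    dates = chem_total_fine.dates
    cal = _calendar_frame(dates)

    pieces = []
    for _, st in stations.coordinates().iterrows():
        try:
            i, j = locate_cell(grid, st["lon"], st["lat"])
        except OutOfDomainError:
            log.warning("station %s outside grid; excluded", st["station_id"])
            continue
        obs = stations.table[stations.table["station_id"] == st["station_id"]]
        obs = obs.set_index("date")["value_ugm3"].reindex(dates)
        block = pd.DataFrame({
            "station_id": st["station_id"],
            "obs": obs.to_numpy(),
            "chem_total": chem_total_fine.values[:, i, j],
        }, index=dates)
        for name in COVARIATE_PREDICTORS:
            block[name] = covariates[name].values[:, i, j]
        block = pd.concat([block, cal], axis=1)
        block["Lon"] = st["lon"]
        block["Lat"] = st["lat"]
        pieces.append(block.rename_axis("date").reset_index())
    if not pieces:
        raise ValueError("no station falls inside the grid")
    table = pd.concat(pieces, ignore_index=True)
    table = table.dropna(subset=["obs", *PREDICTORS]).reset_index(drop=True)
    return table[["station_id", "date", "obs", *PREDICTORS]]


@dataclass(frozen=True)
class RfHyperParams:
    """Random-forest settings; ``max_features`` may be a grid to tune by
    tenfold-CV RMSE."""

    n_estimators: int = 500
    max_features: int | tuple = (3, 5, 7, 9)
    min_samples_leaf: int = 5
    cv_folds: int = 10


class CalibrationModel:
    """Random-forest calibration of all-source concentrations.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`assemble_training` (needs ``obs`` and the 17
        predictor columns).
    hyperparams : RfHyperParams, optional
    pollutant : str
        Label carried into results ("pm25" or "o3").
    """

    def __init__(self, table: pd.DataFrame, hyperparams: RfHyperParams | None = None,
                 pollutant: str = "pm25"):
        missing = set(("obs",) + PREDICTORS) - set(table.columns)
        if missing:
            raise ValueError(f"training table missing columns {sorted(missing)}")
        if len(table) < 50:
            raise ValueError("at least 50 training rows required")
        if (table["obs"] < 0).any():
            raise ValueError("response must be non-negative")
        self.table = table.reset_index(drop=True)
        self.hyperparams = hyperparams or RfHyperParams()
        self.pollutant = pollutant

    def _make_rf(self, max_features: int, seed: int) -> RandomForestRegressor:
        hp = self.hyperparams
        return RandomForestRegressor(
            n_estimators=hp.n_estimators,
            max_features=min(max_features, len(PREDICTORS)),
            min_samples_leaf=hp.min_samples_leaf,
            random_state=seed, n_jobs=1)

    def fit(self, seed: int = 0) -> "CalibrationResults":
        """Fit the forest; tune ``max_features`` by tenfold-CV RMSE if a grid
        was given.  Refitting with the same seed reproduces identical
        predictions."""
        X = self.table[list(PREDICTORS)].to_numpy(float)
        y = self.table["obs"].to_numpy(float)
        if np.ptp(y) == 0:
            warnings.warn("constant response; calibration fit is degenerate",
                          stacklevel=2)
        hp = self.hyperparams
        cv_rmse = None
        if np.iterable(hp.max_features):
            grid = list(hp.max_features)
            cv_rmse = {}
            kf = KFold(n_splits=hp.cv_folds, shuffle=True, random_state=seed)
            for m in grid:
                sse = 0.0
                for tr, te in kf.split(X):
                    rf = self._make_rf(m, seed).fit(X[tr], y[tr])
                    sse += np.sum((rf.predict(X[te]) - y[te]) ** 2)
                cv_rmse[m] = float(np.sqrt(sse / len(y)))
            best = min(cv_rmse, key=cv_rmse.get)
        else:
            best = int(hp.max_features)
        rf = self._make_rf(best, seed).fit(X, y)
        return CalibrationResults(model=self, regressor=rf, seed=seed,
                                  max_features=best, cv_rmse=cv_rmse)


@dataclass
class CalibrationResults:
    """Fitted calibration model with its training metadata."""

    model: CalibrationModel
    regressor: RandomForestRegressor = dc_field(repr=False)
    seed: int
    max_features: int
    cv_rmse: dict | None = None

    @property
    def features(self) -> tuple:
        return PREDICTORS

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predict rows of a predictor frame; NaN predictors give NaN."""
        missing = set(PREDICTORS) - set(frame.columns)
        if missing:
            raise ValueError(f"predictor frame missing {sorted(missing)}")
        X = frame[list(PREDICTORS)].to_numpy(float)
        ok = np.isfinite(X).all(axis=1)
        out = np.full(len(X), np.nan)
        if ok.any():
            out[ok] = self.regressor.predict(X[ok])
        return out

    def fitted_values(self) -> np.ndarray:
        return self.predict(self.model.table)

    def rsquared_insample(self) -> float:
        y = self.model.table["obs"].to_numpy(float)
        yhat = self.fitted_values()
        return 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)

    def predict_field(self, chem_total_fine: DailyField,
                      covariates: dict[str, DailyField]) -> DailyField:
        """Calibrated all-source concentration on the full fine grid.

        Lon/Lat predictors are cell centers; NaN in any predictor
        propagates to NaN output.
        """
        grid = chem_total_fine.grid
        dates = chem_total_fine.dates
        cal = _calendar_frame(dates).to_numpy(float)
        la, lo = grid.cell_centers()
        ncell = grid.ncells
        cov_flat = [covariates[n].values.reshape(len(dates), ncell)
                    for n in COVARIATE_PREDICTORS]
        chem_flat = chem_total_fine.values.reshape(len(dates), ncell)
        out = np.full((len(dates), ncell), np.nan)
        for t in range(len(dates)):
            cols = [chem_flat[t]] + [c[t] for c in cov_flat]
            cols += [np.full(ncell, v) for v in cal[t]]
            cols += [lo.ravel(), la.ravel()]
            X = np.column_stack(cols)
            ok = np.isfinite(X).all(axis=1)
            if ok.any():
                out[t, ok] = self.regressor.predict(X[ok])
        return DailyField(grid, dates, out.reshape(len(dates), *grid.shape),
                          name=f"{self.model.pollutant}_est_total",
                          units=chem_total_fine.units)

    def summary(self) -> str:
        lines = [
            "Calibration model (random forest)",
            "=" * 40,
            f"pollutant:        {self.model.pollutant}",
            f"training rows:    {len(self.model.table)}",
            f"stations:         {self.model.table['station_id'].nunique()}",
            f"features:         {len(PREDICTORS)}",
            f"trees:            {self.regressor.n_estimators}",
            f"max_features:     {self.max_features}"
            + ("  (CV-selected)" if self.cv_rmse else "  (pinned)"),
            f"min_samples_leaf: {self.regressor.min_samples_leaf}",
            f"seed:             {self.seed}",
            f"in-sample R2:     {self.rsquared_insample():.4f}",
        ]
        if self.cv_rmse:
            lines.append("CV RMSE by max_features: "
                         + ", ".join(f"{k}: {v:.3f}" for k, v in self.cv_rmse.items()))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fire-source attribution

@dataclass
class FireFraction:
    """Ratio chem_fire / chem_total per cell-date, in [-1, 1].

    Zero where chem_total is zero (no attributable fire signal); values
    beyond [-1, 1] — possible only through numerical noise in the inputs —
    are clipped and counted.
    """

    field: DailyField
    n_clipped: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.field.values


def fire_fraction(chem_fire: DailyField, chem_total: DailyField) -> FireFraction:
    if not chem_fire.aligned_with(chem_total):
        raise ValueError("fire and total fields are not aligned")
    tot = chem_total.values
    fire = chem_fire.values
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tot != 0, fire / tot, 0.0)
    frac = np.where(np.isnan(tot) | np.isnan(fire), np.nan, frac)
    n_clipped = int(np.sum((frac < -1) | (frac > 1)))
    if n_clipped:
        log.info("fire_fraction: clipped %d cell-dates into [-1, 1]", n_clipped)
    frac = np.clip(frac, -1.0, 1.0)
    return FireFraction(DailyField(chem_total.grid, chem_total.dates, frac,
                                   name=f"{chem_total.name}_fire_fraction",
                                   units="1"), n_clipped)


def scale_fire(est_total: DailyField, fraction: FireFraction) -> DailyField:
    """Fire-sourced concentration: est_total x fire fraction, pointwise."""
    frac = fraction.field
    if not est_total.aligned_with(frac):
        raise ValueError("est_total and fraction are not aligned")
    vals = est_total.values * frac.values
    name = est_total.name.replace("est_total", "est_fire")
    if name == est_total.name:
        name = est_total.name + "_fire"
    return DailyField(est_total.grid, est_total.dates, vals, name=name,
                      units=est_total.units)
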