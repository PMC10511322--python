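"""Model validation machinery.

Covers the cross-validation designs used to judge the calibration —
random tenfold over rows, spatial tenfold over stations, and
leave-one-cluster-out over k-means station clusters — plus the panel
fixed-effects "within R²" statistic, per-station R² summaries, the
background-median smoke PM2.5 observation operator and wildfire-event
station selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .fields import StationSeries
from .grids import great_circle_km

log = logging.getLogger(__name__)

SCHEMES = ("row_tenfold", "station_tenfold", "station_cluster")


@dataclass
class CvPartition:
    """Fold label per row of a training table."""

    scheme: str
    fold: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=int)
        if (np.bincount(self.fold) == 0).any():
            raise ValueError("every fold must be nonempty")

    @property
    def k(self) -> int:
        return int(self.fold.max()) + 1


def make_partition(table: pd.DataFrame, scheme: str = "row_tenfold",
                   k: int = 10, seed: int = 0,
                   cluster_labels: pd.Series | None = None) -> CvPartition:
    """Partition a station-day table into CV folds.

    ``row_tenfold`` splits rows at random; ``station_tenfold`` splits
    *stations* at random so no station straddles folds; ``station_cluster``
    assigns each station's rows to its spatial cluster (labels from
    :func:`kmeans_station_clusters`, or computed here when omitted).
    Fold sizes differ by at most one unit (rows or stations).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n = len(table)
    if scheme == "row_tenfold":
        if k > n:
            raise ValueError("more folds than rows")
        fold = np.empty(n, dtype=int)
        for f, idx in enumerate(np.array_split(rng.permutation(n), k)):
            fold[idx] = f
        return CvPartition(scheme, fold, seed)

    station_of_row = table["station_id"].to_numpy()
    stations = np.sort(np.unique(station_of_row))
    if scheme == "station_tenfold":
        if k > len(stations):
            raise ValueError("more folds than stations")
        assign = {}
        for f, idx in enumerate(np.array_split(rng.permutation(len(stations)), k)):
            for s in stations[idx]:
                assign[s] = f
    else:  # station_cluster
        if cluster_labels is None:
            coords = (table.groupby("station_id")[["Lon", "Lat"]].first())
            cluster_labels = kmeans_station_clusters(
                coords.rename(columns={"Lon": "lon", "Lat": "lat"}), k, seed)
        labels = pd.Series(cluster_labels)
        # re-encode to consecutive fold ids
        codes = {c: f for f, c in enumerate(sorted(labels.unique()))}
        assign = {s: codes[c] for s, c in labels.items()}
        sizes = pd.Series(list(assign.values())).value_counts()
        if (sizes == 1).any():
            log.warning("cluster partition has %d singleton cluster(s)",
                        int((sizes == 1).sum()))
    fold = np.array([assign[s] for s in station_of_row], dtype=int)
    return CvPartition(scheme, fold, seed)


@dataclass
class CvResult:
    """Pooled out-of-fold metrics plus the prediction table behind them."""

    scheme: str
    predictions: pd.DataFrame = dc_field(repr=False)   # obs, pred, fold (+ids)
    pooled_r2: float = np.nan
    rmse: float = np.nan
    per_fold: pd.DataFrame = dc_field(repr=False, default=None)

    def within_r2(self, group1: str = "station_id", group2: str = "year") -> float:
        """Two-way fixed-effects within-R² of obs on out-of-fold predictions."""
        p = self.predictions
        g2 = (p["date"].dt.year if group2 == "year" and "date" in p
              else p[group2])
        return within_r2(p["obs"].to_numpy(), p["pred"].to_numpy(),
                         p[group1].to_numpy(), np.asarray(g2))

    def station_r2(self, min_obs: int = 30):
        return station_r2(self.predictions, min_obs=min_obs)

    def summary(self) -> str:
        lines = [f"Cross-validation ({self.scheme})",
                 "=" * 40,
                 f"rows:       {len(self.predictions)}",
                 f"folds:      {self.predictions['fold'].nunique()}",
                 f"pooled R2:  {self.pooled_r2:.4f}",
                 f"RMSE:       {self.rmse:.4f}"]
        return "\n".join(lines)


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def cross_validate(table: pd.DataFrame, partition: CvPartition,
                   fit_fn) -> CvResult:
    """Out-of-fold evaluation: every row predicted exactly once by a model
    that never saw its fold.

    ``fit_fn(train_table)`` must return a callable mapping a table of rows
    to a prediction vector.
    """
    if len(partition.fold) != len(table):
        raise ValueError("partition length does not match the table")
    table = table.reset_index(drop=True)
    pred = np.full(len(table), np.nan)
    for f in range(partition.k):
        test_mask = partition.fold == f
        train = table[~test_mask]
        if train.empty:
            raise ValueError(f"fold {f} leaves no training data")
        model = fit_fn(train)
        pred[test_mask] = model(table[test_mask])
    out_cols = [c for c in ("station_id", "date") if c in table.columns]
    predictions = table[out_cols + ["obs"]].copy()
    predictions["pred"] = pred
    predictions["fold"] = partition.fold
    obs = predictions["obs"].to_numpy(float)
    per_fold = (predictions.groupby("fold")
                .apply(lambda g: pd.Series({
                    "n": len(g),
                    "r2": _r2(g["obs"].to_numpy(float), g["pred"].to_numpy(float)),
                    "rmse": float(np.sqrt(np.mean((g["obs"] - g["pred"]) ** 2)))}),
                    include_groups=False)
                .reset_index())
    return CvResult(scheme=partition.scheme, predictions=predictions,
                    pooled_r2=_r2(obs, pred),
                    rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
                    per_fold=per_fold)


def rf_fit_fn(hyperparams=None, seed: int = 0, max_train_rows: int | None = None,
              pollutant: str = "pm25"):
    """fit_fn running the package's calibration forest inside CV folds.

    ``max_train_rows`` caps the rows used to grow each fold's forest by a
    seeded subsample — a computational device for replicate studies; the
    out-of-fold predictions still cover every held-out row.
    """
    from .calibrate import CalibrationModel

    def fit(train: pd.DataFrame):
        t = train
        if max_train_rows is not None and len(t) > max_train_rows:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(t), max_train_rows, replace=False)
            t = t.iloc[np.sort(idx)]
        res = CalibrationModel(t, hyperparams, pollutant).fit(seed=seed)
        return lambda test: res.predict(test)

    return fit


# ---------------------------------------------------------------------------
# spatial clustering

def kmeans_station_clusters(stations, k, seed: int = 0,
                            n_init: int = 10) -> pd.Series:
    """Seeded k-means of stations on (lon, lat) with Euclidean distances.

    ``stations`` is a StationSeries or a DataFrame with lon/lat indexed (or
    keyed) by station_id.  When ``k`` is a range, the cluster count is
    chosen by the elbow rule — the k with the largest second difference of
    within-group sum of squares — since within-group SS itself decreases
    monotonically in k and cannot select a minimum.
    """
    if isinstance(stations, StationSeries):
        coords = stations.coordinates().set_index("station_id")
    else:
        coords = pd.DataFrame(stations)
        if "station_id" in coords.columns:
            coords = coords.set_index("station_id")
    X = coords[["lon", "lat"]].to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("station coordinates must be finite")
    n_distinct = len(np.unique(X, axis=0))

    def run(kk: int) -> tuple[np.ndarray, float]:
        if kk > n_distinct:
            raise ValueError(f"k={kk} exceeds {n_distinct} distinct station locations")
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X)
        return km.labels_, float(km.inertia_)

    if np.iterable(k):
        ks = sorted(int(v) for v in k)
        if len(ks) < 3:
            raise ValueError("a k-range needs at least 3 values for the elbow rule")
        wss = np.array([run(kk)[1] for kk in ks])
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        k = ks[1 + int(np.argmax(second_diff))]
    labels, _ = run(int(k))
    return pd.Series(labels, index=coords.index, name="cluster")


def cluster_loocv(table: pd.DataFrame, clusters: pd.Series, fit_fn) -> CvResult:
    """Leave-one-cluster-out CV: each spatial cluster is the test set once."""
    if clusters.nunique() < 2:
        raise ValueError("at least 2 clusters required")
    part = make_partition(table, "station_cluster", k=clusters.nunique(),
                          cluster_labels=clusters)
    res = cross_validate(table, part, fit_fn)
    res.scheme = "cluster_loocv"
    return res


# ---------------------------------------------------------------------------
# fixed-effects within R²

def within_r2(obs, est, group1, group2, tol: float = 1e-10,
              max_iter: int = 500) -> float:
    """R² of obs on est after absorbing two fixed-effect groupings.

    Both variables are demeaned by the two groupings iteratively until all
    group means vanish (to ``tol``), then obs is regressed on est through
    the origin.  Equals the partial R² of est in the dummy-variable OLS
    with both factor sets.  Returns NaN when est is absorbed by the fixed
    effects (no within variation left).
    """
    obs = np.asarray(obs, dtype=float)
    est = np.asarray(est, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(est)
    obs, est = obs[ok], est[ok]
    g1 = pd.factorize(np.asarray(group1)[ok])[0]
    g2 = pd.factorize(np.asarray(group2)[ok])[0]
    if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
        raise ValueError("each grouping needs at least 2 levels")

    def demean(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        for _ in range(max_iter):
            m1 = np.bincount(g1, weights=v) / np.bincount(g1)
            v = v - m1[g1]
            m2 = np.bincount(g2, weights=v) / np.bincount(g2)
            v = v - m2[g2]
            if max(np.abs(m1).max(), np.abs(m2).max()) < tol:
                break
        return v

    y = demean(obs)
    x = demean(est)
    sxx = float(x @ x)
    syy = float(y @ y)
    if syy == 0:
        return float("nan")
    if sxx < tol * max(1.0, float(est @ est)):
        warnings.warn("estimate has no within variation; within-R² undefined",
                      stacklevel=2)
        return float("nan")
    beta = float(x @ y) / sxx
    resid = y - beta * x
    return float(1.0 - resid @ resid / syy)


def station_r2(predictions: pd.DataFrame, min_obs: int = 30):
    """Per-station R² of out-of-fold predictions, with median and the
    10th-percentile floor.

    Stations with fewer than ``min_obs`` rows are excluded and counted.
    Returns (per-station DataFrame, summary dict).
    """
    rows = []
    n_excluded = 0
    for sid, g in predictions.groupby("station_id"):
        if len(g) < min_obs:
            n_excluded += 1
            continue
        rows.append({"station_id": sid, "n": len(g),
                     "r2": _r2(g["obs"].to_numpy(float), g["pred"].to_numpy(float))})
    per_station = pd.DataFrame(rows)
    r2s = per_station["r2"].dropna() if len(per_station) else pd.Series(dtype=float)
    summary = {"median": float(r2s.median()) if len(r2s) else float("nan"),
               "p10": float(r2s.quantile(0.1)) if len(r2s) else float("nan"),
               "n_stations": len(per_station), "n_excluded": n_excluded}
    return per_station, summary


# ---------------------------------------------------------------------------
# smoke PM2.5 observation operator

def observed_smoke_pm(obs: pd.Series, smoke_day: pd.Series) -> pd.Series:
    """Station-observed smoke PM2.5 by the background-median method.

    The background for a smoke day in month m of year y is the median of
    that station's *non-smoke* observations in month m across years
    y-1..y+1; smoke PM2.5 is the observation minus background floored at
    zero, and identically zero on non-smoke days.  Smoke days whose 3-year
    month window holds no non-smoke observation get NaN.
    """
    obs = obs.copy()
    obs.index = pd.DatetimeIndex(obs.index)
    smoke = smoke_day.reindex(obs.index).fillna(False).astype(bool)
    non_smoke = obs[~smoke].dropna()
    out = pd.Series(0.0, index=obs.index)
    for ts in obs.index[smoke.to_numpy()]:
        window = non_smoke[(non_smoke.index.month == ts.month)
                           & (non_smoke.index.year >= ts.year - 1)
                           & (non_smoke.index.year <= ts.year + 1)]
        if window.empty or not np.isfinite(obs[ts]):
            out[ts] = np.nan
        else:
            out[ts] = max(obs[ts] - float(window.median()), 0.0)
    return out


# ---------------------------------------------------------------------------
# wildfire-event validation

def most_affected_station(stations: StationSeries, center: tuple[float, float],
                          event_window: tuple, pre_window: tuple,
                          radius_km: float = 100.0) -> str:
    """Station near a fire with the largest event-vs-pre increase in
    observed concentration; ties break to the smaller station id."""
    lon0, lat0 = center
    ev0, ev1 = pd.Timestamp(event_window[0]), pd.Timestamp(event_window[1])
    pr0, pr1 = pd.Timestamp(pre_window[0]), pd.Timestamp(pre_window[1])
    best_id, best_inc = None, -np.inf
    for _, st in stations.coordinates().iterrows():
        if great_circle_km(lon0, lat0, st["lon"], st["lat"]) > radius_km:
            continue
        ser = stations.series(st["station_id"])
        ev = ser[(ser.index >= ev0) & (ser.index <= ev1)].dropna()
        pr = ser[(ser.index >= pr0) & (ser.index <= pr1)].dropna()
        if ev.empty or pr.empty:
            continue
        inc = float(ev.mean() - pr.mean())
        if inc > best_inc or (inc == best_inc and str(st["station_id"]) < str(best_id)):
            best_id, best_inc = st["station_id"], inc
    if best_id is None:
        raise ValueError("no station within radius has data in both windows")
    return best_id
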