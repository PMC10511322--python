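import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from smokeatlas import StationSeries
from smokeatlas.evaluate import (CvPartition, cluster_loocv, cross_validate,
                                 kmeans_station_clusters, make_partition,
                                 most_affected_station, observed_smoke_pm,
                                 station_r2, within_r2)


def _table(n_stations=10, n_days=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_stations):
        lon, lat = rng.uniform(0, 10, 2)
        for d in range(n_days):
            rows.append({"station_id": f"s{s:02d}", "Lon": lon, "Lat": lat,
                         "date": pd.Timestamp("2015-01-01") + pd.Timedelta(days=d),
                         "x": rng.normal(), "obs": rng.uniform(1, 20)})
    return pd.DataFrame(rows)


class TestPartitions:
    def test_row_scheme_equal_folds(self):
        t = _table(10, 10)
        p = make_partition(t, "row_tenfold", k=10, seed=0)
        assert np.bincount(p.fold).tolist() == [10] * 10

    def test_station_scheme_never_splits_a_station(self):
        t = _table(12, 8)
        p = make_partition(t, "station_tenfold", k=5, seed=0)
        per_station = t.assign(fold=p.fold).groupby("station_id")["fold"].nunique()
        assert (per_station == 1).all()

    def test_deterministic_given_seed(self):
        t = _table()
        p1 = make_partition(t, "station_tenfold", k=5, seed=42)
        p2 = make_partition(t, "station_tenfold", k=5, seed=42)
        np.testing.assert_array_equal(p1.fold, p2.fold)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_partition(_table(4, 3), "station_tenfold", k=10)


class TestCrossValidate:
    def test_perfect_predictor(self):
        t = _table()
        p = make_partition(t, "row_tenfold", k=5, seed=0)
        res = cross_validate(t, p, lambda tr: (lambda te: te["obs"].to_numpy()))
        assert res.pooled_r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0)

    def test_training_mean_predictor_has_no_skill(self):
        t = _table()
        p = make_partition(t, "row_tenfold", k=5, seed=0)
        res = cross_validate(
            t, p, lambda tr: (lambda te: np.full(len(te), tr["obs"].mean())))
        assert res.pooled_r2 <= 0.0 + 1e-9

    def test_matches_hand_loop(self):
        """Out-of-fold metrics equal an explicit per-fold loop with a linear
        fit (independent of the cross_validate implementation)."""
        t = _table(6, 8, seed=3)
        t["obs"] = 2.0 + 1.5 * t["x"] + np.random.default_rng(3).normal(0, 0.3, len(t))
        p = make_partition(t, "row_tenfold", k=4, seed=1)

        def fit(train):
            b, a = np.polyfit(train["x"], train["obs"], 1)
            return lambda te: a + b * te["x"].to_numpy()

        res = cross_validate(t, p, fit)
        pred = np.full(len(t), np.nan)
        for f in range(4):
            tr = t[p.fold != f]
            b, a = np.polyfit(tr["x"], tr["obs"], 1)
            pred[p.fold == f] = a + b * t.loc[p.fold == f, "x"].to_numpy()
        obs = t["obs"].to_numpy()
        r2 = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert res.pooled_r2 == pytest.approx(r2, abs=1e-12)
        assert res.rmse == pytest.approx(np.sqrt(np.mean((obs - pred) ** 2)),
                                         abs=1e-12)

    def test_every_row_predicted_once(self):
        t = _table()
        p = make_partition(t, "station_tenfold", k=5, seed=0)
        res = cross_validate(t, p, lambda tr: (lambda te: np.zeros(len(te))))
        assert res.predictions["pred"].notna().all()
        assert len(res.predictions) == len(t)


class TestKmeans:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.1, (15, 2))
        b = rng.normal([10, 10], 0.1, (15, 2))
        coords = pd.DataFrame(np.vstack([a, b]), columns=["lon", "lat"])
        labels = kmeans_station_clusters(coords, 2, seed=0)
        assert labels[:15].nunique() == 1 and labels[15:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n_zero_wss(self):
        rng = np.random.default_rng(1)
        coords = pd.DataFrame(rng.uniform(0, 5, (8, 2)), columns=["lon", "lat"])
        labels = kmeans_station_clusters(coords, 8, seed=0)
        assert labels.nunique() == 8

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 10, (30, 2))
        coords = pd.DataFrame(X, columns=["lon", "lat"])
        labels = kmeans_station_clusters(coords, 3, seed=0).to_numpy()

        def wss(lab):
            return sum(((X[lab == c] - X[lab == c].mean(0)) ** 2).sum()
                       for c in np.unique(lab))

        km_wss = wss(labels)
        rand_wss = [wss(rng.integers(0, 3, 30)) for _ in range(100)]
        assert km_wss <= min(rand_wss)

    def test_k_range_elbow(self):
        rng = np.random.default_rng(3)
        blobs = np.vstack([rng.normal([c * 8, 0], 0.2, (12, 2)) for c in range(3)])
        coords = pd.DataFrame(blobs, columns=["lon", "lat"])
        labels = kmeans_station_clusters(coords, range(2, 7), seed=0)
        assert labels.nunique() == 3

    def test_too_few_distinct_points(self):
        coords = pd.DataFrame({"lon": [1.0, 1.0], "lat": [2.0, 2.0]})
        with pytest.raises(ValueError):
            kmeans_station_clusters(coords, 2, seed=0)


class TestClusterLoocv:
    def test_coinciding_with_station_folds_is_equivalent(self):
        t = _table(10, 6, seed=5)
        part = make_partition(t, "station_tenfold", k=5, seed=0)
        labels = (t.assign(fold=part.fold).groupby("station_id")["fold"].first())
        fit = lambda tr: (lambda te: np.full(len(te), tr["obs"].mean()))
        res_station = cross_validate(t, part, fit)
        res_cluster = cluster_loocv(t, labels, fit)
        assert res_cluster.pooled_r2 == pytest.approx(res_station.pooled_r2)

    def test_two_cluster_hand_computation(self):
        t = _table(4, 5, seed=9)
        labels = pd.Series([0, 0, 1, 1], index=sorted(t["station_id"].unique()))
        fit = lambda tr: (lambda te: np.full(len(te), tr["obs"].mean()))
        res = cluster_loocv(t, labels, fit)
        obs = t["obs"].to_numpy()
        pred = np.empty(len(t))
        in0 = t["station_id"].isin(["s00", "s01"]).to_numpy()
        pred[in0] = obs[~in0].mean()
        pred[~in0] = obs[in0].mean()
        r2 = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert res.pooled_r2 == pytest.approx(r2, abs=1e-12)


class TestWithinR2:
    def _panel(self, n_stations=20, n_years=5, seed=0, beta=1.0, noise=1.0):
        rng = np.random.default_rng(seed)
        st_fx = rng.normal(0, 3, n_stations)
        yr_fx = rng.normal(0, 2, n_years)
        rows = []
        for s in range(n_stations):
            for y in range(n_years):
                for _ in range(4):
                    x = rng.normal()
                    e = rng.normal(0, noise)
                    rows.append({"station": s, "year": y, "est": x,
                                 "obs": st_fx[s] + yr_fx[y] + beta * x + e})
        return pd.DataFrame(rows)

    def test_identity_prediction_gives_one(self):
        p = self._panel(noise=0.0)
        r2 = within_r2(p["obs"], p["obs"], p["station"], p["year"])
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_absorbed_regressor_is_nan(self):
        p = self._panel()
        est = p["station"].astype(float)  # varies only across stations
        with pytest.warns(UserWarning):
            assert np.isnan(within_r2(p["obs"], est, p["station"], p["year"]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dummy_variable_ols(self, seed):
        """Iterated demeaning equals the explicit fixed-effects design-matrix
        partial R^2 from statsmodels."""
        p = self._panel(n_stations=15, n_years=6, seed=seed, noise=2.0)
        got = within_r2(p["obs"], p["est"], p["station"], p["year"])
        full = smf.ols("obs ~ est + C(station) + C(year)", data=p).fit()
        restr = smf.ols("obs ~ C(station) + C(year)", data=p).fit()
        expect = 1 - full.ssr / restr.ssr
        assert got == pytest.approx(expect, abs=1e-8)


class TestStationR2:
    def test_perfect_and_null_stations(self):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(5):
            obs = rng.uniform(0, 10, 40)
            pred = obs if s < 4 else np.full(40, obs.mean())
            for o, p in zip(obs, pred):
                rows.append({"station_id": f"s{s}", "obs": o, "pred": p})
        per, summary = station_r2(pd.DataFrame(rows), min_obs=30)
        r2s = per.set_index("station_id")["r2"]
        assert np.allclose(r2s[[f"s{i}" for i in range(4)]], 1.0)
        assert r2s["s4"] == pytest.approx(0.0, abs=1e-12)
        assert summary["median"] == 1.0

    def test_quantiles_match_direct_computation(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(5):
            obs = rng.uniform(0, 10, 35)
            pred = obs + rng.normal(0, s + 0.5, 35)
            for o, p in zip(obs, pred):
                rows.append({"station_id": f"s{s}", "obs": o, "pred": p})
        per, summary = station_r2(pd.DataFrame(rows), min_obs=30)
        assert summary["median"] == pytest.approx(per["r2"].median())
        assert summary["p10"] == pytest.approx(per["r2"].quantile(0.1))

    def test_below_minimum_excluded(self):
        rows = [{"station_id": "a", "obs": float(i), "pred": float(i)}
                for i in range(10)]
        per, summary = station_r2(pd.DataFrame(rows), min_obs=30)
        assert summary["n_excluded"] == 1 and summary["n_stations"] == 0


class TestObservedSmokePm:
    def _series(self):
        dates = pd.date_range("2017-01-01", "2019-12-31", freq="D")
        obs = pd.Series(10.0, index=dates)
        smoke = pd.Series(False, index=dates)
        # non-smoke January observations across the 3 years: 8, 10, 12
        obs.loc["2017-01"] = 8.0
        obs.loc["2018-01"] = 10.0
        obs.loc["2019-01"] = 12.0
        obs.loc["2018-01-10"] = 40.0
        smoke.loc["2018-01-10"] = True
        return obs, smoke

    def test_hand_computed_median_background(self):
        obs, smoke = self._series()
        out = observed_smoke_pm(obs, smoke)
        # background = median of non-smoke Jan obs in 2017-2019 = 10
        assert out["2018-01-10"] == pytest.approx(30.0)

    def test_non_smoke_days_are_zero(self):
        obs, smoke = self._series()
        out = observed_smoke_pm(obs, smoke)
        assert (out[~smoke] == 0.0).all()

    def test_floored_at_zero(self):
        obs, smoke = self._series()
        obs.loc["2018-01-10"] = 5.0  # below the background of 10
        assert observed_smoke_pm(obs, smoke)["2018-01-10"] == 0.0

    def test_translation_equivariance(self):
        obs, smoke = self._series()
        shifted = observed_smoke_pm(obs + 7.3, smoke)
        base = observed_smoke_pm(obs, smoke)
        pd.testing.assert_series_equal(shifted, base)

    def test_empty_window_gives_nan(self):
        dates = pd.date_range("2018-01-01", periods=5)
        obs = pd.Series(20.0, index=dates)
        smoke = pd.Series(True, index=dates)  # no non-smoke day at all
        assert observed_smoke_pm(obs, smoke).isna().all()


class TestMostAffectedStation:
    def _stations(self, increases, lons=None):
        dates = pd.date_range("2019-01-01", periods=20)
        rows = []
        for i, inc in enumerate(increases):
            vals = np.full(20, 10.0)
            vals[10:] += inc
            rows.append(pd.DataFrame({
                "station_id": f"s{i}", "lon": (lons or [0.1 * i] * len(increases))[i],
                "lat": 0.0, "date": dates, "value_ugm3": vals}))
        return StationSeries("pm25", pd.concat(rows, ignore_index=True))

    WINDOWS = dict(event_window=("2019-01-11", "2019-01-20"),
                   pre_window=("2019-01-01", "2019-01-10"))

    def test_argmax_increase(self):
        st = self._stations([2.0, 15.0, 7.0])
        assert most_affected_station(st, (0.0, 0.0), **self.WINDOWS) == "s1"

    def test_tie_breaks_to_lower_id(self):
        st = self._stations([10.0, 10.0])
        assert most_affected_station(st, (0.0, 0.0), **self.WINDOWS) == "s0"

    def test_radius_excludes_far_stations(self):
        st = self._stations([2.0, 50.0], lons=[0.0, 30.0])
        assert most_affected_station(st, (0.0, 0.0), radius_km=100,
                                     **self.WINDOWS) == "s0"

    def test_matches_exhaustive_scan(self, rng):
        incs = rng.uniform(-5, 20, 8).tolist()
        st = self._stations(incs)
        expect = f"s{int(np.argmax(incs))}"
        assert most_affected_station(st, (0.0, 0.0), **self.WINDOWS) == expect

    def test_no_qualifying_station_raises(self):
        st = self._stations([1.0])
        with pytest.raises(ValueError):
            most_affected_station(st, (90.0, 0.0), radius_km=10, **self.WINDOWS)
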