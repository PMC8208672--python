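"""Tests for the synthetic-data generator: determinism, construction
invariants and recovery of the generating parameters by the estimators."""

import numpy as np
import pandas as pd
import pytest

from nestheat import isotope as iso
from nestheat import stats as st
from nestheat import thermal as th
from nestheat.errors import InvalidInputError
from nestheat.simulate import (
    BreedingConfig,
    TeConfig,
    WashoutConfig,
    WeatherConfig,
    simulate_breeding,
    simulate_bundle,
    simulate_nest_te,
    simulate_washout,
    simulate_weather,
)

from conftest import small_config


class TestDeterminism:
    def test_washout_same_seed_identical(self):
        a, _ = simulate_washout(WashoutConfig(n_birds=5), 42)
        b, _ = simulate_washout(WashoutConfig(n_birds=5), 42)
        pd.testing.assert_frame_equal(a, b)

    def test_weather_same_seed_identical(self):
        cfg = WeatherConfig(n_days=5)
        pd.testing.assert_frame_equal(
            simulate_weather(cfg, 7), simulate_weather(cfg, 7)
        )

    def test_different_seed_differs(self):
        cfg = WeatherConfig(n_days=5)
        a, b = simulate_weather(cfg, 1), simulate_weather(cfg, 2)
        assert not a["t_air"].equals(b["t_air"])


class TestWashout:
    def test_noise_free_recovery_to_1e9(self):
        cfg = WashoutConfig(n_birds=10, noise_sd=0.0)
        samples, truth = simulate_washout(cfg, 3)
        for _, row in truth.birds.iterrows():
            grp = samples[samples["bird_id"] == row["bird_id"]]
            ss = [
                iso.EnrichmentSample(
                    row["bird_id"], r.t, r.d18O, r.d2H, bool(r.is_background)
                )
                for r in grp.itertuples()
            ]
            initial, final = iso.select_endpoints(ss)
            rates = iso.estimate_turnover(
                initial, final, (cfg.background_d18O, cfg.background_d2H)
            )
            assert rates.kH == pytest.approx(row["kH"], rel=1e-9)
            assert rates.k_diff == pytest.approx(row["k_diff"], rel=1e-9)

    def test_noisy_kh_median_error_under_5pct(self):
        cfg = WashoutConfig(n_birds=200, noise_sd=5.0)
        samples, truth = simulate_washout(cfg, 11)
        errors = []
        for _, row in truth.birds.iterrows():
            grp = samples[samples["bird_id"] == row["bird_id"]]
            ss = [
                iso.EnrichmentSample(
                    row["bird_id"], r.t, r.d18O, r.d2H, bool(r.is_background)
                )
                for r in grp.itertuples()
            ]
            res = iso.analyse_bird_day(
                ss, iso.BodyRecord(row["bird_id"], row["mass_g"], row["mass_g"])
            )
            initial, final = iso.select_endpoints(ss)
            rates = iso.estimate_turnover(
                initial, final, (cfg.background_d18O, cfg.background_d2H)
            )
            errors.append(abs(rates.kH - row["kH"]) / row["kH"])
        assert np.median(errors) < 0.05

    def test_invalid_rate_config(self):
        with pytest.raises(InvalidInputError):
            simulate_washout(WashoutConfig(kH_mean=-0.1), 0)


class TestWeather:
    def test_envelope_mean_and_range(self):
        cfg = WeatherConfig(n_days=1000, step_minutes=60)
        w = simulate_weather(cfg, 19)
        tmax = w.groupby(pd.to_datetime(w["datetime"]).dt.date)["t_air"].max()
        assert abs(tmax.mean() - 34.1) < 0.5
        assert tmax.min() >= 20.7 - 1e-9 and tmax.max() <= 40.8 + 1e-9

    def test_zero_diel_amplitude_flat_day(self):
        cfg = WeatherConfig(n_days=1, diel_amplitude=0.0)
        w = simulate_weather(cfg, 2)
        assert w["t_air"].nunique() == 1

    def test_columns_and_bounds(self):
        w = simulate_weather(WeatherConfig(n_days=3), 5)
        assert set(w.columns) == {"datetime", "t_air", "rh", "solar", "wind", "rain_mm"}
        assert (w["rh"].between(0, 100)).all()
        assert (w[["solar", "wind", "rain_mm"]] >= 0).all().all()


@pytest.fixture(scope="module")
def te_weather():
    return simulate_weather(WeatherConfig(n_days=20), 23)


@pytest.fixture(scope="module")
def breeding_weather():
    return simulate_weather(WeatherConfig(n_days=60, step_minutes=60), 31)


class TestNestTe:

    def test_noiseless_slope_recovered(self, te_weather):
        cfg = TeConfig(n_nests=3, noise_sd=0.0, nest_offset_sd=0.0, days_per_nest=5)
        te, cal_pairs, _ = simulate_nest_te(te_weather, cfg, 1)
        cal = th.calibrate_logger(cal_pairs[["logger", "reference"]].to_numpy())
        te["te_cal"] = cal.apply(te["te_raw"])
        pairs = th.align_te_weather(te, te_weather)
        # exclude records clipped to Tair (Te floor) before regressing
        free = pairs[pairs["te_cal"] > pairs["t_air"] + 1e-6]
        fit = st.fit_glm(
            st.ModelSpec("te_cal", "gaussian", ["t_air"], free.reset_index())
        )
        assert fit.params["t_air"] == pytest.approx(cfg.slope, abs=1e-6)

    def test_daytime_te_at_least_tair(self, te_weather):
        cfg = TeConfig(n_nests=4, days_per_nest=5)
        te, cal_pairs, _ = simulate_nest_te(te_weather, cfg, 2)
        cal = th.calibrate_logger(cal_pairs[["logger", "reference"]].to_numpy())
        te["te_cal"] = cal.apply(te["te_raw"])
        pairs = th.align_te_weather(te, te_weather)
        assert (pairs["te_cal"] >= pairs["t_air"] - 1e-6).all()

    def test_exceedance_bookkeeping_exact(self, te_weather):
        cfg = TeConfig(n_nests=6, days_per_nest=6)
        te, cal_pairs, truth = simulate_nest_te(te_weather, cfg, 3)
        cal = th.calibrate_logger(cal_pairs[["logger", "reference"]].to_numpy())
        te["te_cal"] = cal.apply(te["te_raw"])
        day = te[th.daytime_mask(te["datetime"])]
        per_nest, _ = th.exceedance_stats(day)
        got = per_nest.pivot(index="nest_id", columns="threshold", values="count")
        want = truth.set_index("nest_id")
        assert (got[41.0] == want["count_gt_41"]).all()
        assert (got[50.0] == want["count_gt_50"]).all()


class TestBreeding:

    def test_hatch_probability_is_logistic_in_mean_tmax(self, breeding_weather):
        cfg = BreedingConfig(n_nests=30, n_obs_days=5, n_mass_birds=10)
        tables, truth = simulate_breeding(breeding_weather, cfg, 1)
        from scipy.special import expit

        want = expit(
            cfg.hatch_slope_per_degC * (truth.nests["mean_tmax_inc"] - cfg.hatch_t50)
        )
        assert np.allclose(truth.nests["p_hatch"], want, atol=1e-12)

    def test_attendance_proportions_recovered_exactly(self, breeding_weather):
        from nestheat import behaviour as bh

        cfg = BreedingConfig(n_nests=30, n_obs_days=12, n_mass_birds=10)
        tables, truth = simulate_breeding(breeding_weather, cfg, 2)
        att = bh.attendance_table(tables["bouts"])
        merged = att.merge(truth.attendance, on=["nest_id", "date"])
        assert len(merged) == len(truth.attendance)
        assert (
            (merged["prop_incubated"] - merged["prop_incubated_true"]).abs() < 1e-6
        ).all()

    def test_null_attendance_slope_covers_zero(self, breeding_weather):
        """With a flat attendance model the fitted slope CI covers zero.

        Day-level proportions carry logit-normal noise beyond binomial
        sampling, so the day is the unit of analysis (gaussian fit)."""
        hits = 0
        for rep in range(10):
            cfg = BreedingConfig(
                n_nests=30, n_obs_days=46, n_mass_birds=10, attendance_slope=0.0
            )
            tables, truth = simulate_breeding(breeding_weather, cfg, 100 + rep)
            df = truth.attendance.copy()
            df["y"] = df["prop_incubated_true"]
            dstd, _ = st.standardize(df, ["tmax"])
            fit = st.fit_glm(st.ModelSpec("y", "gaussian", ["tmax"], dstd))
            hits += fit.ci_lower["tmax"] <= 0.0 <= fit.ci_upper["tmax"]
        assert hits >= 9

    def test_declining_attendance_detected(self, breeding_weather):
        """With the default temperature-dependent attendance model the
        fitted slope is negative in nearly all replicates at n = 46 days."""
        neg = 0
        for rep in range(10):
            cfg = BreedingConfig(n_nests=30, n_obs_days=46, n_mass_birds=10)
            tables, truth = simulate_breeding(breeding_weather, cfg, 300 + rep)
            df = truth.attendance.copy()
            df["y"] = df["prop_incubated_true"]
            dstd, _ = st.standardize(df, ["tmax"])
            fit = st.fit_glm(st.ModelSpec("y", "gaussian", ["tmax"], dstd))
            neg += fit.params["tmax"] < 0.0
        assert neg >= 9

    def test_mass_model_segments(self, breeding_weather):
        cfg = BreedingConfig(
            n_nests=10, n_obs_days=5, n_mass_birds=400, mass_resid_sd=0.0
        )
        tables, _ = simulate_breeding(breeding_weather, cfg, 5)
        masses = tables["masses"]
        daily_tmax = breeding_weather.groupby(pd.to_datetime(breeding_weather["datetime"]).dt.date)[
            "t_air"
        ].max()
        for bird, grp in masses.groupby("bird_id"):
            grp = grp.sort_values("date")
            dm = grp["mass_g"].iloc[1] - grp["mass_g"].iloc[0]
            tmax = daily_tmax[grp["date"].iloc[0]]
            if tmax < cfg.mass_breakpoint:
                assert dm == pytest.approx(0.0, abs=1e-9)
            else:
                assert dm == pytest.approx(
                    cfg.mass_slope_above * (tmax - cfg.mass_breakpoint), abs=1e-9
                )


class TestBundle:
    def test_generated_data_pass_validators(self, bundle_dir):
        _, bundle, _ = bundle_dir
        from nestheat import behaviour as bh

        att = bh.attendance_table(bundle["bouts"])  # raises on overlaps
        assert (att["prop_incubated"].between(0, 1)).all()
        assert (bundle["masses"].groupby("bird_id").size() == 2).all()

    def test_bundle_files_written(self, bundle_dir):
        outdir, bundle, _ = bundle_dir
        for name in (
            "weather",
            "te_loggers",
            "calibration",
            "isotopes",
            "masses",
            "bouts",
            "focals",
            "nests",
        ):
            assert (outdir / f"{name}.csv").is_file()
        assert (outdir / "ground_truth.json").is_file()

    def test_bundle_deterministic(self):
        a, _ = simulate_bundle(small_config(), seed=9)
        b, _ = simulate_bundle(small_config(), seed=9)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])
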