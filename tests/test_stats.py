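"""Tests for standardization, VIF screening, GLM fitting, AICc selection,
thresholds, segmented regression and power simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from nestheat import stats as st
from nestheat.errors import (
    ComparabilityError,
    DegeneratePredictorError,
    InvalidInputError,
    UndefinedThresholdError,
)


class TestStandardize:
    def test_unit_triplet(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, tr = st.standardize(df, ["x"])
        assert list(out["x"]) == [-1.0, 0.0, 1.0]
        assert tr.inverse("x", 0.0) == 2.0

    def test_constant_column_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            st.standardize(pd.DataFrame({"x": [5.0, 5.0, 5.0]}), ["x"])

    @given(
        mu=hst.floats(-50, 50),
        sd=hst.floats(0.5, 20),
        z=hst.floats(-3, 3),
    )
    def test_round_trip_identity(self, mu, sd, z):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": mu + sd * rng.standard_normal(50)})
        _, tr = st.standardize(df, ["x"])
        x = tr.inverse("x", z)
        assert tr.forward("x", x) == pytest.approx(z, abs=1e-12)


class TestVif:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"a": [1.0, -1, 1, -1] * 2, "b": [1.0, 1, -1, -1] * 2})
        vifs, subsets = st.vif_screen(df, ["a", "b"])
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert subsets == [("a", "b")]

    def test_duplicated_predictor_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x})
        vifs, subsets = st.vif_screen(df, ["a", "b"])
        assert math.isinf(vifs["a"]) and math.isinf(vifs["b"])
        assert ("a", "b") not in subsets

    def test_correlated_pair_never_cooccurs(self):
        # r = 0.9 between a and b -> VIF = 1/(1-0.81) ~ 5.26 > 2
        rng = np.random.default_rng(2)
        n = 2000
        a = rng.standard_normal(n)
        b = 0.9 * a + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        c = rng.standard_normal(n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        vifs, subsets = st.vif_screen(df, ["a", "b", "c"])
        assert vifs["a"] == pytest.approx(1.0 / (1.0 - 0.81), rel=0.15)
        for sub in subsets:
            assert not {"a", "b"} <= set(sub)
        assert any({"a", "c"} <= set(s) for s in subsets)


class TestFitGlm:
    def test_gaussian_exact_line(self):
        df = pd.DataFrame({"x": np.arange(12.0)})
        df["y"] = 2.0 * df["x"] + 1.0
        fit = st.fit_glm(st.ModelSpec("y", "gaussian", ["x"], df))
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-16)

    def test_gaussian_equals_closed_form(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"x": rng.standard_normal(60), "z": rng.standard_normal(60)}
        )
        df["y"] = 1.0 + 0.5 * df["x"] - 0.3 * df["z"] + rng.standard_normal(60)
        fit = st.fit_glm(st.ModelSpec("y", "gaussian", ["x", "z"], df))
        X = np.column_stack([np.ones(60), df["x"], df["z"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_binomial_simulation_slope(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(5000)
        p = 1.0 / (1.0 + np.exp(-(0.5 - 1.0 * z)))
        df = pd.DataFrame({"z": z, "y": (rng.random(5000) < p).astype(float)})
        fit = st.fit_glm(st.ModelSpec("y", "binomial", ["z"], df))
        assert fit.params["z"] == pytest.approx(-1.0, abs=0.1)
        assert fit.ci_lower["z"] < -1.0 < fit.ci_upper["z"]

    def test_interaction_column(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"x": rng.standard_normal(80), "g": rng.integers(0, 2, 80) - 0.5}
        )
        df["y"] = 2.0 * df["x"] * df["g"]
        fit = st.fit_glm(
            st.ModelSpec("y", "gaussian", ["x", "g"], df, interactions=[("x", "g")])
        )
        assert fit.params["x:g"] == pytest.approx(2.0, abs=1e-8)

    def test_too_few_rows(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(InvalidInputError):
            st.fit_glm(st.ModelSpec("y", "gaussian", ["x"], df))


class TestModelSelection:
    @staticmethod
    def fake_fit(aicc_value, terms, data):
        spec = st.ModelSpec("y", "gaussian", list(terms), data)
        params = pd.Series(1.0, index=["Intercept", *terms])
        se = pd.Series(0.1, index=params.index)
        return st.FitResult(
            spec=spec,
            params=params,
            se=se,
            ci_lower=params - 0.196,
            ci_upper=params + 0.196,
            loglik=0.0,
            n=len(data),
            k=len(params) + 1,
            aicc=aicc_value,
            dispersion=1.0,
        )

    def test_weights_hand_oracle(self):
        w = st.akaike_weights([100.0, 101.0, 104.0])
        e = np.exp([-0.0, -0.5, -2.0])
        assert np.allclose(w, e / e.sum(), atol=1e-10)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_aicc_symmetric_weights(self):
        w = st.akaike_weights([50.0, 50.0])
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)

    def test_averaging_set_and_full_averaging(self):
        data = pd.DataFrame({"y": np.zeros(20)})
        fits = [
            self.fake_fit(100.0, ["a"], data),
            self.fake_fit(101.0, ["b"], data),
            self.fake_fit(104.0, ["c"], data),
        ]
        mset = st.model_selection(fits)
        assert list(mset.averaging_mask) == [True, True, False]
        w = np.exp([-0.0, -0.5]) / np.exp([-0.0, -0.5]).sum()
        # full averaging: "a" appears only in the first model, so it is
        # weighted by w[0] and zero-substituted elsewhere
        assert mset.averaged_coefficients["a"] == pytest.approx(w[0], abs=1e-12)
        assert mset.averaged_coefficients["b"] == pytest.approx(w[1], abs=1e-12)
        assert "c" not in mset.averaged_coefficients.index

    def test_single_candidate_weight_one(self):
        data = pd.DataFrame({"y": np.zeros(10)})
        mset = st.model_selection([self.fake_fit(10.0, ["a"], data)])
        assert mset.weights[0] == 1.0

    def test_differing_rows_rejected(self):
        d1 = pd.DataFrame({"y": np.zeros(10)})
        d2 = pd.DataFrame({"y": np.zeros(12)})
        with pytest.raises(ComparabilityError):
            st.model_selection(
                [self.fake_fit(1.0, ["a"], d1), self.fake_fit(2.0, ["a"], d2)]
            )

    def test_aicc_formula(self):
        assert st.aicc(loglik=-10.0, k=3, n=20) == pytest.approx(
            20.0 + 6.0 + 2 * 3 * 4 / 16.0
        )


class TestThreshold:
    def test_centre_of_logistic(self):
        tr = st.StandardizeTransform(means={"t": 35.3}, sds={"t": 1.0})
        fit = TestModelSelection.fake_fit(0.0, ["t"], pd.DataFrame({"y": [0.0]}))
        fit.params["Intercept"], fit.params["t"] = 0.0, -1.0
        assert st.threshold_from_logistic(fit, tr, "t") == pytest.approx(35.3)

    def test_algebra_case(self):
        tr = st.StandardizeTransform(means={"t": 30.0}, sds={"t": 2.0})
        fit = TestModelSelection.fake_fit(0.0, ["t"], pd.DataFrame({"y": [0.0]}))
        fit.params["Intercept"], fit.params["t"] = 1.0, -2.0
        assert st.threshold_from_logistic(fit, tr, "t") == pytest.approx(31.0)

    def test_zero_slope(self):
        tr = st.StandardizeTransform(means={"t": 30.0}, sds={"t": 2.0})
        fit = TestModelSelection.fake_fit(0.0, ["t"], pd.DataFrame({"y": [0.0]}))
        fit.params["Intercept"], fit.params["t"] = 1.0, 0.0
        with pytest.raises(UndefinedThresholdError):
            st.threshold_from_logistic(fit, tr, "t")

    @pytest.mark.parametrize("n", [100, 1000, 10000])
    def test_consistency_with_growing_samples(self, n):
        """Recovered threshold converges on the generating one as n grows."""
        rng = np.random.default_rng(21)
        t = rng.normal(34.0, 2.5, n)
        p = 1.0 / (1.0 + np.exp(0.9 * (t - 35.3)))
        df = pd.DataFrame({"t": t, "y": (rng.random(n) < p).astype(float)})
        dstd, tr = st.standardize(df, ["t"])
        fit = st.fit_glm(st.ModelSpec("y", "binomial", ["t"], dstd))
        got = st.threshold_from_logistic(fit, tr, "t")
        tol = {100: 2.5, 1000: 0.8, 10000: 0.3}[n]
        assert got == pytest.approx(35.3, abs=tol)


class TestBreakpoint:
    @given(true_bp=hst.floats(32.0, 39.0))
    def test_noiseless_recovery_any_interior_breakpoint(self, true_bp):
        x = np.round(np.arange(28.0, 42.01, 0.1), 3)
        y = np.where(x < true_bp, 0.0, -1.016 * (x - true_bp))
        bp = st.fit_breakpoint(x, y, ci_bootstrap_reps=0)
        assert abs(bp.breakpoint - true_bp) <= 0.1 + 1e-9

    def test_segment_slopes_noiseless(self):
        x = np.arange(28.0, 42.01, 0.05)
        y = np.where(x < 36.1, 0.0, -1.016 * (x - 36.1))
        bp = st.fit_breakpoint(x, y, ci_bootstrap_reps=50, seed=0)
        assert bp.breakpoint == pytest.approx(36.1, abs=0.05)
        assert bp.below.params["x"] == pytest.approx(0.0, abs=1e-8)
        assert bp.above.params["x"] == pytest.approx(-1.016, abs=1e-6)
        assert bp.ci_lower <= bp.breakpoint <= bp.ci_upper

    def test_pure_linear_data_flagged_uninformative(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0.0, 10.0, 120)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 120)
        bp = st.fit_breakpoint(x, y, ci_bootstrap_reps=300, seed=1)
        assert bp.uninformative

    def test_too_few_points(self):
        with pytest.raises(InvalidInputError):
            st.fit_breakpoint(np.arange(10.0), np.arange(10.0))


class TestPower:
    def test_large_effect_saturates(self):
        est = st.estimate_power(1.5, n=70, reps=200, seed=3)
        assert est.power > 0.99

    def test_mc_error_reported(self):
        est = st.estimate_power(0.3, n=70, reps=400, seed=4)
        assert 0.0 <= est.mc_se <= 0.03

    def test_argument_validation(self):
        with pytest.raises(InvalidInputError):
            st.estimate_power(0.1, n=70, reps=10)
        with pytest.raises(InvalidInputError):
            st.estimate_power(0.1, n=70, term="quadratic")
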