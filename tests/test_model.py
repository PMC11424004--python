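import math

import numpy as np
import pytest

from hmbfit import (
    HMBParameters,
    OptimizerConfig,
    RateDataset,
    aic,
    enumerate_variants,
    fit_all,
    fit_variant,
    loglik_from_rss,
    loglog_slope,
    objective,
    predict_rate,
)
from hmbfit.errors import FitFailureError, ValidationError
from hmbfit.model import VARIANT_LABELS, denoised_prediction, get_variant


class TestPrediction:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            ((2.0, -1.0, 0.0), 1.0, 1.0),
            ((2.0, -1.0, 0.0), 0.5, 3.5),
            ((0.0, 0.0, 0.4), 17.3, 0.4),
        ],
    )
    def test_worked_examples(self, params, t, expected):
        assert predict_rate(HMBParameters(*params), t) == pytest.approx(expected)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            predict_rate(HMBParameters(1, 0, 0), 0.0)

    def test_negative_h_rejected(self):
        with pytest.raises(ValidationError):
            HMBParameters(-0.1, 0.0, 0.0)

    def test_denoised_drops_hyperbolic_term(self):
        p = HMBParameters(2.0, -1.0, 0.0)
        assert denoised_prediction(p, 1.0) == pytest.approx(-1.0)
        assert denoised_prediction(HMBParameters(5.0, 0.0, 0.3), 9.0) == pytest.approx(0.3)
        p0 = HMBParameters(0.0, 0.2, 0.1)
        t = np.array([0.5, 2.0, 7.0])
        assert np.allclose(denoised_prediction(p0, t), predict_rate(p0, t))


class TestObjectiveAndLikelihood:
    def test_perfect_fit_rss_zero(self, log_times):
        true = HMBParameters(1.0, 0.01, 0.5)
        ds = RateDataset(time=log_times, rate=predict_rate(true, log_times))
        assert objective(true, ds) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_log(self):
        ds = RateDataset(time=np.array([1.0]), rate=np.array([math.e]), transform="log")
        assert objective(HMBParameters(0.0, 0.0, 1.0), ds) == pytest.approx(1.0)

    def test_out_of_domain_prediction_is_infeasible(self):
        ds = RateDataset(time=np.array([1.0, 10.0]), rate=np.array([1.0, 1.0]))
        # at t=10 prediction is 0.1 - 0.05*10 < 0: outside the log domain
        assert objective(HMBParameters(0.1, -0.05, 0.0), ds) == math.inf

    @pytest.mark.parametrize(
        "rss, n, expected",
        [
            (10.0, 10, 0.0),
            (5 * math.e**2, 5, -5.0),
            (4.0, 2, -0.5 * 2 * math.log(2.0)),
        ],
    )
    def test_loglik_from_rss(self, rss, n, expected):
        assert loglik_from_rss(rss, n) == pytest.approx(expected)

    def test_loglik_invalid_n(self):
        with pytest.raises(ValidationError):
            loglik_from_rss(1.0, 0)

    def test_aic(self):
        assert aic(0.0, 3) == 6.0
        assert aic(-10.0, 1) == 22.0
        assert aic(-3.0, 3) - aic(-3.0, 2) == pytest.approx(2.0)


class TestVariants:
    def test_seven_variants(self):
        variants = enumerate_variants()
        assert len(variants) == 7
        labels = {v.label for v in variants}
        assert {"hmb", "00b"} <= labels
        assert labels == set(VARIANT_LABELS)
        assert all(1 <= v.k <= 3 for v in variants)

    def test_fixed_parameters_are_zero(self, lognormal_dataset, fast_config):
        fit = fit_variant(lognormal_dataset, "0m0", config=fast_config)
        assert fit.params.h == 0.0 and fit.params.b == 0.0


class TestFitting:
    def test_constant_recovery(self, constant_rate_dataset, fast_config):
        fit = fit_variant(constant_rate_dataset, "00b", config=fast_config)
        assert fit.params.b == pytest.approx(0.4, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-15)

    def test_full_model_recovery(self, log_times, fast_config):
        true = HMBParameters(1.0, 0.01, 0.5)
        ds = RateDataset(time=log_times, rate=predict_rate(true, log_times))
        fit = fit_variant(ds, "hmb", config=fast_config, seed=3)
        assert fit.params.h == pytest.approx(true.h, rel=1e-4)
        assert fit.params.m == pytest.approx(true.m, rel=1e-3)
        assert fit.params.b == pytest.approx(true.b, rel=1e-4)

    @pytest.mark.parametrize(
        "label, true",
        [
            ("h00", (0.8, 0.0, 0.0)),
            ("0m0", (0.0, 0.02, 0.0)),
            ("00b", (0.0, 0.0, 0.35)),
            ("h0b", (0.5, 0.0, 0.2)),
            ("0mb", (0.0, 0.015, 0.3)),
            ("hm0", (0.6, 0.012, 0.0)),
            ("hmb", (0.7, 0.008, 0.25)),
        ],
    )
    def test_near_noiseless_recovery_three_sig_figs(self, label, true, fast_config):
        rng = np.random.default_rng(5)
        t = np.geomspace(0.1, 50.0, 100)
        params = HMBParameters(*true)
        rate = np.asarray(predict_rate(params, t)) * np.exp(rng.normal(0, 1e-6, t.size))
        ds = RateDataset(time=t, rate=rate)
        fit = fit_variant(ds, label, config=fast_config, seed=1)
        for name in "hmb":
            want = getattr(params, name)
            got = getattr(fit.params, name)
            if want != 0.0:
                assert got == pytest.approx(want, rel=1e-3)

    def test_one_parameter_grid_oracle(self, lognormal_dataset, fast_config):
        """The optimizer matches a dense 1-D grid search on each
        single-parameter variant."""
        ds = lognormal_dataset
        for label, grid in [
            ("00b", np.linspace(0.01, 2.0, 20001)),
            ("h00", np.linspace(0.01, 20.0, 20001)),
        ]:
            fit = fit_variant(ds, label, config=fast_config)
            idx = "hmb".index(label.strip("0"))
            best_grid = math.inf
            for v in grid:
                theta = [0.0, 0.0, 0.0]
                theta[idx] = v
                best_grid = min(best_grid, objective(HMBParameters(*theta), ds))
            assert fit.rss <= best_grid * (1 + 1e-6)

    def test_nesting_full_model_never_worse(self, noise_over_time_dataset, fast_config):
        sel = fit_all(noise_over_time_dataset, config=fast_config, seed=2)
        by_label = {f.variant.label: f for f in sel.fits}
        full_rss = by_label["hmb"].rss
        for label, fit in by_label.items():
            assert full_rss <= fit.rss * (1 + 1e-8), label

    def test_fit_all_shape_and_ranking(self, constant_rate_dataset, fast_config):
        sel = fit_all(constant_rate_dataset, config=fast_config)
        assert len(sel.fits) == 7
        aics = [f.aic for f in sel.fits]
        assert aics == sorted(aics)
        assert sel.best.aic == min(aics)
        # constant data: a variant with no time-dependence is competitive
        near = {f.variant.label for f in sel.within(2.0)}
        assert "00b" in near

    def test_seeded_determinism(self, lognormal_dataset, fast_config):
        a = fit_variant(lognormal_dataset, "hmb", config=fast_config, seed=11)
        b = fit_variant(lognormal_dataset, "hmb", config=fast_config, seed=11)
        assert a.params == b.params and a.rss == b.rss

    def test_log_rss_objective_same_argmin(self, lognormal_dataset):
        plain = fit_variant(lognormal_dataset, "h0b", config=OptimizerConfig.fast())
        logged = fit_variant(
            lognormal_dataset,
            "h0b",
            config=OptimizerConfig(
                n_random=4, methods=("nelder-mead", "powell"), log_objective=True
            ),
        )
        assert logged.rss == pytest.approx(plain.rss, rel=1e-6)

    def test_all_starts_infeasible_raises(self):
        # a zero bound pins h at 0, so the h-only model predicts 0
        # everywhere: outside the log transform's domain at every start
        ds = RateDataset(time=np.array([1.0, 2.0]), rate=np.array([0.5, 0.5]))
        bad = OptimizerConfig(n_random=0, methods=("nelder-mead",), bound=0.0)
        with pytest.raises(FitFailureError, match="h00"):
            fit_variant(ds, get_variant("h00"), config=bad)


class TestLogLogSlope:
    def test_constant_numerator_slope_minus_one(self):
        t = np.geomspace(0.05, 80.0, 37)
        ds = RateDataset(time=t, rate=3.7 / t, numerator=np.full_like(t, 3.7))
        assert loglog_slope(ds).slope == pytest.approx(-1.0, abs=1e-12)

    def test_constant_rate_slope_zero(self, constant_rate_dataset):
        assert loglog_slope(constant_rate_dataset).slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_rate_slope_plus_one(self):
        t = np.geomspace(0.1, 50.0, 25)
        ds = RateDataset(time=t, rate=0.03 * t)
        assert loglog_slope(ds).slope == pytest.approx(1.0, abs=1e-12)

    def test_zero_rates_need_log1p(self):
        ds = RateDataset(time=np.array([1.0, 2.0]), rate=np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            loglog_slope(ds)
        assert np.isfinite(loglog_slope(ds, transform="log1p").slope)
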