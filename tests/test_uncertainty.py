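import numpy as np
import pytest

from hmbfit import (
    HMBParameters,
    RateDataset,
    contribution_bands,
    decompose,
    fit_variant,
    parameter_bounds,
    rim_threshold,
    sample_region,
)
from hmbfit.errors import DegenerateFitError, UndefinedStatisticError, ValidationError
from hmbfit.uncertainty import ConfidenceRegion


class TestRimThreshold:
    def test_single_parameter_95(self):
        assert rim_threshold(1, 0.95) == pytest.approx(1.92, abs=0.005)

    def test_two_parameter_95(self):
        assert rim_threshold(2, 0.95) == pytest.approx(2.9957, abs=1e-3)

    def test_monotone_in_df(self):
        values = [rim_threshold(k, 0.95) for k in (1, 2, 3, 5)]
        assert values == sorted(values)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            rim_threshold(0, 0.95)
        with pytest.raises(ValidationError):
            rim_threshold(1, 1.0)


class TestDecompose:
    def test_worked_examples(self):
        p = HMBParameters(2.0, -1.0, 0.0)
        assert decompose(p, 1.0)[1] == pytest.approx(1.0 / 3.0)
        assert decompose(p, 0.5)[1] == pytest.approx(1.0 / 9.0)

    def test_constant_only(self):
        assert np.allclose(decompose(HMBParameters(0, 0, 1.0), 7.3), [0, 0, 1])

    def test_normalization_everywhere(self):
        rng = np.random.default_rng(0)
        t = np.geomspace(0.01, 100, 50)
        for _ in range(20):
            p = HMBParameters(rng.uniform(0, 2), rng.uniform(-1, 1), rng.uniform(-1, 1))
            if p.h == 0 and p.m == 0 and p.b == 0:
                continue
            shares = decompose(p, t)
            assert np.allclose(shares.sum(axis=1), 1.0)
            assert np.all((shares >= 0) & (shares <= 1))

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            decompose(HMBParameters(0.0, 0.0, 0.0), 1.0)


@pytest.fixture()
def fitted_constant(lognormal_dataset, fast_config):
    return fit_variant(lognormal_dataset, "00b", config=fast_config)


class TestSampleRegion:
    def test_inside_labels_and_determinism(self, fitted_constant, lognormal_dataset):
        region = sample_region(fitted_constant, lognormal_dataset, n_steps=300, seed=4)
        # labels are consistent with the threshold by construction
        ref = region.logliks >= fitted_constant.loglik - region.threshold
        assert np.array_equal(ref, region.inside_mask)
        assert region.n_inside >= 2
        again = sample_region(fitted_constant, lognormal_dataset, n_steps=300, seed=4)
        assert np.array_equal(region.samples, again.samples)

    def test_degenerate_fit_rejected(self, constant_rate_dataset, fast_config):
        fit = fit_variant(constant_rate_dataset, "00b", config=fast_config)
        with pytest.raises(DegenerateFitError):
            sample_region(fit, constant_rate_dataset, n_steps=200)

    def test_min_steps_enforced(self, fitted_constant, lognormal_dataset):
        with pytest.raises(ValidationError):
            sample_region(fitted_constant, lognormal_dataset, n_steps=50)

    def test_single_parameter_bound_matches_analytic(
        self, fitted_constant, lognormal_dataset
    ):
        """For the constant-rate model under a log transform the profile
        likelihood in ln(b) is exactly quadratic, so the rim crossing is
        available in closed form."""
        ds = lognormal_dataset
        y = np.log(ds.rate)
        n = y.size
        chat = y.mean()
        rss0 = float(((y - chat) ** 2).sum())
        thr = rim_threshold(1, 0.95)
        delta = np.sqrt(rss0 * (np.exp(2 * thr / n) - 1.0) / n)
        lo_true, hi_true = np.exp(chat - delta), np.exp(chat + delta)

        region = sample_region(fitted_constant, ds, n_steps=2000, seed=9)
        lo, hi = parameter_bounds(region)[2]
        assert lo == pytest.approx(lo_true, rel=0.02)
        assert hi == pytest.approx(hi_true, rel=0.02)


class TestParameterBounds:
    def test_box_contains_mle_and_matches_grid_oracle(
        self, fitted_constant, lognormal_dataset
    ):
        from hmbfit.uncertainty import _loglik_at

        region = sample_region(fitted_constant, lognormal_dataset, n_steps=1500, seed=2)
        bounds = parameter_bounds(region)
        b_hat = fitted_constant.params.b
        assert bounds[2, 0] <= b_hat <= bounds[2, 1]
        # dense scan of the same 1-D surface
        grid = np.linspace(b_hat * 0.5, b_hat * 1.5, 4001)
        lls = np.array(
            [_loglik_at(np.array([0.0, 0.0, b]), lognormal_dataset) for b in grid]
        )
        inside = grid[lls >= fitted_constant.loglik - region.threshold]
        step = grid[1] - grid[0]
        assert bounds[2, 0] == pytest.approx(inside.min(), abs=4 * step, rel=0.02)
        assert bounds[2, 1] == pytest.approx(inside.max(), abs=4 * step, rel=0.02)

    def test_zero_width_box_single_point(self, fitted_constant):
        params = fitted_constant.params.as_array()
        region = ConfidenceRegion(
            samples=np.array([params]),
            logliks=np.array([fitted_constant.loglik]),
            inside_mask=np.array([True]),
            threshold=1.92,
            best=fitted_constant,
        )
        bounds = parameter_bounds(region)
        assert bounds[2, 0] == bounds[2, 1] == params[2]


class TestContributionBands:
    def test_zero_width_box_collapses_to_point(self, fitted_constant):
        params = fitted_constant.params.as_array()
        region = ConfidenceRegion(
            samples=np.array([params]),
            logliks=np.array([fitted_constant.loglik]),
            inside_mask=np.array([True]),
            threshold=1.92,
            best=fitted_constant,
        )
        times = np.geomspace(0.1, 50, 20)
        profile = contribution_bands(region, times)
        assert np.allclose(profile.band_min, profile.point)
        assert np.allclose(profile.band_max, profile.point)

    def test_point_estimate_within_bands(self, lognormal_dataset, fast_config):
        fit = fit_variant(lognormal_dataset, "hmb", config=fast_config, seed=1)
        region = sample_region(fit, lognormal_dataset, n_steps=1200, seed=3)
        times = np.geomspace(0.1, 50, 30)
        profile = contribution_bands(region, times)
        assert np.all(profile.band_min <= profile.point + 1e-12)
        assert np.all(profile.point <= profile.band_max + 1e-12)
        # the full model evaluates all 8 box corners: bands are genuinely
        # wider than the point estimate somewhere
        assert np.any(profile.band_max - profile.band_min > 1e-6)

    def test_vertex_bands_bound_dense_sweep_on_monotone_box(self):
        """When the box stays on one side of zero in every coordinate,
        each share is monotone per-parameter, so the 8 vertices attain
        the extremes and a dense interior sweep can never escape them."""
        from hmbfit.model import ModelFit, get_variant

        lo = np.array([0.5, 0.010, 0.20])
        hi = np.array([1.0, 0.020, 0.30])
        center = HMBParameters(*(0.5 * (lo + hi)))
        best = ModelFit(
            variant=get_variant("hmb"), params=center, rss=1.0, n=10, transform="log"
        )
        corners = np.array(
            [[lo[0], lo[1], lo[2]], [hi[0], hi[1], hi[2]]]
            + [
                [b[0], b[1], b[2]]
                for b in np.stack(np.meshgrid(*zip(lo, hi)), axis=-1).reshape(-1, 3)
            ]
        )
        samples = np.vstack([center.as_array(), corners])
        region = ConfidenceRegion(
            samples=samples,
            logliks=np.zeros(len(samples)),
            inside_mask=np.ones(len(samples), dtype=bool),
            threshold=1.92,
            best=best,
        )
        times = np.geomspace(0.1, 50, 25)
        profile = contribution_bands(region, times)
        rng = np.random.default_rng(0)
        for _ in range(200):
            theta = lo + rng.uniform(size=3) * (hi - lo)
            shares = decompose(HMBParameters(*theta), times)
            assert np.all(shares >= profile.band_min - 1e-9)
            assert np.all(shares <= profile.band_max + 1e-9)
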