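"""Skew-normal prior fitting from point + bounds judgments."""

import json

import numpy as np
import pytest
from scipy import stats

from elicitlgm import (
    BoundJudgment,
    SkewNormalPrior,
    band_for_trajectory,
    credible_interval,
    fit_skew_normal,
)
from elicitlgm.skewnorm import FitError


class TestFit:
    def test_symmetric_bounds_give_a_symmetric_normal(self):
        prior = fit_skew_normal(BoundJudgment(30.0, 20.0, 40.0))
        assert prior.shape == 0.0
        assert prior.location == pytest.approx(30.0, abs=1e-8)
        assert prior.cdf(20.0) == pytest.approx(0.01, abs=1e-4)
        assert prior.cdf(40.0) == pytest.approx(0.99, abs=1e-4)

    def test_symmetric_95_coverage_reduces_to_known_normal_scale(self):
        # 97.5% standard-normal quantile is 1.95996; omega = 1 / 1.95996
        prior = fit_skew_normal(
            BoundJudgment(0.0, -1.0, 1.0, coverage=0.95), instrument_range=None
        )
        assert prior.shape == 0.0
        assert prior.scale == pytest.approx(1.0 / 1.959964, rel=1e-5)

    def test_right_shifted_bounds_give_positive_skew_hitting_both_tails(self):
        prior = fit_skew_normal(BoundJudgment(30.0, 25.0, 45.0))
        assert prior.shape > 0
        assert prior.cdf(25.0) == pytest.approx(0.01, abs=1e-4)
        assert prior.cdf(45.0) == pytest.approx(0.99, abs=1e-4)
        assert prior.mode() == pytest.approx(30.0, abs=1e-3 * 20.0)

    def test_judgment_invariants_are_enforced(self):
        with pytest.raises(ValueError, match="lower < upper"):
            BoundJudgment(30.0, 40.0, 20.0)
        with pytest.raises(ValueError, match="inside"):
            BoundJudgment(50.0, 20.0, 40.0)
        with pytest.raises(ValueError, match="coverage"):
            BoundJudgment(30.0, 20.0, 40.0, coverage=1.5)

    def test_infeasible_asymmetry_raises_with_residuals(self):
        # mode essentially on top of the lower bound: beyond any skew normal
        with pytest.raises(FitError, match="shape"):
            fit_skew_normal(BoundJudgment(20.005, 20.0, 40.0), instrument_range=None)

    def test_mass_outside_instrument_range_warns(self):
        with pytest.warns(UserWarning, match="outside the instrument range"):
            fit_skew_normal(BoundJudgment(5.0, -30.0, 20.0))

    @pytest.mark.parametrize("width", [10.0, 20.0, 40.0, 80.0])
    def test_wider_bounds_never_shrink_the_scale(self, width):
        narrow = fit_skew_normal(
            BoundJudgment(50.0, 50.0 - width / 2, 50.0 + width / 2), instrument_range=None
        )
        wide = fit_skew_normal(
            BoundJudgment(50.0, 50.0 - width, 50.0 + width), instrument_range=None
        )
        assert wide.scale >= narrow.scale

    @pytest.mark.parametrize(
        "point, lower, upper", [(30.0, 25.0, 45.0), (10.0, 2.0, 15.0), (0.0, -3.0, 12.0)]
    )
    def test_reflection_symmetry(self, point, lower, upper):
        right = fit_skew_normal(BoundJudgment(point, lower, upper), instrument_range=None)
        left = fit_skew_normal(BoundJudgment(-point, -upper, -lower), instrument_range=None)
        assert left.shape == pytest.approx(-right.shape, abs=1e-3)


class TestDistribution:
    def test_shape_zero_density_equals_normal(self):
        prior = SkewNormalPrior(12.0, 3.0, 0.0)
        x = np.linspace(0, 25, 41)
        np.testing.assert_allclose(prior.pdf(x), stats.norm.pdf(x, 12.0, 3.0), atol=1e-10)

    def test_density_integrates_to_one(self):
        prior = SkewNormalPrior(10.0, 5.0, 4.0)
        from scipy.integrate import quad

        total, _ = quad(prior.pdf, -60, 80)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("p", [0.005, 0.01, 0.025, 0.5, 0.975, 0.99, 0.995])
    def test_quantile_cdf_round_trip(self, p):
        prior = SkewNormalPrior(22.0, 7.5, -2.5)
        assert prior.cdf(prior.ppf(p)) == pytest.approx(p, abs=1e-8)

    def test_seeded_sampling_matches_analytic_mean(self):
        prior = SkewNormalPrior(10.0, 4.0, 3.0)
        rng = np.random.default_rng(1234)
        draws = prior.rvs(1_000_000, rng)
        delta = 3.0 / np.sqrt(10.0)
        analytic = 10.0 + 4.0 * delta * np.sqrt(2.0 / np.pi)
        sd = 4.0 * np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
        assert abs(draws.mean() - analytic) < 4.0 * sd / 1000.0

    def test_json_round_trip_is_lossless(self):
        prior = SkewNormalPrior(27.103933250231854, 6.947747170287407, 4.002680170798711,
                                label="expert-1-intercept")
        back = SkewNormalPrior.from_json(prior.to_json())
        assert back == prior
        payload = json.loads(prior.to_json())
        assert payload["family"] == "skew-normal"


class TestCredibleInterval:
    def test_standard_normal_95_interval(self):
        prior = SkewNormalPrior(0.0, 1.0, 0.0)
        lo, hi = credible_interval(prior, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_interval_mass_equals_level_by_definition(self):
        prior = SkewNormalPrior(5.0, 2.0, 6.0)
        lo, hi = credible_interval(prior, 0.8)
        assert prior.cdf(hi) - prior.cdf(lo) == pytest.approx(0.8, abs=1e-8)

    @pytest.mark.parametrize("level", [0.0, 1.0, 1.4, -0.2])
    def test_degenerate_levels_are_rejected(self, level):
        with pytest.raises(ValueError, match="level"):
            credible_interval(SkewNormalPrior(0.0, 1.0, 0.0), level)


class TestTrajectoryBand:
    def test_intercept_only_band_is_constant_at_the_credible_interval(self):
        prior = SkewNormalPrior(30.0, 5.0, 1.5)
        lo, hi = credible_interval(prior, 0.95)
        band = band_for_trajectory(prior, None, [0.0, 0.25, 1.0])
        for lam, blo, bhi in band:
            assert (blo, bhi) == (lo, hi)

    def test_band_at_zero_loading_matches_intercept_only(self):
        icpt = SkewNormalPrior(30.0, 5.0, 0.0)
        slope = SkewNormalPrior(-10.0, 4.0, 2.0)
        (lam0, lo2, hi2), *_ = band_for_trajectory(icpt, slope, [0.0], seed=3)
        lo1, hi1 = credible_interval(icpt, 0.95)
        assert lo2 == pytest.approx(lo1, abs=0.1)
        assert hi2 == pytest.approx(hi1, abs=0.1)

    def test_two_normal_band_matches_closed_form_sum(self):
        # I ~ N(30, 2²), S ~ N(-10, 3²) independent: I + S ~ N(20, 13)
        icpt = SkewNormalPrior(30.0, 2.0, 0.0)
        slope = SkewNormalPrior(-10.0, 3.0, 0.0)
        (_, lo, hi), = band_for_trajectory(icpt, slope, [1.0], level=0.95, seed=11)
        half = 1.959964 * np.sqrt(13.0)
        assert lo == pytest.approx(20.0 - half, abs=0.15)
        assert hi == pytest.approx(20.0 + half, abs=0.15)

    def test_invalid_level_and_loadings_rejected(self):
        p = SkewNormalPrior(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            band_for_trajectory(p, None, [0.5], level=1.0)
        with pytest.raises(ValueError):
            band_for_trajectory(p, None, [1.5])
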