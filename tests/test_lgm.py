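"""Bayesian latent growth curve model: specs, likelihood, and posterior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import elicitlgm as el
from elicitlgm.densities import HalfT, Normal, Uniform
from elicitlgm.lgm import (
    _fast_logpdf,
    _LogPosterior,
    MCMCConfig,
    PARAM_NAMES,
    ScoreDataset,
    default_benchmark_spec,
)


class TestBenchmarkSpecs:
    def test_benchmark1_mean_priors_encode_the_instrument(self):
        spec = default_benchmark_spec("benchmark1")
        assert spec.prior_alpha1.support == (0.0, 100.0)
        assert spec.prior_alpha2.support == (-100.0, 100.0)

    def test_benchmark2_mean_priors_are_near_flat_normals(self):
        spec = default_benchmark_spec("benchmark2")
        for prior in (spec.prior_alpha1, spec.prior_alpha2):
            assert isinstance(prior, Normal)
            assert prior.mean == 0.0
            assert prior.variance == 1e8

    def test_benchmarks_share_variance_and_correlation_priors(self):
        b1 = default_benchmark_spec("benchmark1")
        b2 = default_benchmark_spec("benchmark2")
        assert b1.prior_psi11 == b2.prior_psi11 == HalfT(3.0, 196.0)
        assert b1.prior_psi22 == b2.prior_psi22
        assert b1.prior_theta == b2.prior_theta
        assert b1.prior_psi21 == b2.prior_psi21 == Uniform(-1.0, 1.0)

    def test_unknown_benchmark_is_rejected(self):
        with pytest.raises(ValueError, match="unknown benchmark"):
            default_benchmark_spec("benchmark3")

    def test_loadings_must_start_at_zero_and_end_at_one(self):
        with pytest.raises(ValueError, match="loadings"):
            el.LGMSpec(loadings=(0.0, 0.25, 0.9))

    def test_correlation_prior_support_must_be_within_unit_interval(self):
        with pytest.raises(ValueError, match="correlation"):
            el.LGMSpec(prior_psi21=Uniform(-2.0, 2.0))

    def test_benchmark1_prior_draws_stay_in_instrument_range(self):
        spec = default_benchmark_spec("benchmark1")
        rng = np.random.default_rng(5)
        draws = spec.prior_alpha1.rvs(10_000, rng)
        assert draws.min() >= 0.0 and draws.max() <= 100.0


class TestScoreDataset:
    def test_from_dataframe_round_trip(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "t1": [30.0, 40.0], "t2": [25.0, 35.0], "t3": [20.0, 30.0]}
        )
        ds = ScoreDataset.from_dataframe(df)
        assert ds.n_subjects == 2 and ds.n_waves == 3
        pd.testing.assert_frame_equal(ds.to_dataframe(), df)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="0, 100"):
            ScoreDataset(np.array([[10.0, 20.0, 120.0]]))

    def test_listwise_deletion_of_incomplete_cases(self):
        scores = np.array([[10.0, 20.0, 30.0], [np.nan, 20.0, 30.0]])
        ds = ScoreDataset(scores)
        assert ds.n_subjects == 1

    def test_degenerate_zero_variance_data_is_an_error(self):
        scores = np.tile([30.0, 30.0, 30.0], (10, 1))
        with pytest.raises(ValueError, match="degenerate"):
            el.LatentGrowthModel(scores)


class TestLogPosterior:
    """The sufficient-statistic likelihood must match a direct MVN evaluation."""

    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(0)
        return ScoreDataset(np.clip(rng.normal(25, 8, size=(17, 3)), 0, 100))

    def test_likelihood_matches_scipy_multivariate_normal(self, data):
        spec = default_benchmark_spec("benchmark2")
        lp = _LogPosterior(data, spec)
        params = np.array([24.0, -8.0, 50.0, 40.0, -0.2, 30.0])
        lam = np.asarray(spec.loadings)
        L = np.column_stack([np.ones_like(lam), lam])
        psi21 = params[4] * np.sqrt(params[2] * params[3])
        Psi = np.array([[params[2], psi21], [psi21, params[3]]])
        Sigma = L @ Psi @ L.T + params[5] * np.eye(3)
        mu = L @ params[:2]
        direct = stats.multivariate_normal(mu, Sigma).logpdf(data.scores).sum()
        expected = direct + spec.log_prior(params)
        assert lp(params) == pytest.approx(expected, rel=1e-10)

    def test_fast_prior_path_matches_generic_logpdf(self, data):
        spec = default_benchmark_spec("benchmark1")
        lp = _LogPosterior(data, spec)
        rng = np.random.default_rng(3)
        for _ in range(25):
            params = np.array(
                [rng.uniform(0, 100), rng.uniform(-100, 100), rng.uniform(1, 300),
                 rng.uniform(1, 300), rng.uniform(-0.99, 0.99), rng.uniform(1, 300)]
            )
            assert lp.log_prior(params) == pytest.approx(spec.log_prior(params), rel=1e-12)

    def test_fast_logpdf_closures_match_scipy(self):
        xs = np.linspace(0.5, 400.0, 23)
        for prior in (Normal(0.0, 1e8), Uniform(-100, 100), HalfT(3.0, 196.0)):
            f = _fast_logpdf(prior)
            for x in xs:
                assert f(x) == pytest.approx(float(prior.logpdf(x)), rel=1e-12)

    def test_out_of_support_parameters_get_minus_infinity(self, data):
        lp = _LogPosterior(data, default_benchmark_spec("benchmark1"))
        assert lp(np.array([150.0, 0.0, 50.0, 50.0, 0.0, 50.0])) == -np.inf
        assert lp(np.array([50.0, 0.0, -1.0, 50.0, 0.0, 50.0])) == -np.inf
        assert lp(np.array([50.0, 0.0, 50.0, 50.0, 1.5, 50.0])) == -np.inf


class TestFit:
    def test_posterior_recovers_simulation_truth(self, truth, ref_fit):
        """Posterior means land within 3 posterior SDs of the generating values."""
        for name, true_val in (("alpha1", truth.alpha1), ("alpha2", truth.alpha2)):
            mean = ref_fit.posterior_mean(name)
            sd = ref_fit.posterior_sd(name)
            assert abs(mean - true_val) < 3.0 * sd

    def test_diagnostics_are_recorded_for_every_parameter(self, ref_fit):
        assert set(ref_fit.rhat) == set(PARAM_NAMES)
        assert set(ref_fit.ess) == set(PARAM_NAMES)
        assert ref_fit.converged
        summary = ref_fit.summarize()
        assert all(v > 0 for v in summary.variances.values())

    def test_summary_table_mentions_key_parameters(self, ref_fit):
        text = ref_fit.summary()
        for name in PARAM_NAMES:
            assert name in text

    def test_moment_matched_marginal_is_a_normal_density(self, ref_fit):
        marg = ref_fit.marginal("alpha1")
        assert isinstance(marg, Normal)
        assert marg.mean == pytest.approx(ref_fit.posterior_mean("alpha1"))

    def test_fit_is_reproducible_for_fixed_seed(self, sim_data):
        cfg = MCMCConfig(chains=1, walkers=12, warmup=40, draws=40)
        model = el.LatentGrowthModel(sim_data, default_benchmark_spec("benchmark2"))
        a = model.fit(seed=5, config=cfg)
        b = model.fit(seed=5, config=cfg)
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_near_degenerate_data_concentrates_on_the_common_path(self, reduced_mcmc):
        """All subjects on (almost) the same 30 → 20 line pins the latent means."""
        rng = np.random.default_rng(8)
        lam = np.array([0.0, 0.25, 1.0])
        scores = 30.0 - 10.0 * lam + rng.normal(0, 0.1, size=(40, 3))
        res = el.LatentGrowthModel(
            ScoreDataset(scores), default_benchmark_spec("benchmark2")
        ).fit(seed=2, config=reduced_mcmc)
        assert res.posterior_mean("alpha1") == pytest.approx(30.0, abs=1.0)
        assert res.posterior_mean("alpha2") == pytest.approx(-10.0, abs=1.0)

    def test_middle_loading_choice_shifts_means_little(self, sim_data, reduced_mcmc):
        """Sensitivity: 3-month loading 0.25 (3/12) vs 2/11 is sub-SD."""
        res_a = el.LatentGrowthModel(
            sim_data, default_benchmark_spec("benchmark2")
        ).fit(seed=9, config=reduced_mcmc)
        spec_b = el.LGMSpec(
            loadings=(0.0, 2.0 / 11.0, 1.0),
            prior_alpha1=Normal(0.0, 1e8),
            prior_alpha2=Normal(0.0, 1e8),
            name="benchmark2-alt-loading",
        )
        res_b = el.LatentGrowthModel(sim_data, spec_b).fit(seed=9, config=reduced_mcmc)
        for name in ("alpha1", "alpha2"):
            diff = abs(res_a.posterior_mean(name) - res_b.posterior_mean(name))
            assert diff < res_a.posterior_sd(name)
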