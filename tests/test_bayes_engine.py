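"""Sampler, density helpers, convergence diagnostics and LOO machinery."""

import arviz as az
import numpy as np
import pytest
from scipy import stats

from heatfish import bayes_engine as be


class TestDensities:
    def test_student_t_matches_scipy(self, rng):
        x = rng.normal(size=50)
        ours = be.student_t_logpdf(x, 4.7, 1.2, 0.8)
        ref = stats.t.logpdf(x, 4.7, loc=1.2, scale=0.8)
        assert np.allclose(ours, ref, rtol=1e-12)

    def test_half_t_matches_scipy_fold(self):
        x = np.array([0.1, 1.0, 5.0])
        ours = be.half_t_logpdf(x, 3.0, 2.5)
        ref = np.log(2) + stats.t.logpdf(x, 3.0, scale=2.5)
        assert np.allclose(ours, ref)
        assert be.half_t_logpdf(-1.0, 3.0, 2.5) == -np.inf

    def test_gamma_matches_scipy(self):
        x = np.array([0.5, 2.0, 20.0])
        ours = be.gamma_logpdf(x, 2.0, 0.1)
        ref = stats.gamma.logpdf(x, 2.0, scale=10.0)
        assert np.allclose(ours, ref)


class TestCorrelationParametrization:
    @pytest.mark.parametrize("dim", [2, 3, 4])
    def test_cholesky_gives_valid_correlation(self, dim, rng):
        for _ in range(20):
            z = np.tanh(rng.normal(size=dim * (dim - 1) // 2))
            L = be.chol_from_partial_correlations(z, dim)
            C = L @ L.T
            assert np.allclose(np.diag(C), 1.0, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(C) > 0)
            assert np.all(np.abs(C) <= 1 + 1e-12)

    def test_mvn_logpdf_matches_scipy(self, rng):
        sds = np.array([0.5, 2.0])
        L = be.chol_from_partial_correlations(np.array([0.6]), 2)
        cov = np.diag(sds) @ (L @ L.T) @ np.diag(sds)
        u = rng.normal(size=(30, 2))
        ours = be.mvn_zero_mean_logpdf(u, sds, L)
        ref = stats.multivariate_normal.logpdf(u, mean=np.zeros(2), cov=cov)
        assert np.allclose(ours, ref, rtol=1e-10)


def _fake_summary(chains_array, name="x"):
    idata = az.from_dict(
        posterior={name: chains_array},
        log_likelihood={"obs": np.zeros(chains_array.shape + (1,))[:, :, :1]},
    )
    return be.PosteriorSummary(
        idata=idata, config=be.SamplerConfig(), model_name="fake")


class TestConvergence:
    def test_well_mixed_chains_pass(self, rng):
        draws = rng.normal(size=(3, 800))
        report = be.check_convergence(_fake_summary(draws))
        assert report.passed
        assert report.rhat["x"] == pytest.approx(1.0, abs=0.02)

    def test_separated_chains_fail(self, rng):
        draws = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        report = be.check_convergence(_fake_summary(draws))
        assert not report.passed
        assert report.rhat["x"] > 1.5

    def test_every_parameter_listed_once(self, rng):
        idata = az.from_dict(
            posterior={"a": rng.normal(size=(2, 100)),
                       "b": rng.normal(size=(2, 100, 3))},
            log_likelihood={"obs": np.zeros((2, 100, 4))},
        )
        summary = be.PosteriorSummary(
            idata=idata, config=be.SamplerConfig(), model_name="fake")
        report = be.check_convergence(summary)
        assert sorted(report.rhat) == ["a", "b"]

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            be.check_convergence(_fake_summary(rng.normal(size=(1, 100))))


class _NormalMeanModel(be.HierarchicalModel):
    """Tiny normal-location model used as a LOO oracle workbench."""

    name = "normal-mean"
    scalar_names = ("mu", "log_sigma")
    blocks = {}

    def __init__(self, y):
        self.y = np.asarray(y, dtype=float)
        self.n_obs = len(self.y)

    def init_state(self, rng):
        return {"mu": float(np.mean(self.y)) + rng.normal(0, 0.5),
                "log_sigma": float(np.log(np.std(self.y) + 0.1)) + rng.normal(0, 0.2)}

    def loglik_pointwise(self, state):
        return be.normal_logpdf(self.y, state["mu"], np.exp(state["log_sigma"]))

    def logp(self, state):
        lp = be.normal_logpdf(state["mu"], 0.0, 100.0)
        lp += be.half_t_logpdf(np.exp(state["log_sigma"]), 3.0, 10.0)
        lp += state["log_sigma"]
        return float(lp + np.sum(self.loglik_pointwise(state)))

    def block_logp_units(self, name, state):  # pragma: no cover - no blocks
        raise NotImplementedError

    def constrained(self, state):
        return {"mu": state["mu"], "sigma": np.exp(state["log_sigma"])}


class TestSampler:
    def test_same_seed_same_draws(self, rng):
        y = rng.normal(3.0, 1.0, size=40)
        cfg = be.SamplerConfig(chains=2, iterations=600, seed=11)
        a = be.sample_posterior(_NormalMeanModel(y), cfg)
        b = be.sample_posterior(_NormalMeanModel(y), cfg)
        assert np.array_equal(a.draws("mu"), b.draws("mu"))

    def test_posterior_mean_matches_analytic(self, rng):
        y = rng.normal(5.0, 2.0, size=200)
        cfg = be.SamplerConfig(chains=3, iterations=2000, seed=1)
        fit = be.sample_posterior(_NormalMeanModel(y), cfg)
        assert float(fit.median("mu")) == pytest.approx(np.mean(y), abs=0.1)
        assert float(fit.median("sigma")) == pytest.approx(np.std(y), rel=0.1)


class TestLoo:
    def test_model_compared_to_itself_zero_difference(self, rng):
        y = rng.normal(size=30)
        cfg = be.SamplerConfig(chains=2, iterations=800, seed=2)
        fit = be.sample_posterior(_NormalMeanModel(y), cfg)
        res = be.loo_compare({"a": fit, "b": fit})
        assert res.diff[("a", "b")] == pytest.approx(0.0, abs=1e-9)
        assert res.diff[("a", "b")] == -res.diff[("b", "a")]

    def test_mismatched_observations_rejected(self, rng):
        cfg = be.SamplerConfig(chains=2, iterations=400, seed=3)
        fit_a = be.sample_posterior(_NormalMeanModel(rng.normal(size=20)), cfg)
        fit_b = be.sample_posterior(_NormalMeanModel(rng.normal(size=25)), cfg)
        with pytest.raises(ValueError, match="different observation sets"):
            be.loo_compare({"a": fit_a, "b": fit_b})

    def test_psis_loo_matches_exact_refit(self, rng):
        """PSIS-LOO elpd agrees with brute-force leave-one-out refitting
        within one elpd unit on a small instance."""
        y = rng.normal(1.5, 1.0, size=30)
        cfg = be.SamplerConfig(chains=2, iterations=1500, seed=4)
        fit = be.sample_posterior(_NormalMeanModel(y), cfg)
        psis = float(az.loo(fit.idata).elpd_loo)
        exact = 0.0
        for i in range(len(y)):
            y_train = np.delete(y, i)
            refit = be.sample_posterior(
                _NormalMeanModel(y_train),
                be.SamplerConfig(chains=2, iterations=1000, seed=100 + i),
            )
            mu = refit.draws("mu")
            sigma = refit.draws("sigma")
            dens = stats.norm.pdf(y[i], loc=mu, scale=sigma)
            exact += np.log(np.mean(dens))
        assert psis == pytest.approx(exact, abs=1.0)


class TestPredictiveCheck:
    def test_typical_observation_not_extreme(self, rng):
        draws = rng.normal(0, 1, size=2000)
        res = be.predictive_check(draws, 0.1)
        assert 0.5 < res.tail_prob <= 1.0
        assert not res.extreme

    def test_outlying_observation_extreme(self, rng):
        draws = rng.normal(0, 1, size=2000)
        res = be.predictive_check(draws, 8.0)
        assert res.tail_prob < 0.01
        assert res.extreme

    def test_calibration_on_wellspecified_data(self, rng):
        """Mean statistic on data from the model itself is rarely extreme."""
        ok = 0
        for _ in range(25):
            data = rng.normal(size=50)
            rep_means = rng.normal(0, 1 / np.sqrt(50), size=400)
            if 0.05 <= be.predictive_check(rep_means, data.mean()).tail_prob:
                ok += 1
        assert ok >= 20

    def test_heavy_tail_statistic_flagged(self, rng):
        """The max of Student-t data is extreme under a fitted-normal
        predictive for the max (direction sanity check)."""
        data = stats.t.rvs(2.0, size=300, random_state=7)
        rep_max = np.max(
            rng.normal(data.mean(), data.std() / 3, size=(400, 300)), axis=1)
        res = be.predictive_check(rep_max, float(np.max(data)))
        assert res.extreme
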