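import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from pmtdsim.inference import (
    FitSettings,
    ModelParams,
    TrialData,
    fit_posterior,
    log_likelihood,
)
from pmtdsim.priors import BayesianLasso, FlatNormal, PriorSpec, SpikeSlab
from pmtdsim.scenarios import DoseGrid

GRID = DoseGrid((1, 3, 5, 7, 9), 5)
FAST = FitSettings(chains=2, warmup=500, draws=500)
LONG = FitSettings(chains=4, warmup=2000, draws=2000)


def random_data(rng, n, p=0):
    return TrialData(
        rng.integers(0, 5, n),
        rng.standard_normal((n, p)) if p else np.empty((n, 0)),
        rng.integers(0, 2, n),
    )


class TestLogLikelihood:
    def test_half_probability_single_patient(self):
        # at the reference dose p = expit(alpha); alpha = 0 gives p = 1/2
        data = TrialData([2], np.empty((1, 0)), [1])
        params = ModelParams(alpha=0.0, log_beta=0.0)
        assert log_likelihood(params, data, GRID) == pytest.approx(np.log(0.5))

    def test_empty_data(self):
        assert log_likelihood(ModelParams(0, 0), TrialData.empty(), GRID) == 0.0

    def test_brute_force_bernoulli_oracle(self, rng):
        data = random_data(rng, 10, p=2)
        params = ModelParams(0.4, -0.3, (0.8, -1.2))
        expected = 0.0
        for i in range(data.n):
            eta = (
                params.alpha
                + params.beta * np.log(GRID.doses[data.dose_index[i]] / 5)
                + data.covariates[i] @ np.array(params.gamma)
            )
            expected += stats.bernoulli.logpmf(data.outcome[i], expit(eta))
        assert log_likelihood(params, data, GRID) == pytest.approx(expected)

    def test_clamping_warns(self):
        data = TrialData([4], np.empty((1, 0)), [0])
        params = ModelParams(alpha=100.0, log_beta=0.0)
        with pytest.warns(RuntimeWarning):
            ll = log_likelihood(params, data, GRID)
        assert np.isfinite(ll)

    def test_dimension_mismatch(self, rng):
        data = random_data(rng, 5, p=1)
        with pytest.raises(ValueError):
            log_likelihood(ModelParams(0, 0), data, GRID)


class TestFitPosterior:
    def test_no_data_matches_prior_mean(self):
        spec = PriorSpec()
        post = fit_posterior(spec, TrialData.empty(), GRID, engine="quadrature")
        draws = np.random.default_rng(0).multivariate_normal(
            spec.base_mean_arr(), spec.base_cov_arr(), 500_000
        )
        prior_mean = expit(draws[:, 0]).mean()
        assert post.prob(2) == pytest.approx(prior_mean, abs=0.005)
        # prior median of p at the reference dose is 0.1 by construction
        assert expit(spec.base_mean[0]) == pytest.approx(0.1)

    def test_cross_engine_agreement_p0(self, rng):
        spec = PriorSpec()
        for _ in range(3):
            data = random_data(rng, 12)
            q = fit_posterior(spec, data, GRID, engine="quadrature")
            m = fit_posterior(spec, data, GRID, engine="mcmc",
                              settings=LONG, seed=int(rng.integers(2**31)))
            assert np.abs(q.prob_curve() - m.prob_curve()).max() < 0.01

    def test_cross_engine_agreement_p1(self, rng):
        spec = PriorSpec(covariate=FlatNormal(4.0))
        data = random_data(rng, 15, p=1)
        q = fit_posterior(spec, data, GRID, kinds=("normal",), engine="quadrature")
        m = fit_posterior(spec, data, GRID, kinds=("normal",), engine="mcmc",
                          settings=LONG, seed=7)
        for x in ([0.0], [1.0], [-1.3]):
            assert np.abs(q.prob_curve(x) - m.prob_curve(x)).max() < 0.01

    def test_mcmc_deterministic_given_seed(self, rng):
        spec = PriorSpec(covariate=FlatNormal())
        data = random_data(rng, 9, p=2)
        kw = dict(kinds=("normal", "normal"), engine="mcmc", settings=FAST, seed=42)
        a = fit_posterior(spec, data, GRID, **kw)
        b = fit_posterior(spec, data, GRID, **kw)
        assert np.array_equal(a.draws, b.draws)

    def test_ordering_invariance(self, rng):
        spec = PriorSpec()
        data = random_data(rng, 12)
        perm = rng.permutation(12)
        shuffled = TrialData(
            data.dose_index[perm], data.covariates[perm], data.outcome[perm]
        )
        a = fit_posterior(spec, data, GRID, engine="quadrature")
        b = fit_posterior(spec, shuffled, GRID, engine="quadrature")
        assert np.allclose(a.prob_curve(), b.prob_curve(), atol=1e-12)

    def test_extra_dlt_never_decreases_phat(self, rng):
        spec = PriorSpec()
        for _ in range(5):
            data = random_data(rng, 9)
            post = fit_posterior(spec, data, GRID, engine="quadrature")
            more = data.append([2], np.empty((1, 0)), [1])
            post2 = fit_posterior(spec, more, GRID, engine="quadrature")
            assert post2.prob(2) >= post.prob(2) - 1e-9

    def test_quadrature_rejects_many_covariates(self, rng):
        spec = PriorSpec(covariate=FlatNormal())
        data = random_data(rng, 6, p=2)
        with pytest.raises(ValueError):
            fit_posterior(spec, data, GRID, kinds=("normal", "normal"),
                          engine="quadrature")

    def test_kinds_must_align(self, rng):
        with pytest.raises(ValueError):
            fit_posterior(PriorSpec(), random_data(rng, 5, p=1), GRID)


class TestEstimateProb:
    def test_blrm_rejects_covariates(self, rng):
        post = fit_posterior(PriorSpec(), random_data(rng, 6), GRID,
                             engine="quadrature")
        with pytest.raises(ValueError):
            post.prob(2, [1.0])

    def test_average_patient_curve(self, rng):
        spec = PriorSpec(covariate=FlatNormal())
        data = random_data(rng, 12, p=2)
        post = fit_posterior(spec, data, GRID, kinds=("normal", "normal"),
                             engine="mcmc", settings=FAST, seed=3)
        assert np.allclose(
            post.prob_curve([0.0, 0.0]),
            post.prob_matrix(np.zeros((1, 2)))[0],
            atol=1e-12,
        )

    def test_draw_average_oracle(self, rng):
        spec = PriorSpec(covariate=FlatNormal())
        data = random_data(rng, 12, p=1)
        post = fit_posterior(spec, data, GRID, kinds=("normal",),
                             engine="mcmc", settings=FAST, seed=5)
        df = post.export_draws()
        x = 0.8
        for k in range(5):
            manual = expit(
                df["alpha"]
                + np.exp(df["log_beta"]) * np.log(GRID.doses[k] / 5)
                + df["gamma_1"] * x
            ).mean()
            assert post.prob(k, [x]) == pytest.approx(manual, abs=1e-12)

    def test_monotone_in_dose(self, rng):
        post = fit_posterior(PriorSpec(), random_data(rng, 15), GRID,
                             engine="quadrature")
        assert np.all(np.diff(post.prob_curve()) >= 0)


class TestPriorReduction:
    """Shrinkage priors with shrinkage disabled reproduce the flat fits."""

    def test_spike_equals_slab_matches_flat(self, rng):
        data = random_data(rng, 30, p=1)
        flat = fit_posterior(
            PriorSpec(covariate=FlatNormal(4.0)), data, GRID,
            kinds=("normal",), engine="mcmc", settings=LONG, seed=1,
        )
        ss = fit_posterior(
            PriorSpec(covariate=SpikeSlab(spike_variance_continuous=3.999,
                                          slab_variance=4.0)),
            data, GRID, kinds=("normal",), engine="mcmc", settings=LONG, seed=2,
        )
        for x in ([0.0], [1.0]):
            assert np.abs(flat.prob_curve(x) - ss.prob_curve(x)).max() < 0.02

    def test_lasso_weak_penalty_near_flat(self, rng):
        data = random_data(rng, 30, p=1)
        flat = fit_posterior(
            PriorSpec(covariate=FlatNormal(4.0)), data, GRID,
            kinds=("normal",), engine="mcmc", settings=LONG, seed=3,
        )
        lasso = fit_posterior(
            PriorSpec(covariate=BayesianLasso(fixed_lambda=0.05)), data, GRID,
            kinds=("normal",), engine="mcmc", settings=LONG, seed=4,
        )
        for x in ([0.0], [1.0]):
            assert np.abs(flat.prob_curve(x) - lasso.prob_curve(x)).max() < 0.03

    def test_spike_pinned_converges_to_blrm(self, rng):
        # weight pinned to a vanishing spike forces gamma ~ 0
        data = random_data(rng, 24, p=1)
        blrm = fit_posterior(PriorSpec(), data.select_covariates([]), GRID,
                             engine="quadrature")
        pinned = fit_posterior(
            PriorSpec(covariate=SpikeSlab(b1=1.0, b2=100.0,
                                          spike_variance_continuous=1e-4)),
            data, GRID, kinds=("normal",), engine="mcmc",
            settings=LONG, seed=6,
        )
        assert np.abs(blrm.prob_curve() - pinned.prob_curve([0.0])).max() < 0.03


class TestDiagnostics:
    def test_metadata_recorded(self, rng):
        post = fit_posterior(
            PriorSpec(covariate=FlatNormal()), random_data(rng, 9, p=1), GRID,
            kinds=("normal",), engine="mcmc", settings=FAST, seed=11,
        )
        d = post.diagnostics
        assert {"rhat", "accept_rate", "convergence_flag"} <= set(d)
        assert 0 < d["accept_rate"] < 1

    def test_lasso_and_spike_aux_draws(self, rng):
        data = random_data(rng, 12, p=2)
        lasso = fit_posterior(
            PriorSpec(covariate=BayesianLasso()), data, GRID,
            kinds=("normal", "normal"), engine="mcmc", settings=FAST, seed=8,
        )
        assert "lambda_normal" in lasso.aux_draws
        assert np.all(lasso.aux_draws["lambda_normal"] > 0)
        ss = fit_posterior(
            PriorSpec(covariate=SpikeSlab()), data, GRID,
            kinds=("normal", "normal"), engine="mcmc", settings=FAST, seed=9,
        )
        assert {"m_1", "m_2"} <= set(ss.aux_draws)
        for m in (ss.aux_draws["m_1"], ss.aux_draws["m_2"]):
            assert np.all((m >= 0) & (m <= 1))
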