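import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from pmtdsim.scenarios import (
    Covariate,
    CovariateSpec,
    DoseGrid,
    ScenarioTruth,
    calibrate_truth,
    closest_dose,
    emax_prob,
    logistic_prob,
    marginal_prob,
    marginal_probs,
    pmtd_distribution,
    true_pmtd,
)

GRID = DoseGrid((1, 3, 5, 7, 9), 5)
# scenario-3-style coefficients solved from the cells p(d3)=0.24, p(d4)=0.45
S3_ALPHA = float(logit(0.24))
S3_BETA = float((logit(0.45) - logit(0.24)) / np.log(7 / 5))


class TestDoseGrid:
    def test_valid(self):
        g = DoseGrid((1, 2, 4), 2)
        assert g.n_doses == 3
        assert g.log_ratio()[1] == 0.0

    @pytest.mark.parametrize(
        "doses,ref",
        [((3, 2, 1), 2), ((0, 1, 2), 1), ((1, 2), -1), ((), 1)],
    )
    def test_invalid(self, doses, ref):
        with pytest.raises(ValueError):
            DoseGrid(doses, ref)


class TestLogisticProb:
    def test_scenario3_top_dose(self):
        p = logistic_prob((S3_ALPHA, S3_BETA), GRID, 4)
        assert round(p, 2) == 0.62

    def test_reference_dose_is_inv_logit_alpha(self):
        for alpha in (-2.0, 0.0, 1.3):
            assert logistic_prob((alpha, 1.7), GRID, 2) == pytest.approx(
                expit(alpha), abs=1e-12
            )

    def test_zero_gamma_reduces_to_no_covariates(self):
        base = logistic_prob((S3_ALPHA, S3_BETA), GRID, 3)
        with_g = logistic_prob(
            (S3_ALPHA, S3_BETA), GRID, 3, covariates=(1.4, -0.2), gamma=(0, 0)
        )
        assert with_g == pytest.approx(base, abs=1e-15)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            logistic_prob((0, 1), GRID, 0, covariates=(1.0,), gamma=())

    def test_monotone_in_dose_for_positive_beta(self):
        probs = [logistic_prob((-1.0, 2.0), GRID, k) for k in range(5)]
        assert np.all(np.diff(probs) > 0)
        assert all(0 < p < 1 for p in probs)


class TestEmaxProb:
    def test_low_dose_limit(self):
        g = DoseGrid((1e-9, 1, 5), 5)
        assert emax_prob((-2, 3, 5), g, 0) == pytest.approx(expit(-2), abs=1e-6)

    def test_saturation(self):
        g = DoseGrid((1, 5, 1e9), 5)
        assert emax_prob((-2, 3, 5), g, 2) == pytest.approx(expit(1), abs=1e-6)

    def test_direct_formula(self):
        # alpha1=-2, alpha2=3, alpha3=5 at dose 5: logit^-1(-2 + 3*5/10)
        assert emax_prob((-2, 3, 5), GRID, 2) == pytest.approx(
            expit(-0.5), abs=1e-12
        )

    def test_alpha3_domain(self):
        with pytest.raises(ValueError):
            emax_prob((-2, 3, 0), GRID, 2)

    def test_monotone_for_positive_alpha2(self):
        probs = [emax_prob((-2, 3, 5), GRID, k) for k in range(5)]
        assert np.all(np.diff(probs) > 0)


class TestTruePmtd:
    def test_scenario3_mtd(self, nocov_truths):
        assert true_pmtd(nocov_truths["d3"]) == 2

    def test_tie_breaks_to_higher_dose(self):
        assert closest_dose(np.array([0.20, 0.30]), 0.25) == 1

    def test_brute_force_oracle(self, rng):
        for _ in range(1000):
            probs = np.sort(rng.random(5))
            tau = rng.random()
            best = closest_dose(probs, tau)
            # exhaustive scan with explicit upward tie rule
            dist = np.abs(probs - tau)
            expected = max(np.flatnonzero(dist == dist.min()))
            assert best == expected

    def test_random_truths_match_scan(self, rng):
        for _ in range(200):
            truth = ScenarioTruth(
                "logistic", GRID, (rng.normal(), np.exp(rng.normal())),
                (rng.normal(),), CovariateSpec((Covariate.normal(),)),
            )
            x = rng.normal(size=1)
            probs = truth.prob_matrix(x.reshape(1, -1))[0]
            dist = np.abs(probs - truth.tau)
            assert true_pmtd(truth, x) == max(
                np.flatnonzero(dist == dist.min())
            )


class TestMarginalProb:
    def test_gamma_zero_equals_conditional(self, nocov_truths):
        truth = nocov_truths["d3"]
        for k in range(5):
            assert marginal_prob(truth, k) == pytest.approx(
                truth.prob(k), abs=1e-15
            )

    def test_binary_two_point_expectation(self):
        spec = CovariateSpec((Covariate.bernoulli(0.5),))
        truth = ScenarioTruth("logistic", GRID, (S3_ALPHA, S3_BETA), (1.2,), spec)
        expected = 0.5 * truth.prob(3, (0.0,)) + 0.5 * truth.prob(3, (1.0,))
        assert marginal_prob(truth, 3) == pytest.approx(expected, abs=1e-12)

    def test_two_normal_quadrature_vs_monte_carlo(self, two_normal_spec, rng):
        truth = ScenarioTruth(
            "logistic", GRID, (S3_ALPHA, S3_BETA), (0.8, -0.5), two_normal_spec
        )
        n = 400_000
        X = two_normal_spec.sample(n, rng)
        for k in (0, 2, 4):
            draws = truth.prob_matrix(X)[:, k]
            mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(n)
            assert marginal_prob(truth, k) == pytest.approx(mc, abs=3 * se)

    def test_correlated_spec_validation(self):
        with pytest.raises(ValueError):
            CovariateSpec(
                (Covariate.normal(), Covariate.normal()),
                correlation=((1.0, 1.2), (1.2, 1.0)),
            )


class TestCalibration:
    def test_scenario3_reproduces_printed_row(self, marginal_table):
        res = calibrate_truth(marginal_table["scenarios"]["d3"], dose_grid=GRID)
        a = res.achieved
        assert round(a[0], 3) == 0.003
        assert round(a[1], 2) == 0.07
        assert round(a[2], 2) == 0.24
        assert round(a[3], 2) == 0.45
        assert round(a[4], 2) == 0.62

    def test_scenario1_d3_cell(self, marginal_table):
        res = calibrate_truth(marginal_table["scenarios"]["d1"], dose_grid=GRID)
        assert round(res.achieved[2], 2) == 0.46

    def test_gamma_nonzero_roundtrip_vs_mc(self, two_normal_spec, rng):
        targets = (0.003, 0.07, 0.24, 0.45, 0.62)
        res = calibrate_truth(
            targets, gamma=(1.0, 0.7), covariate_spec=two_normal_spec,
            dose_grid=GRID,
        )
        # marginalising over covariates changes the curve shape, so the
        # 5-target least-squares fit is close but not exact
        assert res.max_abs_residual < 0.03
        X = two_normal_spec.sample(300_000, rng)
        pm = res.truth.prob_matrix(X)
        for k, t in enumerate(targets):
            mc = pm[:, k].mean()
            se = pm[:, k].std(ddof=1) / np.sqrt(len(X))
            assert marginal_probs(res.truth)[k] == pytest.approx(mc, abs=4 * se)

    def test_emax_calibration(self):
        targets = (0.05, 0.12, 0.24, 0.36, 0.46)
        res = calibrate_truth(targets, family="emax", dose_grid=GRID)
        assert res.truth.family == "emax"
        assert res.truth.coeffs[2] > 0
        assert res.max_abs_residual < 0.02

    def test_rejects_non_increasing_targets(self):
        with pytest.raises(ValueError):
            calibrate_truth((0.3, 0.2, 0.4, 0.5, 0.6), dose_grid=GRID)


class TestPmtdDistribution:
    def test_point_mass_without_covariates(self, nocov_truths):
        dist = pmtd_distribution(nocov_truths["d4"], n_draws=10)
        assert dist[3] == 1.0 and dist.sum() == 1.0

    def test_sums_to_one_and_seed_stability(self, two_normal_spec):
        truth = ScenarioTruth(
            "logistic", GRID, (S3_ALPHA, S3_BETA), (1.0, 1.0), two_normal_spec
        )
        n = 100_000
        d1 = pmtd_distribution(truth, n_draws=n, seed=1)
        d2 = pmtd_distribution(truth, n_draws=n, seed=2)
        assert d1.sum() == pytest.approx(1.0)
        se = np.sqrt(d1 * (1 - d1) / n)
        assert np.all(np.abs(d1 - d2) <= 3 * np.maximum(se, 1e-3))


@settings(max_examples=50, deadline=None)
@given(
    alpha=st.floats(-4, 2),
    log_beta=st.floats(-1.5, 1.5),
    tau=st.floats(0.05, 0.5),
)
def test_probabilities_in_unit_interval_and_monotone(alpha, log_beta, tau):
    truth = ScenarioTruth(
        "logistic", GRID, (alpha, np.exp(log_beta)), tau=tau
    )
    probs = truth.prob_matrix(np.empty((1, 0)))[0]
    assert np.all((probs > 0) & (probs < 1))
    assert np.all(np.diff(probs) > 0)
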