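"""AFT variable selection: likelihood oracles, prior normalisation,
Laplace accuracy against quadrature, model-space posteriors and PIPs."""

import numpy as np
import pytest
from scipy import integrate, stats

from ghsurv.selection import (
    AFTVariableSelection,
    SelectionPrior,
    aft_loglik,
    aft_loglik_grad,
    compute_pips,
    laplace_log_marginal,
    log_model_prior,
    log_parameter_prior,
    log_tau_prior,
    select_variables,
)
from ghsurv.simulate import selection_benchmark


def small_benchmark(n=30, p=1, beta=1.0, censor=0.3, seed=5):
    return selection_benchmark(n, p, list(range(p)), beta,
                               sigma=1.0, censor_rate=censor, seed=seed)


class TestLoglik:
    def test_single_uncensored_at_origin(self):
        # standard-normal log-density at 0
        val = aft_loglik([0.0], 1.0, [0.0], [1], [[1.0]])
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_single_censored_at_median(self):
        val = aft_loglik([0.0], 1.0, [0.0], [0], [[1.0]])
        assert val == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_direct_parameterisation_oracle(self, rng):
        # events: N(x'beta, sigma^2) log-density; censored: its log-ccdf,
        # with beta = alpha/tau and sigma = 1/tau
        n, p = 10, 2
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        status = rng.integers(0, 2, n)
        alpha = rng.normal(size=p)
        tau = 1.7
        beta, sigma = alpha / tau, 1.0 / tau
        mu = X @ beta
        oracle = sum(
            stats.norm.logpdf(yi, mi, sigma) if d else stats.norm.logsf(yi, mi, sigma)
            for yi, mi, d in zip(y, mu, status)
        )
        assert aft_loglik(alpha, tau, y, status, X) == pytest.approx(oracle, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        n, p = 25, 3
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        status = rng.integers(0, 2, n)
        alpha, tau = rng.normal(size=p), 1.3
        ga, gt = aft_loglik_grad(alpha, tau, y, status, X)
        eps = 1e-6
        for j in range(p):
            da = alpha.copy()
            da[j] += eps
            fd = (aft_loglik(da, tau, y, status, X)
                  - aft_loglik(alpha, tau, y, status, X)) / eps
            assert fd == pytest.approx(ga[j], rel=1e-4, abs=1e-6)
        fd = (aft_loglik(alpha, tau + eps, y, status, X)
              - aft_loglik(alpha, tau, y, status, X)) / eps
        assert fd == pytest.approx(gt, rel=1e-4)

    def test_concavity_chord_property(self, rng):
        # l(mid) >= (l(a)+l(b))/2 for the jointly log-concave likelihood
        n, p = 40, 2
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        status = rng.integers(0, 2, n)
        for _ in range(100):
            a1, a2 = rng.normal(size=p), rng.normal(size=p)
            t1, t2 = rng.uniform(0.3, 3.0, 2)
            mid_a, mid_t = (a1 + a2) / 2, (t1 + t2) / 2
            lo = 0.5 * (aft_loglik(a1, t1, y, status, X)
                        + aft_loglik(a2, t2, y, status, X))
            assert aft_loglik(mid_a, mid_t, y, status, X) >= lo - 1e-9

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            aft_loglik([0.0], 0.0, [0.0], [1], [[1.0]])


class TestPriors:
    def test_tau_prior_normalised(self):
        val, _ = integrate.quad(lambda t: np.exp(log_tau_prior(t, 1.0, 1.0)),
                                0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_tau_prior_normalised_other_hyperparameters(self):
        val, _ = integrate.quad(lambda t: np.exp(log_tau_prior(t, 3.0, 2.0)),
                                0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mom_marginal_normalised(self):
        # (a^2/g) N(a; 0, g) integrates to 1 for the recommended g
        g = 0.192
        prior = SelectionPrior(coefficient_prior="mom", elicitation="fixed", g_M=g)

        def dens(a):
            return np.exp(
                log_parameter_prior([a], 1.0, prior, [10.0], 10)
                - log_tau_prior(1.0, prior.a_tau, prior.b_tau))

        val, _ = integrate.quad(dens, -np.inf, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_mom_vanishes_at_zero(self):
        prior = SelectionPrior(coefficient_prior="mom", elicitation="fixed")
        assert log_parameter_prior([0.0], 1.0, prior, [5.0], 10) == -np.inf

    def test_model_prior_hand_values_p2(self):
        # uniform-on-size Beta-Binomial: 1/3 null, 1/6 each singleton, 1/3 full
        probs = {k: np.exp(log_model_prior(k, 2)) for k in (0, 1, 2)}
        assert probs[0] == pytest.approx(1 / 3, abs=1e-12)
        assert probs[1] == pytest.approx(1 / 6, abs=1e-12)
        assert probs[2] == pytest.approx(1 / 3, abs=1e-12)

    def test_model_prior_symmetric_p1(self):
        assert np.exp(log_model_prior(0, 1)) == pytest.approx(0.5, abs=1e-12)
        assert np.exp(log_model_prior(1, 1)) == pytest.approx(0.5, abs=1e-12)

    def test_model_prior_sums_to_one_p8(self):
        from itertools import product

        total = sum(np.exp(log_model_prior(sum(g), 8))
                    for g in product((0, 1), repeat=8))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLaplace:
    @pytest.mark.parametrize("coefficient_prior", ["zellner", "mom"])
    def test_against_2d_quadrature(self, coefficient_prior):
        data, _ = small_benchmark(n=30, p=1, beta=1.0, seed=7)
        prior = SelectionPrior(coefficient_prior=coefficient_prior,
                               elicitation="fixed")
        X = data.X
        col_ss = np.array([float(X[:, 0] @ X[:, 0])])
        approx = laplace_log_marginal(data.y, data.status, X, prior,
                                      col_ss=col_ss)

        def integrand(a, t):
            return np.exp(
                aft_loglik([a], t, data.y, data.status, X)
                + log_parameter_prior([a], t, prior, col_ss, data.n)
                - approx)

        val, err = integrate.dblquad(integrand, 0.05, 8.0,
                                     lambda t: -6.0, lambda t: 8.0,
                                     epsabs=1e-10, epsrel=1e-8)
        assert abs(np.log(val)) < 0.1  # log-scale gap |approx - quadrature|

    def test_null_model_against_1d_quadrature(self):
        data, _ = small_benchmark(n=30, p=1, seed=7)
        prior = SelectionPrior(coefficient_prior="zellner", elicitation="fixed")
        X0 = np.zeros((data.n, 0))
        approx = laplace_log_marginal(data.y, data.status, X0, prior,
                                      col_ss=np.zeros(0),
                                      start=np.array([1.0]))

        def integrand(t):
            return np.exp(aft_loglik(np.zeros(0), t, data.y, data.status, X0)
                          + log_tau_prior(t, prior.a_tau, prior.b_tau) - approx)

        val, _ = integrate.quad(integrand, 1e-3, 10.0, limit=400)
        assert abs(np.log(val)) < 0.05

    def test_bayes_factor_of_model_against_itself_is_one(self):
        data, _ = small_benchmark(n=40, p=2, beta=[0.8, 0.5], seed=3)
        model = AFTVariableSelection.from_selection_data(data)
        prior = SelectionPrior()
        a = model.log_marginal((1, 0), prior)
        b = model.log_marginal((1, 0), prior)
        assert np.exp(a - b) == pytest.approx(1.0, abs=1e-12)


class TestModelPosterior:
    def test_two_model_closed_form(self):
        # p=1: pi(gamma=1|y) = 1 / (1 + B_{0,1} pi(0)/pi(1))
        data, _ = small_benchmark(n=60, p=1, beta=0.9, seed=2)
        model = AFTVariableSelection.from_selection_data(data)
        prior = SelectionPrior(coefficient_prior="zellner")
        res = model.fit(prior=prior)
        lm1 = model.log_marginal((1,), prior)
        lm0 = model.log_marginal((0,), prior)
        b01 = np.exp(lm0 - lm1)
        expect = 1.0 / (1.0 + b01 * 1.0)  # equal model priors at p=1
        assert res.model_posteriors[(1,)] == pytest.approx(expect, abs=1e-10)

    def test_exhaustive_probabilities_normalised_p8(self):
        data, _ = selection_benchmark(120, 8, [0, 1], [0.8, 0.6], seed=4)
        model = AFTVariableSelection.from_selection_data(data)
        res = model.fit(coefficient_prior="zellner")
        assert sum(res.model_posteriors.values()) == pytest.approx(1.0, abs=1e-10)
        # PIP identity: sum over models containing j
        pips = compute_pips(res.model_posteriors, 8)
        assert np.allclose(pips, res.pips.to_numpy(), atol=1e-12)

    def test_invariance_under_column_permutation(self):
        data, _ = selection_benchmark(100, 4, [0, 2], [0.9, 0.7], seed=9)
        model = AFTVariableSelection.from_selection_data(data)
        res = model.fit(coefficient_prior="mom")
        perm = [2, 0, 3, 1]
        data2 = type(data)(data.y, data.status, data.X[:, perm],
                           [data.names[j] for j in perm])
        res2 = AFTVariableSelection.from_selection_data(data2).fit(
            coefficient_prior="mom")
        assert np.allclose(res.pips.to_numpy()[perm], res2.pips.to_numpy(),
                           atol=1e-8)

    def test_gibbs_pips_match_exhaustive(self):
        data, _ = selection_benchmark(150, 6, [1, 4], [0.9, 0.8], seed=12)
        model = AFTVariableSelection.from_selection_data(data)
        exact = model.fit(coefficient_prior="zellner", method="exhaustive")
        gibbs = model.fit(coefficient_prior="zellner", method="gibbs",
                          gibbs_sweeps=500, gibbs_burn=50, seed=1)
        assert np.allclose(exact.pips.to_numpy(), gibbs.pips.to_numpy(),
                           atol=0.02)

    def test_recovers_active_set_single_replicate(self):
        data, truth = selection_benchmark(
            500, 10, [0, 3, 7], [0.6, 0.5, -0.7], censor_rate=0.3, seed=11)
        model = AFTVariableSelection.from_selection_data(data)
        res = model.fit(coefficient_prior="mom", elicitation="unit_information")
        assert res.selected() == truth


class TestPipRules:
    def test_forced_arithmetic_example(self):
        posts = {(0, 0): 0.1, (1, 0): 0.6, (0, 1): 0.1, (1, 1): 0.2}
        assert compute_pips(posts, 2) == pytest.approx([0.8, 0.3], abs=1e-12)

    def test_absent_variable_has_zero_pip(self):
        posts = {(1, 0): 0.7, (0, 0): 0.3}
        assert compute_pips(posts, 2)[1] == 0.0

    def test_threshold_rule_is_strict(self):
        # reported PIP profile: only the first variable clears 0.5
        assert select_variables([1.00, 0.44, 0.35]) == (1, 0, 0)
        assert select_variables([0.5, 0.5, 0.5]) == (0, 0, 0)
        assert select_variables([0.4, 0.0, 0.2], threshold=0.0) == (1, 0, 1)

    def test_invalid_pips_rejected(self):
        with pytest.raises(ValueError):
            select_variables([1.2, 0.3])


class TestNonlocalShrinkage:
    def test_mom_penalises_small_effects_relative_to_zellner(self):
        # tiny effect e^beta = 1.1: the non-local prior should not give it
        # a larger average PIP than the g-prior does
        pips_m, pips_l = [], []
        for seed in range(10):
            data, _ = selection_benchmark(300, 3, [0], np.log(1.1),
                                          censor_rate=0.3, seed=100 + seed)
            model = AFTVariableSelection.from_selection_data(data)
            pips_m.append(model.fit(coefficient_prior="mom",
                                    elicitation="fixed").pips.iloc[0])
            pips_l.append(model.fit(coefficient_prior="zellner",
                                    elicitation="fixed").pips.iloc[0])
        assert np.mean(pips_m) <= np.mean(pips_l) + 1e-6


class TestValidation:
    def test_zero_times_rejected(self):
        with pytest.raises(ValueError):
            AFTVariableSelection([0.0, 1.0], [1, 1], [[1.0], [2.0]])
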