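"""Posterior sampling: quadrature oracles, determinism, diagnostics."""

import numpy as np
import pytest

from invlindley import load_fixture, loglik
from invlindley.bayes import (
    Estimand,
    PriorSpec,
    gelman_rubin,
    log_posterior,
    mh_sample,
    posterior_mean_quadrature,
    summarize,
)


class TestLogPosterior:
    def test_flat_limit_differs_from_loglik_by_log_theta(self, rme_s1):
        prior = PriorSpec(0.0, 0.0)
        for th in (0.5, 1.0, 2.0):
            diff = log_posterior(th, rme_s1, prior, "LF") - loglik(th, rme_s1)
            assert diff == pytest.approx(-np.log(th), rel=1e-12)

    def test_negative_theta_maps_to_minus_inf(self, rme_s1):
        assert log_posterior(-1.0, rme_s1, PriorSpec(1, 1)) == -np.inf
        assert log_posterior(0.0, rme_s1, PriorSpec(1, 1)) == -np.inf

    def test_mode_agrees_with_grid_search(self, rme_s1):
        prior = PriorSpec(0.0, 0.0)
        grid = np.linspace(0.2, 4.0, 4001)
        vals = [log_posterior(g, rme_s1, prior, "LF") for g in grid]
        grid_mode = grid[int(np.argmax(vals))]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda th: -log_posterior(th, rme_s1, prior, "LF"),
            bounds=(0.2, 4.0),
            method="bounded",
        )
        assert abs(res.x - grid_mode) < 1e-3

    def test_unknown_source_rejected(self, rme_s1):
        with pytest.raises(ValueError):
            log_posterior(1.0, rme_s1, PriorSpec(), source="XX")


class TestMetropolisHastings:
    @pytest.mark.parametrize("source", ["LF", "SF"])
    def test_chain_mean_matches_quadrature(self, rme_s1, source):
        prior = PriorSpec(0.0, 0.0)
        chain = mh_sample(rme_s1, prior, source=source, n_iter=20_000,
                          burn_in=4_000, seed=17)
        for est in (Estimand("theta"), Estimand("rf", 0.5), Estimand("hrf", 0.5)):
            point, _ = summarize(chain, est)
            oracle = posterior_mean_quadrature(rme_s1, prior, est, source=source)
            # tolerance ~3 MC standard errors for a correlated chain
            sd = np.std(est.transform(chain.draws))
            assert abs(point - oracle) < 3 * sd / np.sqrt(400), (source, est.which)

    def test_fixed_seed_is_bit_reproducible(self, rme_s1):
        a = mh_sample(rme_s1, PriorSpec(), n_iter=3000, burn_in=500, seed=5)
        b = mh_sample(rme_s1, PriorSpec(), n_iter=3000, burn_in=500, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_in_reported_band(self, rme_s1, art_s1):
        # small-step normal proposal keeps acceptance high (~0.9)
        for s in (rme_s1, art_s1):
            chain = mh_sample(s, PriorSpec(), n_iter=8000, burn_in=1000, seed=2)
            assert 0.85 <= chain.acceptance_rate <= 0.99

    def test_invalid_iteration_counts(self, rme_s1):
        with pytest.raises(ValueError):
            mh_sample(rme_s1, PriorSpec(), n_iter=100, burn_in=100)

    def test_all_draws_positive(self, rme_s1):
        chain = mh_sample(rme_s1, PriorSpec(), n_iter=3000, burn_in=0, seed=9)
        assert np.all(chain.draws > 0)


class TestSummaries:
    def test_point_is_mean_of_transformed_draws(self, rme_s1):
        chain = mh_sample(rme_s1, PriorSpec(), n_iter=4000, burn_in=500, seed=13)
        est = Estimand("rf", 0.5)
        point, _ = summarize(chain, est)
        assert point == pytest.approx(float(np.mean(est.transform(chain.draws))))
        # and is not the plug-in at the posterior mean
        from invlindley import il_model

        plug = float(il_model.rf(0.5, float(np.mean(chain.draws))))
        assert point != pytest.approx(plug, abs=1e-6)

    def test_interval_contains_median(self, rme_s1):
        chain = mh_sample(rme_s1, PriorSpec(), n_iter=4000, burn_in=500, seed=13)
        point, ci = summarize(chain, Estimand("theta"), level=0.95)
        assert ci.contains(float(np.median(chain.draws)))
        assert ci.level == 0.95

    def test_shrinkage_toward_informative_prior(self):
        # prior mean a/b ~ 0.506; posterior mean lands between it and the MLE
        from invlindley import complete_sample, fit_mle, il_model

        data = il_model.sample(0.5, 200, seed=31)
        s = complete_sample(data)
        mle = fit_mle(s).theta_hat
        prior = PriorSpec(93.156, 184.08)
        est = posterior_mean_quadrature(s, prior, Estimand("theta"))
        lo, hi = sorted((93.156 / 184.08, mle))
        assert lo - 1e-6 <= est <= hi + 1e-6


class TestGelmanRubin:
    def test_identical_chains_give_one(self, rme_s1):
        c = mh_sample(rme_s1, PriorSpec(), n_iter=3000, burn_in=500, seed=1)
        assert gelman_rubin([c, c]) == pytest.approx(1.0, abs=1e-12)

    def test_converged_chains_near_one(self, rme_s1):
        chains = [
            mh_sample(rme_s1, PriorSpec(), n_iter=12_000, burn_in=2_000, seed=s)
            for s in (101, 202)
        ]
        assert gelman_rubin(chains) < 1.05

    def test_disperse_short_chains_detected(self, rme_s1):
        chains = [
            mh_sample(rme_s1, PriorSpec(), n_iter=60, burn_in=0, seed=s,
                      init=init, proposal_sd=0.01)
            for s, init in ((1, 0.01), (2, 100.0))
        ]
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_rejected(self, rme_s1):
        c = mh_sample(rme_s1, PriorSpec(), n_iter=1000, burn_in=0, seed=1)
        with pytest.raises(ValueError):
            gelman_rubin([c])
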