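"""Censoring algebra, fixture validation, and simulator cross-checks."""

import numpy as np
import pytest

from invlindley import (
    ATIPCSample,
    CensoringPlan,
    DegenerateSampleError,
    complete_sample,
    from_observations,
    il_model,
    load_fixture,
    read_sample,
    simulate_atipc,
    simulate_fixed_k,
    simulate_latent,
    write_sample,
)


class TestPlanValidation:
    def test_infeasible_m(self):
        with pytest.raises(ValueError):
            CensoringPlan(n=10, m=11, scheme=(), tau=1.0)

    def test_scheme_budget_exceeded(self):
        with pytest.raises(ValueError):
            CensoringPlan(n=10, m=8, scheme=(3, 3), tau=1.0)

    def test_trailing_zeros_accepted(self):
        plan = CensoringPlan(n=30, m=15, scheme=(3,) * 5 + (0,) * 20, tau=1.5)
        assert sum(plan.active_scheme) == 15

    def test_negative_removals_rejected(self):
        with pytest.raises(ValueError):
            CensoringPlan(n=10, m=5, scheme=(-1, 2), tau=1.0)


class TestObservedSamples:
    # every censored fixture reproduces its published S* count
    @pytest.mark.parametrize(
        "name,k,s_star,applied",
        [
            ("rme_S1", 10, 5, 15),
            ("rme_S2", 12, 3, 15),
            ("rme_S3", 17, 1, 12),
            ("art_S1", 15, 5, 20),
            ("art_S2", 17, 3, 20),
            ("art_S3", 24, 1, 15),
        ],
    )
    def test_fixture_withdrawal_accounting(self, name, k, s_star, applied):
        s = load_fixture(name)
        assert s.k == k
        assert s.s_star == s_star
        assert int(s.s_applied.sum()) == applied
        assert s.n == s.k + int(s.s_applied.sum()) + s.s_star

    def test_removals_stop_after_m_minus_one_failures(self):
        # 17 observed failures but removals only through failure 14 (m=15)
        s = load_fixture("rme_S3")
        assert np.all(s.s_applied[14:] == 0)

    def test_complete_sample_is_degenerate_case(self):
        s = complete_sample([0.5, 1.0, 2.0])
        assert s.k == 3 and s.s_star == 0 and s.is_complete
        assert s.T == 0.0

    def test_inconsistent_plan_rejected(self):
        plan = CensoringPlan(n=12, m=10, scheme=(2, 0, 0, 0, 0, 0, 0, 0, 0), tau=5.0)
        with pytest.raises(ValueError, match="S\\*"):
            from_observations(np.linspace(0.1, 4.9, 11), plan)

    def test_empty_sample_rejected(self):
        plan = CensoringPlan(n=5, m=3, scheme=(), tau=1.0)
        with pytest.raises(ValueError):
            from_observations([], plan)

    def test_q_and_qstar_algebra(self, rme_s1):
        x = 1.0 / rme_s1.z
        T = 1.0 / rme_s1.tau
        expect_q = np.sum((1 + rme_s1.s_applied) * x) + rme_s1.s_star * T
        assert rme_s1.Q == pytest.approx(expect_q, rel=1e-14)
        assert rme_s1.Q - rme_s1.Q_star == pytest.approx(np.sum(x), rel=1e-14)


class TestSimulators:
    def test_conservation_identity_over_seeds(self, small_plan):
        for seed in range(300):
            try:
                s = simulate_atipc(small_plan, 0.5, seed=seed)
            except DegenerateSampleError:
                continue
            assert s.n == s.k + int(s.s_applied.sum()) + s.s_star
            assert s.z[-1] <= s.tau

    def test_complete_reduction(self):
        plan = CensoringPlan(n=15, m=15, scheme=(), tau=np.inf)
        s = simulate_atipc(plan, 0.8, seed=3)
        assert s.k == 15 and s.s_star == 0 and s.is_complete
        assert np.all(np.diff(s.z) > 0)

    def test_degenerate_sample_flagged(self):
        plan = CensoringPlan(n=5, m=3, scheme=(), tau=1e-6)
        with pytest.raises(DegenerateSampleError):
            simulate_atipc(plan, 0.5, seed=0)

    def test_sequential_matches_latent_lifetime_oracle_mean_k(self, small_plan):
        ks_seq, ks_lat = [], []
        rng1 = np.random.default_rng(11)
        rng2 = np.random.default_rng(12)
        for _ in range(800):
            ks_seq.append(simulate_atipc(small_plan, 0.5, rng1).k)
            ks_lat.append(simulate_latent(small_plan, 0.5, rng2).k)
        ks_seq, ks_lat = np.asarray(ks_seq), np.asarray(ks_lat)
        se = np.sqrt(ks_seq.var() / 800 + ks_lat.var() / 800)
        assert abs(ks_seq.mean() - ks_lat.mean()) < 2.5 * se

    def test_sequential_matches_latent_on_small_design_distribution(self):
        plan = CensoringPlan(n=6, m=4, scheme=(1, 1), tau=1.0)
        counts_seq: dict = {}
        counts_lat: dict = {}
        rng1 = np.random.default_rng(21)
        rng2 = np.random.default_rng(22)
        n_rep = 4000
        for _ in range(n_rep):
            for gen, counts in ((simulate_atipc, counts_seq), (simulate_latent, counts_lat)):
                try:
                    s = gen(plan, 0.7, rng1 if counts is counts_seq else rng2)
                    key = (s.k, s.s_star)
                except DegenerateSampleError:
                    key = (0, plan.n)
                counts[key] = counts.get(key, 0) + 1
        keys = set(counts_seq) | set(counts_lat)
        for key in keys:
            p1 = counts_seq.get(key, 0) / n_rep
            p2 = counts_lat.get(key, 0) / n_rep
            se = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / n_rep) + 1e-9
            assert abs(p1 - p2) < max(4 * se, 0.02), (key, p1, p2)

    def test_order_statistics_match_classical_law(self):
        # no removals, tau = inf: j-th generated value is the j-th order stat
        plan = CensoringPlan(n=5, m=5, scheme=(), tau=np.inf)
        rng = np.random.default_rng(5)
        thirds = np.array([simulate_atipc(plan, 1.0, rng).z[2] for _ in range(5000)])
        # F(Z_(3)) ~ Beta(3, 3)
        u = np.sort(np.asarray(il_model.cdf(thirds, 1.0)))
        from scipy import stats

        d = stats.kstest(u, stats.beta(3, 3).cdf).statistic
        assert d < 1.63 / np.sqrt(5000)

    def test_fixed_k_always_observes_m_failures(self, small_plan):
        for seed in range(100):
            s = simulate_fixed_k(small_plan, 0.5, seed=seed)
            assert s.k == small_plan.m
            assert s.n == s.k + int(s.s_applied.sum()) + s.s_star
            assert s.tau == s.z[-1]

    def test_fixed_k_suspends_removals_after_threshold(self):
        plan = CensoringPlan(n=20, m=10, scheme=(2,) * 5, tau=1e-9)
        s = simulate_fixed_k(plan, 0.5, seed=1)
        # threshold precedes every failure, so no planned removal is applied
        assert int(s.s_applied.sum()) == 0
        assert s.s_star == 10


class TestRoundTrip:
    def test_csv_roundtrip_preserves_sample(self, tmp_path, rme_s1):
        path = tmp_path / "s1.csv"
        write_sample(rme_s1, path)
        back = read_sample(path)
        np.testing.assert_array_equal(back.z, rme_s1.z)
        np.testing.assert_array_equal(back.s_applied, rme_s1.s_applied)
        assert back.s_star == rme_s1.s_star
        assert back.tau == rme_s1.tau
        assert (back.n, back.m) == (rme_s1.n, rme_s1.m)
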