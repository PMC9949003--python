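import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from diffjudge.optimal import (MDPConfig, find_rho, omega, posterior_coherence,
                               prob_correct_choice, simulate_policy,
                               solve_bellman, SAMPLE)


@pytest.fixture(scope="module")
def small_cfg():
    """Coarse grid for fast exact-property checks."""
    return MDPConfig(dt=0.1, d_dv=0.2, dv_max=8.0, horizon=3.0)


@pytest.fixture(scope="module")
def small_policy(small_cfg):
    return find_rho(small_cfg, tol=1e-6)


class TestPosterior:
    def test_zero_time_returns_prior(self):
        cfg = MDPConfig()
        p = posterior_coherence(0.7, 0.0, cfg.kappa, cfg.levels)
        np.testing.assert_allclose(p, 1 / 12)

    def test_symmetric_at_zero_dv(self):
        cfg = MDPConfig()
        p = posterior_coherence(0.0, 1.0, cfg.kappa, cfg.levels)
        np.testing.assert_allclose(p, p[::-1])

    def test_matches_direct_summation(self):
        cfg = MDPConfig()
        lv = cfg.levels
        like = norm.pdf(8.0, loc=cfg.kappa * lv * 1.0, scale=1.0)
        expected = like / like.sum()
        got = posterior_coherence(8.0, 1.0, cfg.kappa, lv)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_normalized(self):
        cfg = MDPConfig()
        p = posterior_coherence(-3.2, 0.55, cfg.kappa, cfg.levels)
        assert p.sum() == pytest.approx(1.0)


class TestChoiceBelief:
    @pytest.mark.parametrize("a,b,expected", [
        (0.64, 0.128, 1.0), (0.128, 0.64, 0.0), (0.512, -0.512, 0.5),
        (0.0, 0.0, 0.5),
    ])
    def test_omega(self, a, b, expected):
        assert omega(a, b) == expected

    def test_initial_state_is_even(self):
        cfg = MDPConfig()
        assert prob_correct_choice(0, 0, 0, 0, cfg, 1) == pytest.approx(0.5)

    def test_complementarity(self):
        cfg = MDPConfig()
        for dv1, dv2, t1, t2 in [(2.0, -1.0, 0.5, 0.5), (0.3, 4.0, 1.0, 1.0)]:
            b1 = prob_correct_choice(dv1, t1, dv2, t2, cfg, 1)
            b2 = prob_correct_choice(dv1, t1, dv2, t2, cfg, 2)
            assert b1 + b2 == pytest.approx(1.0)


class TestBellman:
    def test_choose_value_at_even_belief_no_penalty(self, small_cfg):
        # with tp = 0 and b = 0.5 the choose-value is 0.5 - (tnd + tw) * rho
        cfg = dataclasses.replace(small_cfg, tp=0.0)
        rho = 0.3
        pol = solve_bellman(cfg, rho)
        nb = len(pol.dv_grid) // 2
        expected = 0.5 - (cfg.tnd_mean + cfg.tw) * rho
        # with a zero horizon only the choose actions exist, and the
        # origin's belief is exactly even
        term = solve_bellman(dataclasses.replace(cfg, horizon=0.0), rho)
        assert term.values[nb, nb] == pytest.approx(expected, abs=1e-9)

    def test_zero_rho_keeps_sampling(self, small_cfg):
        pol = solve_bellman(small_cfg, 0.0)
        nb = len(pol.dv_grid) // 2
        # no time pressure: continue at the origin in the first slices
        assert pol.actions[0, nb, nb] == SAMPLE

    def test_value_nonincreasing_in_rho(self, small_cfg):
        v = [solve_bellman(small_cfg, r).v0 for r in (0.1, 0.3, 0.5)]
        assert v[0] >= v[1] >= v[2]

    def test_sampling_region_symmetric(self, small_policy):
        # flipping all DV signs leaves the continue-sampling region
        # unchanged exactly; swapping the stimuli (transpose) is exact up to
        # the strict-alternation phase (which stimulus samples next), so a
        # tiny fraction of edge states may differ
        for k in (4, 10, 20):
            samp = small_policy.actions[k] == SAMPLE
            assert (samp == samp[::-1, ::-1]).all()
            assert (samp != samp.T).mean() < 0.01


class TestFindRho:
    def test_root_property(self, small_policy):
        assert abs(small_policy.v0) < 1e-6
        assert small_policy.rho > 0

    def test_no_reward_means_zero_rate(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, rc=0.0, rn=0.0)
        pol = find_rho(cfg, tol=1e-6)
        assert pol.rho == pytest.approx(0.0, abs=1e-4)

    def test_longer_dead_time_lowers_rho(self, small_cfg, small_policy):
        slow = find_rho(dataclasses.replace(small_cfg, tw=2.0), tol=1e-6)
        assert slow.rho < small_policy.rho


class TestSimulatePolicy:
    def test_accuracy_and_speed_increase_with_gap(self, small_policy):
        conds = [(0.64, 0.0), (0.256, 0.0), (0.64, 0.512)]
        tr = simulate_policy(small_policy, conds, n=2000, seed=77)
        acc = tr.groupby(["c1_signed", "c2_signed"]).correct.mean()
        assert acc[(0.64, 0.0)] > acc[(0.256, 0.0)] > 0.5
        assert acc[(0.64, 0.0)] > acc[(0.64, 0.512)]

    def test_symmetric_conditions_even_choices(self, small_policy):
        tr = simulate_policy(small_policy, [(0.384, 0.384)], n=4000, seed=78)
        assert (tr.choice == 1).mean() == pytest.approx(0.5, abs=0.05)

    def test_rt_includes_non_decision_time(self, small_policy):
        tr = simulate_policy(small_policy, [(0.64, 0.0)], n=500, seed=79)
        assert (tr.rt >= small_policy.config.tnd_mean).all()
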