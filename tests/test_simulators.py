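import numpy as np
import pandas as pd
import pytest

from diffjudge.design import Condition
from diffjudge.params import DifficultyParams
from diffjudge.simulate import (AccumulatorState, serial_paths, simulate_abs_momentary,
                                simulate_difference, simulate_difference_known,
                                simulate_model, simulate_race,
                                simulate_two_step, step_serial)

TASK = "difficulty_rt_unknown"
KNOWN = "difficulty_rt_known"


def _cond(c1, c2, task=TASK):
    return Condition(task, c1, c2)


def _mrt(df, c1, c2):
    sel = (df.c1_signed == c1) & (df.c2_signed == c2)
    return df.loc[sel, "rt"].mean()


class TestSerialAccumulation:
    def test_alternation(self, rng):
        s = AccumulatorState()
        s1 = step_serial(s, 0.64, 0.0, 5.0, 0.005, rng)
        assert s1.dv_s2 == 0.0 and s1.dv_s1 != 0.0
        s2 = step_serial(s1, 0.64, 0.0, 5.0, 0.005, rng)
        assert s2.dv_s1 == s1.dv_s1 and s2.dv_s2 != 0.0

    def test_variance_is_half_elapsed_time(self, rng):
        # each stimulus samples for t/2 under perfect time sharing
        dv1, dv2 = serial_paths(0.0, 0.0, 0.0, 0.005, n_steps=200,
                                n_paths=100_000, rng=rng)
        t = 200 * 0.005
        assert dv1.var() == pytest.approx(t / 2, rel=0.02)
        assert dv2.var() == pytest.approx(t / 2, rel=0.02)
        assert abs(dv1.mean()) < 0.01

    def test_mean_drift_under_time_sharing(self, rng):
        kappa = 5.47
        dv1, _ = serial_paths(0.64, 0.0, kappa, 0.005, n_steps=200,
                              n_paths=100_000, rng=rng)
        t = 200 * 0.005
        assert dv1.mean() == pytest.approx(kappa * 0.64 * t / 2, abs=0.01)


@pytest.fixture(scope="module")
def params():
    return DifficultyParams(kappa=5.47, u=1.39, a=2.52, d=1.06, tnd=0.33,
                            b_mini=0.7)


class TestSimulatorProperties:
    @pytest.mark.parametrize("sim", [simulate_race, simulate_difference,
                                     simulate_two_step, simulate_abs_momentary])
    def test_equal_strengths_give_even_choices(self, sim, params):
        d = sim(params, [_cond(0.384, 0.384)], n=4000, seed=9)
        assert (d.choice == 1).mean() == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("sim", [simulate_race, simulate_difference,
                                     simulate_two_step, simulate_abs_momentary])
    def test_label_symmetry(self, sim, params):
        a = sim(params, [_cond(0.512, 0.128)], n=4000, seed=10)
        b = sim(params, [_cond(0.128, 0.512)], n=4000, seed=11)
        assert (a.choice == 1).mean() == pytest.approx((b.choice == 2).mean(),
                                                       abs=0.04)

    def test_difference_large_gap_near_certain(self, params):
        d = simulate_difference(params, [_cond(0.64, 0.0)], n=4000, seed=12)
        assert (d.choice == 1).mean() > 0.9

    def test_difference_accuracy_monotone_in_gap(self, params):
        acc = []
        for c1 in (0.128, 0.256, 0.384, 0.512, 0.64):
            d = simulate_difference(params, [_cond(c1, 0.0)], n=3000, seed=13)
            acc.append((d.choice == 1).mean())
        assert all(b >= a - 0.02 for a, b in zip(acc, acc[1:]))

    def test_race_fastest_at_easy_easy(self, params):
        conds = [_cond(a, b) for a in (0.0, 0.64) for b in (0.0, 0.64)]
        d = simulate_race(params, conds, n=4000, seed=14)
        rt_ee = _mrt(d, 0.64, 0.64)
        assert rt_ee < _mrt(d, 0.0, 0.0)
        assert rt_ee < _mrt(d, 0.0, 0.64)
        assert rt_ee < _mrt(d, 0.64, 0.0)

    def test_difference_criss_cross(self, params):
        conds = [_cond(a, b) for a in (0.0, 0.64) for b in (0.0, 0.64)]
        d = simulate_difference(params, conds, n=4000, seed=15)
        assert _mrt(d, 0.0, 0.0) > _mrt(d, 0.64, 0.64)
        assert _mrt(d, 0.0, 0.0) > _mrt(d, 0.0, 0.64)
        assert _mrt(d, 0.64, 0.64) > _mrt(d, 0.64, 0.0)

    def test_abs_momentary_flattens_hard_easy_rt_contrast(self, params):
        # accumulating unsigned momentary evidence makes hard-hard and
        # easy-easy nearly equally fast, unlike the Difference model whose
        # hard-hard comparisons are distinctly slower; this is why the
        # unsigned-accumulation account understates hard-hard RTs when fit
        conds = [_cond(0.0, 0.0), _cond(0.64, 0.64)]
        da = simulate_abs_momentary(params, conds, n=4000, seed=16)
        dd = simulate_difference(params, conds, n=4000, seed=16)
        spread_a = _mrt(da, 0, 0) - _mrt(da, 0.64, 0.64)
        spread_d = _mrt(dd, 0, 0) - _mrt(dd, 0.64, 0.64)
        assert spread_a < spread_d / 2

    def test_abs_momentary_zero_drift_even_choices(self, params):
        # increments are folded normals for both DVs; the difference has
        # zero drift, so choices stay even
        d = simulate_abs_momentary(params, [_cond(0.0, 0.0)], n=4000, seed=17)
        assert (d.choice == 1).mean() == pytest.approx(0.5, abs=0.03)

    def test_two_step_sign_estimates_mostly_right_when_easy(self, params):
        d = simulate_two_step(params, [_cond(0.64, 0.0)], n=3000, seed=18)
        assert (d.choice == 1).mean() > 0.9

    def test_rts_exceed_non_decision_time(self, params):
        d = simulate_difference(params, [_cond(0.0, 0.0)], n=2000, seed=19)
        assert (d.rt > 0).all()
        assert d.rt.min() > 0.005  # at least one accumulation step + tnd draw

    def test_censoring_rare_at_reference_parameters(self, params, rt_design):
        d = simulate_difference(params, rt_design, n=30, seed=20)
        assert d.censored.mean() < 0.01

    def test_unknown_model_name_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_model("drift_race", params, [_cond(0, 0)], 10, 1)

    def test_two_step_requires_b_mini(self):
        p = DifficultyParams(kappa=5.0, u=1.0, a=2.0, d=1.0, tnd=0.3)
        with pytest.raises(ValueError, match="b_mini"):
            simulate_two_step(p, [_cond(0, 0)], 10, 1)


class TestKnownColor:
    def test_equal_delta_c_gives_same_rt_distribution(self, params):
        # the signed-difference process drifts at kappa*(C1-C2)/2: cells with
        # the same strength difference share the RT distribution
        from scipy.stats import ks_2samp
        d = simulate_difference_known(
            params, [_cond(0.256, 0.128, KNOWN), _cond(0.64, 0.512, KNOWN)],
            n=4000, seed=21)
        a = d[d.c1_signed == 0.256].rt
        b = d[d.c1_signed == 0.64].rt
        assert ks_2samp(a, b).pvalue > 0.01

    def test_known_faster_than_unknown(self, params):
        conds_k = [_cond(0.384, 0.128, KNOWN)]
        d_k = simulate_difference_known(params, conds_k, n=4000, seed=22)
        d_u = simulate_difference(params, [_cond(0.384, 0.128)], n=4000, seed=22)
        assert d_k.rt.mean() < d_u.rt.mean()

    def test_zero_delta_c_even_choices(self, params):
        d = simulate_difference_known(params, [_cond(0.384, 0.384, KNOWN)],
                                      n=4000, seed=23)
        assert (d.choice == 1).mean() == pytest.approx(0.5, abs=0.03)

    def test_mixed_sign_condition_rejected(self, params):
        cond = Condition(TASK, 0.384, -0.128)  # unknown task allows mixed signs
        with pytest.raises(ValueError, match="same-sign"):
            simulate_difference_known(params, [cond], n=10, seed=1)
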