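import numpy as np
import pytest

from diffjudge.colorddm import (ChoiceRTDensity, ColorDDM, bound, fp_solve,
                                rt_distribution)
from diffjudge.design import make_design
from diffjudge.params import ColorParams


@pytest.fixture(scope="module")
def subj_params():
    return ColorParams(kappa=6.37, c0=0.0, u=0.97, a=4.46, d=1.16, tnd=0.34)


class TestBound:
    def test_half_height_at_d(self):
        assert bound(1.16, u=0.97, a=4.46, d=1.16) == pytest.approx(0.97 / 2)

    def test_collapses_to_zero(self):
        assert bound(200.0, u=0.97, a=4.46, d=1.16) == pytest.approx(0.0, abs=1e-12)

    def test_initial_height(self):
        # u / (1 + exp(-a d)) for the reference subject
        assert bound(0.0, u=0.97, a=4.46, d=1.16) == pytest.approx(0.9645, abs=1e-3)


class TestFPSolve:
    def test_symmetric_drift_splits_evenly(self, subj_params):
        dens = fp_solve(subj_params, 0.0, dt=1e-3)
        assert dens.p_upper == pytest.approx(0.5, abs=1e-3)
        assert dens.p_lower == pytest.approx(0.5, abs=1e-3)

    def test_strong_drift_near_certain(self):
        p = ColorParams(kappa=20.0, c0=0.0, u=0.97, a=4.46, d=1.16, tnd=0.34)
        dens = fp_solve(p, 0.64, dt=1e-3)
        assert dens.p_upper > 0.99

    def test_probability_conservation(self, subj_params):
        dens = fp_solve(subj_params, 0.256, dt=1e-3)
        assert dens.p_upper + dens.p_lower + dens.residual == pytest.approx(1.0, abs=1e-6)

    def test_sign_symmetry_swaps_choices(self, subj_params):
        up = fp_solve(subj_params, 0.384, dt=1e-3)
        dn = fp_solve(subj_params, -0.384, dt=1e-3)
        np.testing.assert_allclose(up.f_upper, dn.f_lower, atol=1e-9)
        np.testing.assert_allclose(up.f_lower, dn.f_upper, atol=1e-9)

    def test_monotone_in_strength(self, subj_params):
        sols = [fp_solve(subj_params, c, dt=1e-3)
                for c in (0.0, 0.128, 0.256, 0.384, 0.512, 0.64)]
        pc = [s.p_upper for s in sols]
        mt = [s.mean_td() for s in sols]
        assert all(b >= a - 1e-9 for a, b in zip(pc, pc[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(mt, mt[1:]))

    def test_coherence_offset_bias(self, subj_params):
        p = ColorParams(kappa=6.37, c0=0.1, u=0.97, a=4.46, d=1.16, tnd=0.34)
        assert fp_solve(p, 0.0, dt=1e-3).p_upper > 0.55


class TestRTDistribution:
    def test_point_mass_becomes_gaussian(self):
        dt = 1e-3
        n = 3000
        f_up = np.zeros(n)
        f_up[999] = 1.0 / dt  # decision-time point mass at 1.0 s
        dens = ChoiceRTDensity(t=(np.arange(n) + 1) * dt, dt=dt,
                               f_upper=f_up, f_lower=np.zeros(n), residual=0.0)
        t, fu, fl = rt_distribution(dens, tnd=0.34, sigma_tnd=0.05)
        from scipy.stats import norm
        for q in (1.25, 1.34, 1.45):
            i = np.argmin(np.abs(t - q))
            assert fu[i] == pytest.approx(norm.pdf(q, 1.34, 0.05), rel=0.02)
        assert np.all(fl == 0)

    def test_mean_rt_is_mean_td_plus_tnd(self, subj_params):
        dens = fp_solve(subj_params, 0.256, dt=1e-3)
        t, fu, fl = rt_distribution(dens, tnd=0.34)
        f = fu + fl
        mean_rt = (t * f).sum() / f.sum()
        assert mean_rt == pytest.approx(dens.mean_td() + 0.34, abs=2e-3)

    def test_zero_tnd_is_identity(self, subj_params):
        dens = fp_solve(subj_params, 0.256, dt=1e-3)
        t, fu, fl = rt_distribution(dens, tnd=0.0, sigma_tnd=0.0)
        np.testing.assert_allclose(fu[:len(dens.f_upper)], dens.f_upper)


class TestColorFit:
    def test_parameter_recovery(self, subj_params):
        """Simulated color-task data should give back drift and latency."""
        import pandas as pd
        rng = np.random.default_rng(5)
        rows = []
        n_per = 40  # 480 trials over the 12 signed levels
        for cond in make_design("color_rt", reps=1):
            dens = fp_solve(subj_params, cond.c1_signed, dt=2e-3)
            t, fu, fl = rt_distribution(dens, subj_params.tnd)
            p_up = np.trapezoid(fu, t)
            for _ in range(n_per):
                blue = rng.random() < p_up
                f = fu if blue else fl
                rt = rng.choice(t, p=f / f.sum())
                rows.append({"subject": 0, "task": "color_rt",
                             "c1_signed": cond.c1_signed, "c2_signed": np.nan,
                             "duration": np.nan, "choice": 1 if blue else 2,
                             "rt": rt, "correct": 1})
        trials = pd.DataFrame(rows)
        est = ColorDDM(n_starts=2, dt=2e-3, max_evals=80, random_state=0)
        est.fit(trials)
        assert est.params_.kappa == pytest.approx(subj_params.kappa, rel=0.35)
        assert est.params_.tnd == pytest.approx(subj_params.tnd, abs=0.08)

    def test_empty_input_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            ColorDDM().fit(pd.DataFrame({"task": []}))
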