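import numpy as np
import pandas as pd
import pytest

from diffjudge.design import make_design
from diffjudge.fitting import (DifficultyModel, FitResult, bic, compare_models,
                               epanechnikov_density, fit_model,
                               kernel_likelihood)
from diffjudge.params import DifficultyParams
from diffjudge.simulate import simulate_difference


@pytest.fixture(scope="module")
def gen_params():
    return DifficultyParams(kappa=5.47, u=1.39, a=2.52, d=1.06, tnd=0.33)


@pytest.fixture(scope="module")
def small_data(gen_params):
    design = make_design("difficulty_rt_unknown", 2, 1 / 3)
    d = simulate_difference(gen_params, design, n=1, seed=50)
    return d[~d.censored].reset_index(drop=True)


class TestEpanechnikovDensity:
    def test_hand_summed_kernel_value(self):
        # three samples, bandwidth 0.2, evaluated at the middle sample:
        # [K(0.5) + K(0) + K(-0.5)] / (3 h) with K(z) = 0.75 (1 - z^2)
        samples = np.array([1.0, 1.1, 1.2])
        expected = (0.75 * (1 - 0.25) * 2 + 0.75) / (3 * 0.2)
        assert epanechnikov_density(1.1, samples, h=0.2) == pytest.approx(expected)

    def test_integrates_to_choice_mass(self):
        samples = np.random.default_rng(0).normal(1.0, 0.1, size=200)
        x = np.linspace(0, 2, 2001)
        dens = epanechnikov_density(x, samples, h=0.05, n_total=400)
        assert np.trapezoid(dens, x) == pytest.approx(0.5, abs=1e-3)


class TestKernelLikelihood:
    def test_empty_table_scores_zero(self, gen_params):
        empty = pd.DataFrame({"c1_signed": [], "c2_signed": [], "rt": [],
                              "choice": []})
        assert kernel_likelihood(empty, gen_params, "difference") == 0.0

    def test_invariant_to_trial_order(self, gen_params, small_data):
        ll = kernel_likelihood(small_data, gen_params, "difference",
                               n_sim=200, seed=3)
        shuffled = small_data.sample(frac=1.0, random_state=9)
        ll2 = kernel_likelihood(shuffled, gen_params, "difference",
                                n_sim=200, seed=3)
        assert ll == pytest.approx(ll2, abs=1e-9)

    def test_true_parameters_beat_distorted(self, gen_params):
        # likelihood ordering over replicates: generating parameters beat a
        # kappa-doubled alternative
        design = make_design("difficulty_rt_unknown", 2, 1 / 3)
        distorted = DifficultyParams(kappa=2 * gen_params.kappa,
                                     u=gen_params.u, a=gen_params.a,
                                     d=gen_params.d, tnd=gen_params.tnd)
        wins = 0
        for rep in range(5):
            d = simulate_difference(gen_params, design, n=1, seed=60 + rep)
            d = d[~d.censored].reset_index(drop=True)
            ll_true = kernel_likelihood(d, gen_params, "difference",
                                        n_sim=400, seed=7)
            ll_bad = kernel_likelihood(d, distorted, "difference",
                                       n_sim=400, seed=7)
            wins += ll_true > ll_bad
        assert wins >= 4


class TestBIC:
    def test_formula(self):
        assert bic(-500.0, 5, 100) == pytest.approx(5 * np.log(100) + 1000)

    def test_machine_precision(self):
        ll, k, n = -1234.5678, 6, 1152
        assert bic(ll, k, n) == k * np.log(n) - 2 * ll


def _fit(model, subject, b, ll=-500.0, n=100):
    k = 6 if model == "two_step" else 5
    return FitResult(model=model,
                     params=DifficultyParams(kappa=5, u=1, a=2, d=1, tnd=0.3,
                                             b_mini=0.5 if k == 6 else None),
                     loglik=ll, bic=b, n_trials=n, n_params=k, subject=subject)


class TestCompareModels:
    def test_single_model_zero_delta(self):
        out = compare_models([_fit("difference", 0, 1000.0)])
        assert out["delta_bic"].iloc[0, 0] == 0.0
        assert out["group_winner"] == "difference"

    def test_winner_counts_and_group(self):
        fits = [_fit("difference", 0, 1000.0), _fit("race", 0, 1100.0),
                _fit("difference", 1, 990.0), _fit("race", 1, 980.0)]
        out = compare_models(fits)
        assert out["winner_counts"] == {"difference": 1, "race": 1}
        assert out["group_winner"] == "difference"  # 1990 < 2080

    def test_constant_shift_of_one_subject_cancels(self):
        base = [_fit("difference", 0, 1000.0), _fit("race", 0, 1040.0),
                _fit("difference", 1, 900.0), _fit("race", 1, 920.0)]
        shifted = [_fit(f.model, f.subject,
                        f.bic + (50.0 if f.subject == 1 else 0.0))
                   for f in base]
        assert (compare_models(base)["group_winner"]
                == compare_models(shifted)["group_winner"])

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_models([_fit("difference", 0, 1000.0),
                            _fit("race", 1, 1000.0)])


class TestFitModel:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_model("difference", pd.DataFrame({"rt": [], "choice": [],
                                                  "c1_signed": [],
                                                  "c2_signed": []}))

    def test_unknown_model_rejected(self, small_data):
        with pytest.raises(ValueError):
            fit_model("mystery", small_data)

    def test_fit_is_deterministic_given_seed(self, small_data):
        kw = dict(n_sim=150, n_starts=1, max_evals=30, random_state=11)
        a = DifficultyModel(model="difference", **kw).fit(small_data)
        b = DifficultyModel(model="difference", **kw).fit(small_data)
        assert a.loglik_ == b.loglik_
        assert vars(a.params_) == vars(b.params_)

    def test_sklearn_param_interface(self):
        est = DifficultyModel(model="race", n_sim=123)
        assert est.get_params()["n_sim"] == 123
        est.set_params(n_sim=200)
        assert est.n_sim == 200
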