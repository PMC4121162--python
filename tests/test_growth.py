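import math
import subprocess
import sys

import numpy as np
import pytest
from hypothesis import given, strategies as st

import octogrowth as og
from octogrowth.growth import FitError, akaike_weights

from conftest import gompertz_data


class TestPredictMass:
    def test_asymptote_limit(self, gompertz_all):
        a = 50.0 / gompertz_all.g1
        assert og.predict_mass(gompertz_all, a) == pytest.approx(
            gompertz_all.m_inf, rel=1e-6
        )

    def test_shape_collapse_limit(self):
        p = og.GrowthParams(model="gompertz", m_inf=100.0, gamma=1e-9, g1=0.01)
        ages = np.array([0.0, 10.0, 100.0, 300.0])
        assert np.allclose(og.predict_mass(p, ages), 100.0, rtol=1e-8)

    def test_inflection_weight_is_m_inf_over_e(self, gompertz_all):
        # whole-cohort curve: inflection weight 63.11 g at a* = ln(gamma)/g1
        a_star = math.log(gompertz_all.gamma) / gompertz_all.g1
        assert og.predict_mass(gompertz_all, a_star) == pytest.approx(63.11, rel=1e-12)
        assert gompertz_all.inflection_weight == pytest.approx(63.11, rel=1e-12)

    def test_inflection_is_second_derivative_root(self, gompertz_all):
        # numerical second derivative changes sign across a*
        a_star = gompertz_all.inflection_age
        h = 1e-3

        def d2(a):
            f = lambda x: og.predict_mass(gompertz_all, x)
            return (f(a + h) - 2 * f(a) + f(a - h)) / h**2

        assert d2(a_star - 5.0) > 0 > d2(a_star + 5.0)
        assert abs(d2(a_star)) < abs(d2(a_star - 5.0))

    def test_monotone_increasing_and_bounded(self, gompertz_all):
        ages = np.linspace(0.0, 600.0, 400)
        m = og.predict_mass(gompertz_all, ages)
        assert np.all(np.diff(m) > 0)
        assert np.all(m < gompertz_all.m_inf)

    def test_simple_models(self):
        assert og.predict_mass(
            og.GrowthParams(model="exponential", b0=2.0, c=0.01), 100.0
        ) == pytest.approx(2.0 * math.e)
        assert og.predict_mass(
            og.GrowthParams(model="power", b0=0.5, c=2.0), 3.0
        ) == pytest.approx(4.5)
        assert og.predict_mass(
            og.GrowthParams(model="linear", b0=1.0, c=0.5), 10.0
        ) == pytest.approx(6.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            og.GrowthParams(model="gompertz", m_inf=-5.0, gamma=1.0, g1=0.01)
        with pytest.raises(ValueError):
            og.GrowthParams(model="gompertz", m_inf=5.0, gamma=1.0)  # g1 missing


class TestRelativeGrowthRate:
    def test_vanishes_at_large_age(self, gompertz_all):
        assert og.relative_growth_rate(gompertz_all, 1e6) == pytest.approx(0.0, abs=1e-30)

    def test_equals_g1_at_inflection(self, gompertz_all):
        a_star = gompertz_all.inflection_age
        assert og.relative_growth_rate(gompertz_all, a_star) == pytest.approx(
            gompertz_all.g1, rel=1e-12
        )

    def test_strictly_decreasing(self, gompertz_all):
        ages = np.linspace(0.0, 400.0, 200)
        assert np.all(np.diff(og.relative_growth_rate(gompertz_all, ages)) < 0)

    def test_matches_log_mass_derivative(self, gompertz_all):
        # G = d ln m / da by central finite differences
        ages = np.array([50.0, 100.0, 163.0, 250.0])
        h = 1e-4
        num = (
            np.log(og.predict_mass(gompertz_all, ages + h))
            - np.log(og.predict_mass(gompertz_all, ages - h))
        ) / (2 * h)
        assert np.allclose(og.relative_growth_rate(gompertz_all, ages), num, rtol=1e-8)

    def test_unsupported_model(self):
        with pytest.raises(ValueError):
            og.relative_growth_rate(og.GrowthParams(model="linear", b0=1.0, c=1.0), 10.0)


class TestFitModel:
    def test_zero_noise_gompertz_identifiable(self, gompertz_all):
        ages = np.linspace(60.0, 320.0, 20)
        m = og.predict_mass(gompertz_all, ages)
        fit = og.fit_model(ages, m, model="gompertz")
        assert fit.converged
        assert fit.params.m_inf == pytest.approx(gompertz_all.m_inf, rel=1e-6)
        assert fit.params.gamma == pytest.approx(gompertz_all.gamma, rel=1e-6)
        assert fit.params.g1 == pytest.approx(gompertz_all.g1, rel=1e-6)
        assert fit.rss_weighted < 1e-12

    @pytest.mark.parametrize(
        "model,truth",
        [
            ("exponential", og.GrowthParams(model="exponential", b0=0.5, c=0.018)),
            ("power", og.GrowthParams(model="power", b0=0.01, c=1.7)),
            ("linear", og.GrowthParams(model="linear", b0=5.0, c=0.4)),
        ],
    )
    def test_zero_noise_simple_models(self, model, truth):
        ages = np.linspace(30.0, 300.0, 25)
        m = og.predict_mass(truth, ages)
        fit = og.fit_model(ages, m, model=model, weighting="none")
        assert fit.params.b0 == pytest.approx(truth.b0, rel=1e-6)
        assert fit.params.c == pytest.approx(truth.c, rel=1e-6)

    def test_linear_fit_equals_normal_equations(self, rng):
        ages = rng.uniform(10.0, 200.0, 60)
        m = 8.0 + 0.3 * ages + rng.normal(0.0, 2.0, 60)
        m = np.abs(m) + 0.1
        fit = og.fit_model(ages, m, model="linear", weighting="none")
        X = np.column_stack([np.ones_like(ages), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ m)  # normal-equations oracle
        assert fit.params.b0 == pytest.approx(beta[0], rel=1e-10)
        assert fit.params.c == pytest.approx(beta[1], rel=1e-10)

    def test_deterministic_given_data(self, gompertz_all):
        ages, m = gompertz_data(gompertz_all, 150, 0.15, seed=99)
        f1 = og.fit_model(ages, m)
        f2 = og.fit_model(ages, m)
        assert np.array_equal(f1.params.theta, f2.params.theta)

    def test_matches_r_minpack_lm_oracle(self, gompertz_all, tmp_path):
        ages, m = gompertz_data(gompertz_all, 40, 0.10, seed=5)
        np.savetxt(
            tmp_path / "d.csv",
            np.column_stack([ages, m]),
            delimiter=",",
            header="a,m",
            comments="",
        )
        script = tmp_path / "fit.R"
        script.write_text(
            'library(minpack.lm)\n'
            f'd <- read.csv("{tmp_path / "d.csv"}")\n'
            "f <- nlsLM(m ~ minf*exp(-g*exp(-k*a)), data=d,\n"
            "           start=list(minf=200, g=10, k=0.01),\n"
            "           control=nls.lm.control(maxiter=200, ftol=1e-12, ptol=1e-12))\n"
            'cat(sprintf("%.12g %.12g %.12g\\n", coef(f)[1], coef(f)[2], coef(f)[3]))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        minf_r, gamma_r, g1_r = map(float, out.stdout.split())
        fit = og.fit_model(ages, m, weighting="none")
        assert fit.params.m_inf == pytest.approx(minf_r, rel=1e-5)
        assert fit.params.gamma == pytest.approx(gamma_r, rel=1e-5)
        assert fit.params.g1 == pytest.approx(g1_r, rel=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            og.fit_model([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], model="gompertz")

    def test_asymptotic_ses_present(self, gompertz_all):
        ages, m = gompertz_data(gompertz_all, 120, 0.15, seed=3)
        fit = og.fit_model(ages, m)
        assert set(fit.se) == {"m_inf", "gamma", "g1"}
        assert all(v > 0 for v in fit.se.values())


class TestAkaikeWeights:
    def test_two_model_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        e = math.exp(-1.0)
        assert w[0] == pytest.approx(1.0 / (1.0 + e), rel=1e-12)
        assert w[1] == pytest.approx(e / (1.0 + e), rel=1e-12)

    def test_equal_aics_split_evenly(self):
        assert np.allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    @given(
        aics=st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=6),
        shift=st.floats(-1e3, 1e3),
    )
    def test_sum_to_one_and_shift_invariant(self, aics, shift):
        w = akaike_weights(aics)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.allclose(w, akaike_weights([a + shift for a in aics]), atol=1e-9)

    def test_aic_and_weights_requires_common_n(self, gompertz_all):
        a1, m1 = gompertz_data(gompertz_all, 50, 0.1, seed=1)
        a2, m2 = gompertz_data(gompertz_all, 60, 0.1, seed=2)
        f1 = og.fit_model(a1, m1, weighting="data_sq")
        f2 = og.fit_model(a2, m2, model="linear", weighting="data_sq")
        with pytest.raises(ValueError, match="differing n"):
            og.aic_and_weights([f1, f2])

    def test_populates_aic_waic_over_candidates(self, gompertz_all):
        ages, m = gompertz_data(gompertz_all, 150, 0.15, seed=10)
        fits = og.aic_and_weights(
            [
                og.fit_model(ages, m, model=k, weighting="data_sq")
                for k in ("gompertz", "exponential", "power", "linear")
            ]
        )
        assert sum(f.waic for f in fits) == pytest.approx(1.0, abs=1e-12)
        n = fits[0].n
        for f in fits:  # least-squares AIC with the error variance counted
            assert f.aic == pytest.approx(
                n * math.log(f.rss_weighted / n) + 2 * (f.k + 1)
            )


class TestBootstrap:
    def test_zero_noise_interval_degenerates(self, gompertz_all):
        ages = np.linspace(60.0, 320.0, 20)
        m = np.asarray(og.predict_mass(gompertz_all, ages))
        ci, failed = og.bootstrap_ci(ages, m, n_boot=50, seed=1)
        assert failed == 0
        for name, (lo, hi) in ci.items():
            assert (hi - lo) / max(abs(lo), 1e-12) < 1e-4

    def test_same_seed_reproduces_intervals(self, gompertz_all):
        ages, m = gompertz_data(gompertz_all, 80, 0.15, seed=21)
        ci1, _ = og.bootstrap_ci(ages, m, n_boot=100, seed=77)
        ci2, _ = og.bootstrap_ci(ages, m, n_boot=100, seed=77)
        assert ci1 == ci2

    def test_linear_percentile_ci_near_normal_theory(self, rng):
        n = 200
        ages = rng.uniform(10.0, 200.0, n)
        m = 10.0 + 0.30 * ages + rng.normal(0.0, 1.0, n)
        fit = og.fit_model(ages, m, model="linear", weighting="none")
        ci, _ = og.bootstrap_ci(
            ages, m, model="linear", weighting="none", n_boot=1000, seed=5, point_fit=fit
        )
        # analytic OLS slope CI
        from scipy import stats

        X = np.column_stack([np.ones_like(ages), ages])
        resid = m - X @ np.linalg.solve(X.T @ X, X.T @ m)
        s2 = resid @ resid / (n - 2)
        se_slope = math.sqrt(s2 / np.sum((ages - ages.mean()) ** 2))
        width_theory = 2 * stats.t.ppf(0.975, n - 2) * se_slope
        width_boot = ci["c"][1] - ci["c"][0]
        assert abs(width_boot - width_theory) / width_theory < 0.15
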