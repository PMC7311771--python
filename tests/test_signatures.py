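import numpy as np
import pytest
from scipy import optimize, stats

from mmspike.errors import FitError, ValidationError
from mmspike.signatures import (
    GammaSignature,
    empirical_pdf,
    fit_family,
    fit_gamma_mle,
    gamma_ci,
    loglog_plane_fit,
    moment_coordinates,
    select_best_family,
)


def brute_force_gamma_mle(x):
    """Independent oracle: 2-D grid search plus nested golden-section refinement
    of the Gamma log-likelihood evaluated via scipy's logpdf."""

    def negll(a, b):
        return -stats.gamma.logpdf(x, a, scale=b).sum()

    a_grid = np.geomspace(0.05, 100, 120)
    b_grid = np.geomspace(x.mean() / 100, x.mean() * 20, 120)
    best = min(
        ((a, b) for a in a_grid for b in b_grid), key=lambda ab: negll(*ab)
    )

    def refine_b(a):
        res = optimize.minimize_scalar(
            lambda lb: negll(a, np.exp(lb)),
            bracket=(np.log(best[1]) - 1, np.log(best[1]) + 1),
            method="golden",
            options={"xtol": 1e-12},
        )
        return np.exp(res.x), res.fun

    res = optimize.minimize_scalar(
        lambda la: refine_b(np.exp(la))[1],
        bracket=(np.log(best[0]) - 1, np.log(best[0]) + 1),
        method="golden",
        options={"xtol": 1e-12},
    )
    a_hat = np.exp(res.x)
    return a_hat, refine_b(a_hat)[0]


class TestFitFamily:
    def test_exponential_closed_form(self):
        params, ll = fit_family([1.0, 2.0, 3.0], "exponential", min_obs=3)
        assert params["mean"] == pytest.approx(2.0)
        assert ll == pytest.approx(-3 * np.log(2) - 3)

    def test_gaussian_n_denominator(self):
        params, _ = fit_family([0.0, 0.0, 4.0, 4.0], "gaussian", min_obs=4)
        assert params["mean"] == pytest.approx(2.0)
        assert params["sd"] == pytest.approx(2.0)

    def test_lognormal_is_gaussian_on_logs(self, rng):
        x = rng.lognormal(-1.0, 0.4, size=500)
        params, ll = fit_family(x, "lognormal")
        lx = np.log(x)
        assert params["mu_log"] == pytest.approx(lx.mean())
        assert params["sigma_log"] == pytest.approx(lx.std())
        # cross-check likelihood against scipy's lognormal density
        ll_scipy = stats.lognorm.logpdf(
            x, params["sigma_log"], scale=np.exp(params["mu_log"])
        ).sum()
        assert ll == pytest.approx(ll_scipy)

    def test_exponential_case_recovered_as_shape_one(self, rng):
        x = rng.exponential(0.5, size=4000)
        sig = select_best_family(x)
        lo, hi = sig.ci_shape
        assert lo <= 1.0 <= hi
        assert sig.loglik_by_family["gamma"] >= sig.loglik_by_family["exponential"]

    def test_min_obs_floor(self):
        with pytest.raises(FitError):
            fit_family([1.0] * 5, "gamma")

    def test_nonpositive_values_name_family(self):
        with pytest.raises(FitError, match="gamma"):
            fit_family([1.0] * 9 + [-1.0], "gamma")

    def test_degenerate_constant_sample(self):
        with pytest.raises(FitError):
            fit_family([2.0] * 50, "gamma", min_obs=10)


class TestGammaMLE:
    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        a_true = rng.uniform(0.5, 6.0)
        b_true = rng.uniform(0.01, 1.0)
        x = rng.gamma(a_true, b_true, size=200)
        a_hat, b_hat = fit_gamma_mle(x)
        a_ref, b_ref = brute_force_gamma_mle(x)
        assert a_hat == pytest.approx(a_ref, rel=1e-4)
        assert b_hat == pytest.approx(b_ref, rel=1e-4)

    def test_nesting_gamma_beats_exponential(self, rng):
        for _ in range(30):
            x = rng.gamma(rng.uniform(0.3, 8), rng.uniform(0.01, 2), size=100)
            _, ll_g = fit_family(x, "gamma")
            _, ll_e = fit_family(x, "exponential")
            assert ll_g >= ll_e


class TestSelectBestFamily:
    def test_gamma_sample_not_won_by_exponential(self, rng):
        x = rng.gamma(3.0, 0.1, size=2000)
        sig = select_best_family(x)
        assert sig.best_family in ("gamma", "lognormal")
        assert sig.loglik_by_family["gamma"] >= sig.loglik_by_family["exponential"]

    def test_signature_identities(self, rng):
        x = rng.gamma(2.0, 0.05, size=500)
        sig = select_best_family(x)
        assert sig.mean == pytest.approx(sig.shape * sig.scale, rel=1e-12)
        assert sig.variance == pytest.approx(sig.shape * sig.scale**2, rel=1e-12)
        assert sig.nsr == pytest.approx(sig.variance / sig.mean, rel=1e-12)
        assert sig.ci_shape[0] <= sig.shape <= sig.ci_shape[1]
        assert sig.ci_scale[0] <= sig.scale <= sig.ci_scale[1]


class TestGammaCI:
    def test_width_shrinks_with_n(self, rng):
        x = rng.gamma(2.0, 0.1, size=10000)
        (lo1, hi1), _ = gamma_ci(x[:100])
        (lo2, hi2), _ = gamma_ci(x)
        assert (hi1 - lo1) > (hi2 - lo2)

    def test_level_zero_degenerates_to_mle(self, rng):
        x = rng.gamma(2.0, 0.1, size=200)
        (lo, hi), (blo, bhi) = gamma_ci(x, level=0.0)
        a, b = fit_gamma_mle(x)
        assert lo == hi == pytest.approx(a)
        assert blo == bhi == pytest.approx(b)

    def test_coverage_near_nominal(self):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            x = rng.gamma(2.0, 0.1, size=800)
            (lo, hi), _ = gamma_ci(x)
            hits += lo <= 2.0 <= hi
        assert 0.90 * n_rep <= hits <= 0.99 * n_rep


class TestMoments:
    def test_closed_forms(self):
        sig = GammaSignature(4.0, 0.5, (0, 0), (0, 0), {}, "gamma", 100)
        assert moment_coordinates(sig) == pytest.approx((2.0, 1.0, 1.0, 4.5))

    def test_shape_one_is_exponential(self):
        sig = GammaSignature(1.0, 1.0, (0, 0), (0, 0), {}, "gamma", 100)
        assert sig.skewness == pytest.approx(2.0)
        assert sig.kurtosis == pytest.approx(9.0)

    def test_large_shape_tends_gaussian(self):
        sig = GammaSignature(1e8, 1.0, (0, 0), (0, 0), {}, "gamma", 100)
        assert sig.skewness < 1e-3
        assert sig.kurtosis == pytest.approx(3.0, abs=1e-3)


class TestLogLogPlane:
    @staticmethod
    def sig(a, b):
        return GammaSignature(a, b, (0, 0), (0, 0), {}, "gamma", 100)

    def test_exact_power_law_recovered(self):
        k, c = -0.8, 0.3
        sigs = [self.sig(a, c * a**k) for a in (0.5, 1.0, 2.0, 4.0, 8.0)]
        fit = loglog_plane_fit(sigs)
        assert fit["slope"] == pytest.approx(k, abs=1e-10)
        assert fit["intercept"] == pytest.approx(np.log(c), abs=1e-10)
        assert fit["residual_norm"] == pytest.approx(0.0, abs=1e-10)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            loglog_plane_fit([self.sig(1, 1), self.sig(2, 2)])

    def test_noisy_power_law_slope_in_ci(self, rng):
        k, c = -1.2, 0.5
        a = np.geomspace(0.5, 10, 40)
        b = c * a**k * np.exp(rng.normal(0, 0.1, size=a.size))
        fit = loglog_plane_fit([self.sig(ai, bi) for ai, bi in zip(a, b)])
        lo, hi = fit["ci_slope"]
        assert lo <= k <= hi


class TestEmpiricalPdf:
    def test_exponential_density_value(self):
        sig = GammaSignature(1.0, 1.0, (0, 0), (0, 0), {}, "gamma", 100)
        assert empirical_pdf(sig, [0.5])[0] == pytest.approx(np.exp(-0.5))

    def test_normalization_by_trapezoid(self):
        sig = GammaSignature(3.0, 0.1, (0, 0), (0, 0), {}, "gamma", 100)
        grid = np.linspace(1e-6, 3.0, 20000)
        total = np.trapezoid(empirical_pdf(sig, grid), grid)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_mode_location(self):
        a, b = 4.0, 0.25
        sig = GammaSignature(a, b, (0, 0), (0, 0), {}, "gamma", 100)
        grid = np.linspace(1e-4, 5.0, 50001)
        dens = empirical_pdf(sig, grid)
        assert grid[np.argmax(dens)] == pytest.approx((a - 1) * b, abs=2e-4)

    def test_nonpositive_grid_rejected(self):
        sig = GammaSignature(1.0, 1.0, (0, 0), (0, 0), {}, "gamma", 100)
        with pytest.raises(ValidationError):
            empirical_pdf(sig, [0.0, 1.0])
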