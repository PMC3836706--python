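"""Value models: dread accumulation, closed forms, utility fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dreadchoice as dc
from dreadchoice.valuation import weibull_utility


def brute_force_dread(x, T, gamma_p, gamma_d, alpha):
    """Term-by-term prospective dread sum (independent of the closed forms):
    moment t in 0..T-1 contributes gamma_d**t * gamma_p**(T-t) * u(x)."""
    return alpha * x * sum(gamma_d**t * gamma_p ** (T - t) for t in range(T))


class TestUtility:
    def test_linear_is_identity(self):
        spec = dc.ModelSpec("null")
        assert dc.utility(10.0, spec) == 10.0
        assert np.allclose(dc.utility([0, 3, 12], spec), [0, 3, 12])

    def test_weibull_values(self):
        wp = dc.WeibullUtilityParams(r_max=10, scale=5, shape=1)
        spec = dc.ModelSpec("null", utility_kind="weibull")
        assert dc.utility(0.0, spec, wp) == 0.0
        assert dc.utility(5.0, spec, wp) == pytest.approx(10 * (1 - np.e**-1),
                                                          abs=1e-4)

    def test_weibull_requires_params(self):
        with pytest.raises(ValueError):
            dc.utility(3.0, dc.ModelSpec("null", utility_kind="weibull"))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=20))
    def test_monotone_nondecreasing(self, xs):
        xs = np.sort(np.asarray(xs))
        wp = dc.WeibullUtilityParams(r_max=9, scale=8, shape=1.2)
        for spec in (dc.ModelSpec("null"),
                     dc.ModelSpec("null", utility_kind="weibull")):
            u = dc.utility(xs, spec, wp)
            assert np.all(np.diff(u) >= -1e-12)


class TestDread:
    @pytest.mark.parametrize("model", dc.MODEL_IDS)
    def test_zero_delay_means_zero_dread(self, model):
        params = dc.ModelParams(beta=1, gamma_p=0.9, gamma_d=0.8, alpha=0.7,
                                A=-5)
        assert dc.dread(10, 0, params, dc.ModelSpec(model)) == pytest.approx(0)

    def test_undiscounted_matches_brute_force(self):
        params = dc.ModelParams(beta=1, gamma_p=0.9, alpha=0.5)
        d = dc.dread(10, 5, params, dc.ModelSpec("undiscounted_dread"))
        assert d == pytest.approx(18.42795, abs=1e-4)
        assert d == pytest.approx(brute_force_dread(10, 5, 0.9, 1.0, 0.5),
                                  abs=1e-10)

    def test_restricted_closed_form(self):
        params = dc.ModelParams(beta=1, gamma_p=0.9, alpha=0.5)
        d = dc.dread(10, 5, params, dc.ModelSpec("restricted_dread"))
        assert d == pytest.approx(0.5 * 5 * 0.9**5 * 10, abs=1e-10)

    def test_closed_forms_equal_brute_force_everywhere(self):
        """General/undiscounted/restricted dread all agree with the explicit
        prospective sum to 1e-12 over a full (x, T, alpha, gamma) grid."""
        for x in (1.0, 7.0, 14.0):
            for T in (0, 1, 5, 23, 60):
                for alpha in (0.1, 0.5, 1.0):
                    for gp in (0.05, 0.5, 0.9, 0.99, 1.0):
                        for gd, model in ((1.0, "undiscounted_dread"),
                                          (gp, "restricted_dread"),
                                          (0.7, "general_dread")):
                            params = dc.ModelParams(beta=1, gamma_p=gp,
                                                    gamma_d=gd, alpha=alpha)
                            got = float(dc.dread(x, T, params,
                                                 dc.ModelSpec(model)))
                            want = brute_force_dread(x, T, gp, gd, alpha)
                            assert got == pytest.approx(want, abs=1e-9), \
                                (model, x, T, alpha, gp, gd)

    def test_restricted_equals_general_at_equal_rates(self):
        """The restricted model is exactly the general model at
        gamma_D = gamma_P (the stated simplification)."""
        for gp in (0.3, 0.8, 0.95):
            for T in range(0, 61, 7):
                for alpha in (0.2, 0.9):
                    p_r = dc.ModelParams(beta=1, gamma_p=gp, alpha=alpha)
                    p_g = dc.ModelParams(beta=1, gamma_p=gp, gamma_d=gp,
                                         alpha=alpha)
                    a = dc.dread(8.0, T, p_r, dc.ModelSpec("restricted_dread"))
                    b = dc.dread(8.0, T, p_g, dc.ModelSpec("general_dread"))
                    assert float(a) == pytest.approx(float(b), abs=1e-12)


class TestTotalValue:
    def pair(self, xs, ds, xl, dl):
        return dc.ChoicePair(dc.ChoiceOption(xs, ds), dc.ChoiceOption(xl, dl))

    def test_null_ignores_delay(self):
        params = dc.ModelParams(beta=1)
        spec = dc.ModelSpec("null")
        for T in (0, 5, 50):
            p = self.pair(10, min(T, 5), 10, T)
            assert dc.total_value(p, "later", params, spec) == -10

    def test_exponential_discounting(self):
        params = dc.ModelParams(beta=1, gamma_p=0.9)
        p = self.pair(10, 5, 10, 5)
        v = dc.total_value(p, "sooner", params, dc.ModelSpec("exp_discount"))
        assert v == pytest.approx(-5.9049, abs=1e-4)

    def test_undiscounted_dread_total(self):
        params = dc.ModelParams(beta=1, gamma_p=0.9, alpha=0.5)
        p = self.pair(10, 5, 10, 5)
        v = dc.total_value(p, "sooner", params, dc.ModelSpec("undiscounted_dread"))
        assert v == pytest.approx(-24.3329, abs=1e-3)

    def test_values_are_nonpositive(self):
        rng = np.random.default_rng(0)
        for model in dc.MODEL_IDS:
            spec = dc.ModelSpec(model)
            for _ in range(20):
                params = dc.ModelParams(beta=1, gamma_p=rng.uniform(0, 1),
                                        gamma_d=rng.uniform(0, 1),
                                        alpha=rng.uniform(0, 1),
                                        A=-rng.uniform(0, 50))
                p = self.pair(rng.uniform(3, 12), 4, rng.uniform(3, 12), 20)
                for which in ("sooner", "later"):
                    assert dc.total_value(p, which, params, spec) <= 1e-12

    def test_fixed_delay_cost_conventions(self):
        params = dc.ModelParams(beta=1, gamma_p=1.0, A=-5)
        rel = dc.ModelSpec("fixed_delay_cost", delay_cost_convention="relative")
        ab = dc.ModelSpec("fixed_delay_cost", delay_cost_convention="absolute")
        p = self.pair(10, 4, 10, 20)  # both options delayed
        # relative: A hits only the strictly later option
        assert dc.total_value(p, "sooner", params, rel) == -10
        assert dc.total_value(p, "later", params, rel) == -15
        # absolute: A hits every delayed option
        assert dc.total_value(p, "sooner", params, ab) == -15
        assert dc.total_value(p, "later", params, ab) == -15
        today = self.pair(10, 0, 10, 20)
        assert dc.total_value(today, "sooner", params, ab) == -10

    def test_alpha_zero_collapses_dread_models(self):
        params = dc.ModelParams(beta=1, gamma_p=0.8, gamma_d=0.5, alpha=0.0)
        p = self.pair(7, 4, 9, 30)
        ref = dc.total_value(p, "later", params, dc.ModelSpec("exp_discount"))
        for model in ("constant_dread", "undiscounted_dread",
                      "restricted_dread", "general_dread"):
            assert dc.total_value(p, "later", params,
                                  dc.ModelSpec(model)) == pytest.approx(ref)

    def test_gamma_one_alpha_zero_is_null(self):
        params = dc.ModelParams(beta=1, gamma_p=1.0, alpha=0.0)
        p = self.pair(7, 4, 9, 30)
        for model in ("exp_discount", "undiscounted_dread", "general_dread"):
            assert dc.total_value(p, "later", params, dc.ModelSpec(model)) == -9


class TestShapeProperties:
    def aversiveness(self, model, gp, alpha, T):
        params = dc.ModelParams(beta=1, gamma_p=gp, alpha=alpha)
        p = dc.ChoicePair(dc.ChoiceOption(10, 0), dc.ChoiceOption(10, int(T)))
        return -dc.total_value(p, "later", params, dc.ModelSpec(model))

    @pytest.mark.parametrize("gp,alpha", [(0.8, 0.3), (0.9, 0.5), (0.95, 1.0)])
    def test_undiscounted_monotone_and_saturating(self, gp, alpha):
        vals = np.array([self.aversiveness("undiscounted_dread", gp, alpha, T)
                         for T in range(0, 61)])
        assert np.all(np.diff(vals) >= -1e-10)  # aversion never decreases
        bound = 10 * (1 + alpha * gp / (1 - gp))
        assert np.all(vals <= bound + 1e-9)
        # saturation: aversion grows at a strictly diminishing rate
        assert np.all(np.diff(vals, 2) <= 1e-9)
        assert vals[60] - vals[50] < 0.3 * (vals[10] - vals[0])

    @pytest.mark.parametrize("gp,alpha", [(0.9, 0.5), (0.93, 0.5), (0.85, 0.8)])
    def test_restricted_interior_maximum_location(self, gp, alpha):
        """Brute-force scan: the integer maximizer of (1+alpha*T)*gamma**T
        lies within 1 of the continuous stationary point."""
        vals = [self.aversiveness("restricted_dread", gp, alpha, T)
                for T in range(0, 200)]
        t_star = -1.0 / np.log(gp) - 1.0 / alpha
        assert t_star > 0
        assert abs(int(np.argmax(vals)) - t_star) <= 1


class TestWeibullFit:
    def test_noiseless_recovery(self):
        wp = dc.WeibullUtilityParams(r_max=9, scale=8, shape=1.2)
        mags = np.arange(2, 15)
        ratings = list(zip(mags, weibull_utility(mags, wp)))
        est = dc.fit_weibull_utility(ratings)
        assert est.r_max == pytest.approx(9, abs=1e-3)
        assert est.scale == pytest.approx(8, abs=1e-3)
        assert est.shape == pytest.approx(1.2, abs=1e-3)

    def test_flat_ratings_warn_and_fit_level(self):
        ratings = [(x, 0.0) for x in range(2, 15, 2)]
        with pytest.warns(UserWarning):
            est = dc.fit_weibull_utility(ratings)
        assert weibull_utility(10.0, est) == pytest.approx(0.0, abs=1e-6)

    def test_beats_coarse_grid_on_linear_ratings(self):
        mags = np.arange(2, 15, dtype=float)
        ratings = list(zip(mags, mags))  # perfectly linear ratings
        est = dc.fit_weibull_utility(ratings)
        rss_fit = float(np.sum((weibull_utility(mags, est) - mags) ** 2))
        # independent coarse-grid oracle
        best_grid = np.inf
        for r_max in np.linspace(5, 40, 12):
            for scale in np.linspace(2, 40, 12):
                for shape in np.linspace(0.3, 3, 10):
                    wp = dc.WeibullUtilityParams(r_max, scale, shape)
                    rss = float(np.sum((weibull_utility(mags, wp) - mags) ** 2))
                    best_grid = min(best_grid, rss)
        assert rss_fit <= best_grid + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dc.fit_weibull_utility([(2, 1.0), (4, 2.0)])
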