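import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from netaging import (
    GompertzParams,
    MechanisticNetworkSpec,
    NetworkAgingParams,
    WeibullParams,
    decay_rate_from_t0,
    gompertz_coefficient,
    gompertz_model,
    module_hazard,
    module_hazard_early,
    module_survival,
    network_density,
    network_hazard,
    network_hazard_binomial,
    network_survival,
    phenomenological_from_mechanistic,
    weibull_model,
)


class TestParameterValidation:
    def test_network_params_reject_bad_values(self):
        with pytest.raises(ValueError):
            NetworkAgingParams(R=-0.01, t0=50, n=7)
        with pytest.raises(ValueError):
            NetworkAgingParams(R=0.01, t0=0, n=7)
        with pytest.raises(ValueError):
            NetworkAgingParams(R=0.01, t0=50, n=1.0)  # constant-hazard degenerate
        with pytest.raises(ValueError):
            NetworkAgingParams(R=0.01, t0=np.inf, n=7)

    def test_mechanistic_spec_validation(self):
        with pytest.raises(ValueError):
            MechanisticNetworkSpec(m=0, n=7, p=0.7, lam=0.01)
        with pytest.raises(ValueError):
            MechanisticNetworkSpec(m=10, n=7.5, p=0.7, lam=0.01)
        with pytest.raises(ValueError):
            MechanisticNetworkSpec(m=10, n=7, p=0.0, lam=0.01)
        with pytest.raises(ValueError):
            MechanisticNetworkSpec(m=10, n=7, p=0.7, lam=0.0)

    def test_normalizing_constant(self):
        spec = MechanisticNetworkSpec(m=10, n=3, p=0.5, lam=0.01)
        assert spec.c == pytest.approx(1.0 / (1.0 - 0.5**3))
        assert spec.c >= 1.0
        assert MechanisticNetworkSpec(m=10, n=3, p=1.0, lam=0.01).c == 1.0

    def test_gompertz_weibull_validation(self):
        with pytest.raises(ValueError):
            GompertzParams(R=0.0, G=0.1)
        with pytest.raises(ValueError):
            GompertzParams(R=0.01, G=-0.1)
        GompertzParams(R=0.01, G=0.0)  # exponential limit allowed
        with pytest.raises(ValueError):
            WeibullParams(shape=0, scale=10)


class TestModuleFunctions:
    def test_survival_n1_is_exponential(self):
        assert module_survival(0.01, 1, 10.0) == pytest.approx(np.exp(-0.1))

    def test_survival_at_zero(self):
        assert module_survival(0.02, 5, 0.0) == 1.0

    def test_survival_arithmetic(self):
        expected = 1 - (1 - np.exp(-0.5)) ** 3
        assert module_survival(0.01, 3, 50.0) == pytest.approx(expected, rel=1e-12)

    def test_survival_domain_errors(self):
        with pytest.raises(ValueError):
            module_survival(0.0, 3, 10.0)
        with pytest.raises(ValueError):
            module_survival(0.01, 0, 10.0)
        with pytest.raises(ValueError):
            module_survival(0.01, 3, -1.0)

    @given(
        lam=st.floats(1e-4, 1e-1),
        n=st.integers(1, 12),
        t1=st.floats(0.0, 500.0),
        t2=st.floats(0.0, 500.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_survival_monotone_nonincreasing(self, lam, n, t1, t2):
        lo, hi = sorted([t1, t2])
        assert module_survival(lam, n, lo) >= module_survival(lam, n, hi)

    def test_hazard_zero_at_birth_for_redundant_module(self):
        assert module_hazard(0.01, 5, 0.0) == 0.0

    def test_hazard_constant_for_single_component(self):
        for t in (0.0, 13.0, 200.0):
            assert module_hazard(0.01, 1, t) == pytest.approx(0.01)

    def test_hazard_matches_numerical_log_derivative(self):
        lam, n, t, h = 0.01, 3, 50.0, 1e-4
        fd = -(
            np.log(module_survival(lam, n, t + h)) - np.log(module_survival(lam, n, t - h))
        ) / (2 * h)
        assert module_hazard(lam, n, t) == pytest.approx(fd, rel=1e-6)

    def test_hazard_overflow_diagnostic(self):
        with pytest.raises(OverflowError):
            module_hazard(1.0, 2, 1e6)

    def test_early_hazard_reduces_to_lambda(self):
        assert module_hazard_early(0.01, 1, 7.0) == pytest.approx(0.01)

    def test_early_hazard_arithmetic(self):
        assert module_hazard_early(0.01, 3, 5.0) == pytest.approx(7.5e-5)

    def test_early_hazard_close_to_exact_when_lam_t_small(self):
        lam, n = 0.001, 4
        t = np.linspace(1.0, 10.0, 10)  # lam*t <= 0.01
        exact = module_hazard(lam, n, t)
        early = module_hazard_early(lam, n, t)
        assert np.all(np.abs(early - exact) / exact < 0.05)


class TestNetworkHazard:
    def test_binomial_p1_reduces_to_m_copies_of_early_module(self):
        spec = MechanisticNetworkSpec(m=100, n=4, p=1.0, lam=0.01)
        t = 12.0
        expected = 100 * 4 * 0.01 * (0.01 * t) ** 3
        assert network_hazard_binomial(spec, t) == pytest.approx(expected, rel=1e-12)

    def test_binomial_single_term(self):
        spec = MechanisticNetworkSpec(m=1, n=1, p=0.5, lam=0.01)
        assert network_hazard_binomial(spec, 10.0) == pytest.approx(0.01)

    def test_binomial_warns_beyond_validity(self):
        spec = MechanisticNetworkSpec(m=10, n=3, p=0.5, lam=0.01)
        with pytest.warns(RuntimeWarning):
            network_hazard_binomial(spec, 150.0)

    def test_hazard_at_birth_is_R(self, by4742_params):
        assert network_hazard(by4742_params, 0.0) == by4742_params.R

    def test_hazard_at_t0(self, by4742_params):
        assert network_hazard(by4742_params, 56.2) == pytest.approx(
            0.0047 * 2**6.9, rel=1e-12
        )

    def test_hazard_strictly_increasing(self, by4742_params):
        t = np.linspace(0, 200, 500)
        assert np.all(np.diff(network_hazard(by4742_params, t)) > 0)

    @pytest.mark.parametrize("n", [2, 3, 5, 8, 12])
    @pytest.mark.parametrize("p", [0.2, 0.5, 0.9])
    def test_binomial_sum_equals_closed_form(self, n, p):
        lam = 0.01
        spec = MechanisticNetworkSpec(m=100, n=n, p=p, lam=lam)
        params = phenomenological_from_mechanistic(spec)
        t = np.linspace(0.0, 0.2 / lam, 25)
        mu_sum = network_hazard_binomial(spec, t)
        mu_closed = network_hazard(params, t)
        np.testing.assert_allclose(mu_sum, mu_closed, rtol=1e-10)

    def test_gompertz_limit_small_t(self, by4742_params):
        G = gompertz_coefficient(by4742_params)
        t = np.linspace(0, by4742_params.t0 / 20, 50)
        mu = network_hazard(by4742_params, t)
        approx = by4742_params.R * np.exp(G * t)
        assert np.all(np.abs(mu - approx) / mu < 0.02)


class TestNetworkSurvivalDensity:
    def test_survival_one_at_birth(self, by4742_params):
        assert network_survival(by4742_params, 0.0) == 1.0

    def test_survival_arithmetic(self, by4742_params):
        expected = np.exp(
            (0.0047 * 56.2 / 7.9) * (1 - (1 + 26.6 / 56.2) ** 7.9)
        )
        assert network_survival(by4742_params, 26.6) == pytest.approx(expected, rel=1e-12)

    def test_survival_decreasing_to_zero(self, by4742_params):
        t = np.linspace(0, 400, 200)
        s = network_survival(by4742_params, t)
        positive = s > 0
        assert np.all(np.diff(s[positive]) < 0)  # strictly decreasing until underflow
        assert positive.sum() < t.size  # and it does underflow in this range
        assert network_survival(by4742_params, 1e6) == 0.0

    def test_neg_log_survival_equals_hazard_integral(self, by4742_params):
        for t_end in (10.0, 40.0, 90.0):
            integral, _ = quad(
                lambda u: network_hazard(by4742_params, u), 0, t_end, limit=200
            )
            assert -np.log(network_survival(by4742_params, t_end)) == pytest.approx(
                integral, rel=1e-6
            )

    def test_density_at_birth_is_R(self, by4742_params):
        assert network_density(by4742_params, 0.0) == pytest.approx(by4742_params.R)

    def test_density_integrates_to_one(self, by4742_params):
        total, _ = quad(
            lambda u: network_density(by4742_params, u),
            0,
            10 * by4742_params.t0,
            limit=400,
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_density_over_survival_is_hazard(self, by4742_params):
        t = np.linspace(0.0, 120.0, 40)
        f = network_density(by4742_params, t)
        s = network_survival(by4742_params, t)
        np.testing.assert_allclose(f / s, network_hazard(by4742_params, t), rtol=1e-10)


class TestReferenceModels:
    def test_gompertz_exponential_limit(self):
        _, survival, _ = gompertz_model(GompertzParams(R=0.01, G=0.0), 100.0)
        assert survival == pytest.approx(np.exp(-1.0))

    def test_gompertz_at_birth(self):
        hazard, survival, density = gompertz_model(GompertzParams(R=0.02, G=0.1), 0.0)
        assert hazard == pytest.approx(0.02)
        assert survival == 1.0
        assert density == pytest.approx(0.02)

    def test_gompertz_quadrature(self):
        p = GompertzParams(R=0.005, G=0.1)
        for t_end in (10.0, 30.0, 60.0):
            integral, _ = quad(lambda u: gompertz_model(p, u).hazard, 0, t_end)
            assert -np.log(gompertz_model(p, t_end).survival) == pytest.approx(
                integral, rel=1e-6
            )

    def test_weibull_exponential_special_case(self):
        p = WeibullParams(shape=1.0, scale=10.0)
        for t in (0.0, 5.0, 42.0):
            assert weibull_model(p, t).hazard == pytest.approx(0.1)

    def test_weibull_survival_at_scale(self):
        assert weibull_model(WeibullParams(2.0, 10.0), 10.0).survival == pytest.approx(
            np.exp(-1.0)
        )

    def test_weibull_infinite_hazard_flag(self):
        assert weibull_model(WeibullParams(0.5, 10.0), 0.0).hazard == np.inf

    def test_weibull_density_integrates_to_one(self):
        p = WeibullParams(shape=2.5, scale=30.0)
        total, _ = quad(lambda u: weibull_model(p, u).density, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_weibull_matches_scipy(self):
        # independent cross-check of the shape/scale convention
        p = WeibullParams(shape=3.0, scale=25.0)
        t = np.linspace(0.5, 80.0, 30)
        out = weibull_model(p, t)
        np.testing.assert_allclose(
            out.density, stats.weibull_min.pdf(t, 3.0, scale=25.0), rtol=1e-10
        )
        np.testing.assert_allclose(
            out.survival, stats.weibull_min.sf(t, 3.0, scale=25.0), rtol=1e-10
        )


class TestMappings:
    def test_gompertz_coefficient_examples(self):
        assert gompertz_coefficient(
            NetworkAgingParams(0.0047, 56.2, 7.9)
        ) == pytest.approx(6.9 / 56.2)
        assert gompertz_coefficient(
            NetworkAgingParams(0.0025, 36.0, 6.7)
        ) == pytest.approx(5.7 / 36.0)
        # n -> 1 gives G -> 0 (non-aging limit)
        assert gompertz_coefficient(NetworkAgingParams(0.01, 50.0, 1.0 + 1e-9)) < 1e-9

    def test_t0_from_p_half(self):
        spec = MechanisticNetworkSpec(m=10, n=3, p=0.5, lam=0.01)
        assert phenomenological_from_mechanistic(spec).t0 == pytest.approx(100.0)

    def test_R_matches_binomial_sum_at_zero(self):
        spec = MechanisticNetworkSpec(m=1000, n=7, p=0.7, lam=0.0123)
        params = phenomenological_from_mechanistic(spec)
        assert params.R == pytest.approx(network_hazard_binomial(spec, 0.0), rel=1e-10)

    def test_p_one_is_degenerate(self):
        spec = MechanisticNetworkSpec(m=10, n=3, p=1.0, lam=0.01)
        with pytest.raises(ValueError):
            phenomenological_from_mechanistic(spec)

    def test_decay_rate_round_trip(self):
        spec = MechanisticNetworkSpec(m=10, n=5, p=0.7, lam=0.0042)
        params = phenomenological_from_mechanistic(spec)
        back = decay_rate_from_t0(params.t0, 0.7)
        assert back.lam == pytest.approx(0.0042, rel=1e-12)

    def test_decay_rate_examples(self):
        assert decay_rate_from_t0(45.4, 0.7).tau == pytest.approx(105.93, abs=0.01)
        assert decay_rate_from_t0(74.0, 0.9).tau == pytest.approx(666.0)
        assert decay_rate_from_t0(33.0, 0.5).tau == pytest.approx(33.0)

    def test_decay_rate_domain(self):
        with pytest.raises(ValueError):
            decay_rate_from_t0(50.0, 1.0)
        with pytest.raises(ValueError):
            decay_rate_from_t0(50.0, 0.0)

    def test_smaller_G_means_larger_t0_means_smaller_lambda(self):
        # monotone chain: G -> 0 forces t0 -> inf forces lam -> 0
        p = 0.7
        g_values = [0.3, 0.1, 0.03, 0.01]
        t0s = [(7.0 - 1.0) / g for g in g_values]
        lams = [decay_rate_from_t0(t0, p).lam for t0 in t0s]
        assert all(a < b for a, b in zip(t0s, t0s[1:]))
        assert all(a > b for a, b in zip(lams, lams[1:]))
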