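"""Pivot normalization, series coefficients, and the closed-form fit."""



import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

import weibull_perturb as wp
from weibull_perturb.perturbation import _compositions

from conftest import random_censored_sample


def make_sample(times, events=None):
    times = np.asarray(times, dtype=float)
    if events is None:
        events = np.ones_like(times, dtype=int)
    return wp.LifetimeSample(times=times, events=np.asarray(events))


TWO_POINT = make_sample([1.0, np.e])


@st.composite
def lifetime_samples(draw):
    """Valid complete samples with spread-out positive times."""
    times = draw(
        st.lists(
            st.floats(0.01, 1e4, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=40,
            unique=True,
        )
    )
    return make_sample(times)


class TestPivotAndNormalization:
    def test_beta1_two_point(self):
        assert wp.beta1(TWO_POINT) == pytest.approx(2.0)

    def test_beta1_case1(self, case1):
        # frozen from direct summation; consistent with the published
        # beta*/zeta* ratio
        assert wp.beta1(case1) == pytest.approx(1.33561, abs=1e-5)

    def test_beta1_equals_inverse_log_gap(self, case1):
        expected = 1.0 / (np.log(case1.t_max) - wp.log_tau(case1))
        assert wp.beta1(case1) == pytest.approx(expected)

    def test_degenerate_all_failures_at_max_rejected(self):
        with pytest.raises(wp.DegenerateSampleError):
            make_sample([1.0, 5.0, 5.0], [0, 1, 1])

    def test_normalize_two_point(self):
        norm = wp.normalize(TWO_POINT)
        np.testing.assert_allclose(norm.x, [np.exp(-2.0), 1.0])
        assert norm.beta1 == pytest.approx(2.0)
        assert norm.m_index == 1

    @given(lifetime_samples())
    @settings(max_examples=100, deadline=None)
    def test_normalize_invariants(self, sample):
        norm = wp.normalize(sample)
        assert norm.x[-1] == 1.0
        assert np.all(norm.x > 0) and np.all(norm.x <= 1)
        assert np.all(np.diff(norm.x) >= 0)
        assert 1 <= norm.m_index <= sample.N - 1


class TestSigmaCoefficients:
    @given(lifetime_samples())
    @settings(max_examples=100, deadline=None)
    def test_sigma1_is_one_identically(self, sample):
        norm = wp.normalize(sample)
        assert wp.sigma_m(norm, 1) == pytest.approx(1.0, abs=1e-14)

    def test_case1_published_values(self, case1):
        norm = wp.normalize(case1)
        expected = {0: -0.2244, 2: -0.3397, 3: 0.3617, 4: -0.3320}
        for m, value in expected.items():
            assert wp.sigma_m(norm, m) == pytest.approx(value, abs=5e-4)

    @given(lifetime_samples())
    @settings(max_examples=100, deadline=None)
    def test_sigma0_in_unit_interval(self, sample):
        # the small-parameter requirement 0 < -sigma_0 < 1, checked at
        # runtime rather than assumed
        s0 = wp.sigma_m(wp.normalize(sample), 0)
        assert -1.0 < s0 < 0.0

    def test_negative_m_rejected(self, case1):
        with pytest.raises(ValueError):
            wp.sigma_m(wp.normalize(case1), -1)


def xi_sympy(sigma, Q):
    """Independent symbolic oracle: expand the series equation in epsilon
    and solve the vanishing-coefficient equations one by one."""
    eps = sympy.Symbol("eps")
    xi_syms = sympy.symbols(f"xi1:{Q + 1}")
    z = sum(eps ** q * xi_syms[q - 1] for q in range(1, Q + 1))
    expr = -eps + sum(
        sympy.Rational(1) * sigma[m] * z**m / sympy.factorial(m)
        for m in range(1, Q + 1)
    )
    poly = sympy.Poly(sympy.expand(expr), eps)
    solution = {}
    for q in range(1, Q + 1):
        coeff = poly.coeff_monomial(eps**q).subs(solution)
        solution[xi_syms[q - 1]] = sympy.solve(coeff, xi_syms[q - 1])[0]
    return [solution[s] for s in xi_syms]


class TestXiCoefficients:
    def test_closed_forms_symbolically(self):
        # the general composition recursion must reproduce the explicit
        # order-4 formulas coefficient by coefficient
        s2, s3, s4 = sympy.symbols("sigma2 sigma3 sigma4")
        expected = [
            sympy.Integer(1),
            -s2 / 2,
            s2**2 / 2 - s3 / 6,
            -5 * s2**3 / 8 + 5 * s3 * s2 / 12 - s4 / 24,
        ]
        got = xi_sympy([None, sympy.Integer(1), s2, s3, s4], 4)
        for g, e in zip(got, expected):
            assert sympy.simplify(g - e) == 0

    def test_recursion_matches_symbolic_oracle_at_order_6(self):
        rng = np.random.default_rng(7)
        raw = rng.uniform(-1, 1, size=7)
        raw[1] = 1.0
        sigmas = wp.SigmaCoefficients(sigma=raw, order=6)
        got = wp.xi_coefficients(sigmas, 6)
        sym = [None, sympy.Integer(1)] + [sympy.Rational(v).limit_denominator(10**9)
                                          for v in raw[2:]]
        expected = [float(v) for v in xi_sympy(sym, 6)]
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_xi1_is_one(self, case1):
        sigmas = wp.sigma_coefficients(wp.normalize(case1), 4)
        assert wp.xi_coefficients(sigmas)[0] == pytest.approx(1.0)

    def test_higher_sigmas_zero_gives_zero_xi(self):
        sigmas = wp.SigmaCoefficients(sigma=np.array([-0.3, 1.0, 0, 0, 0]), order=4)
        np.testing.assert_array_equal(wp.xi_coefficients(sigmas)[1:], 0.0)

    def test_compositions_enumeration(self):
        assert _compositions(3, 2) == ((1, 2), (2, 1))
        assert len(_compositions(6, 3)) == 10  # C(5, 2) ordered compositions

    def test_order_must_be_positive(self):
        sigmas = wp.SigmaCoefficients(sigma=np.array([-0.3, 1.0]), order=1)
        with pytest.raises(ValueError):
            wp.xi_coefficients(sigmas, 0)


class TestSolveZ:
    def test_series_collapses_without_higher_sigmas(self):
        sigmas = wp.SigmaCoefficients(sigma=np.array([-0.3, 1.0, 0, 0, 0]), order=4)
        sol = wp.solve_z(sigmas)
        assert sol.z == pytest.approx(0.3)
        assert sol.zeta_star == pytest.approx(1.3)
        assert sol.series_valid

    def test_z_reproduced_from_parts(self, case1):
        sol = wp.fit(case1).solution
        powers = sol.epsilon ** np.arange(1, sol.order + 1)
        assert sol.z == pytest.approx(float(powers @ sol.xi))

    def test_out_of_range_epsilon_warns(self):
        sigmas = wp.SigmaCoefficients(sigma=np.array([0.2, 1.0, 0.1]), order=2)
        with pytest.warns(wp.SmallParameterWarning):
            sol = wp.solve_z(sigmas)
        assert not sol.series_valid

    def test_truncation_order_improves_accuracy(self, case1):
        # |Z| at the series root shrinks as the truncation order grows
        norm = wp.normalize(case1)
        nr = wp.newton_raphson_fit(case1, beta0=2.0, tol=1e-12)
        zeta_exact = nr.params.beta / norm.beta1
        sigmas = wp.sigma_coefficients(norm, 4)
        err_q1 = abs(wp.solve_z(sigmas, 1).zeta_star - zeta_exact)
        err_q4 = abs(wp.solve_z(sigmas, 4).zeta_star - zeta_exact)
        assert err_q4 < err_q1


class TestFit:
    def test_case1_published_estimates(self, case1):
        fit = wp.fit(case1)
        assert fit.params.beta == pytest.approx(1.6466, abs=5e-4)
        assert fit.params.alpha == pytest.approx(162.22306, abs=5e-2)
        assert fit.solution.series_valid
        assert fit.warnings == ()

    def test_case2_published_estimates(self, case2):
        fit = wp.fit(case2)
        assert fit.params.beta == pytest.approx(3.205, abs=5e-3)
        assert fit.params.alpha == pytest.approx(35.245, abs=5e-2)

    def test_zeta_star_exceeds_one(self, case1, case2, rng):
        samples = [case1, case2] + [random_censored_sample(rng) for _ in range(20)]
        for s in samples:
            assert wp.fit(s).solution.zeta_star > 1.0

    def test_agrees_with_newton_raphson(self, case1, case2, rng):
        samples = [case1, case2] + [random_censored_sample(rng) for _ in range(20)]
        for s in samples:
            fit = wp.fit(s)
            if abs(fit.sigmas.sigma[0]) >= 0.5:
                continue
            nr = wp.newton_raphson_fit(s, tol=1e-10)
            assert fit.params.beta == pytest.approx(nr.params.beta, rel=0.05)

    def test_recovers_generating_parameters(self):
        # 100 time-censored samples of size 500 from W(3, 1.5): the mean
        # shape estimate must sit within 3 standard errors of the truth.
        # (The censored design is the regime the series targets: the
        # common censoring time caps t_N, keeping epsilon well below 1.)
        config = wp.SimulationConfig(M=500, p=0.8, eta=100, seed=42)
        rng = np.random.default_rng(config.seed)
        betas = [wp.fit(wp.generate_sample(config, rng)).params.beta
                 for _ in range(config.eta)]
        betas = np.asarray(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 1.5) < 3 * se
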