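"""Intensity families, scaling families and their Laplace transforms."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from siphtool import (
    CompoundPoissonGamma,
    Degenerate,
    DiscreteScaling,
    GammaScaling,
    InverseGaussianScaling,
    InverseStable,
    PHRepresentation,
    PositiveStable,
    PVFScaling,
    make_intensity,
    make_scaling,
    ph_frac_moment,
)
from siphtool.matfun import kron_sum, mat_exp, mat_frac_power, mat_fun

INTENSITIES = [
    ("constant", ()),
    ("pareto", (1.7,)),
    ("weibull", (0.8,)),
    ("weibull", (2.3,)),
    ("lognormal", (2.5,)),
    ("loglogistic", (1.4, 2.0)),
    ("gompertz", (0.6,)),
]

SCALINGS_WITH_DENSITY = [
    GammaScaling(1.7),
    PositiveStable(0.6),
    InverseStable(0.75),
    InverseGaussianScaling(0.8),
]

ALL_SCALINGS = SCALINGS_WITH_DENSITY + [
    Degenerate(2.0),
    PVFScaling(1.5, 0.5),
    CompoundPoissonGamma(2.0, 1.2),
    DiscreteScaling([0.5, 1.0, 3.0], [0.3, 0.5, 0.2]),
]


@pytest.mark.parametrize("family,params", INTENSITIES)
class TestIntensityFamilies:
    def test_h_and_inverse_are_inverse(self, family, params):
        it = make_intensity(family, params)
        y = np.geomspace(0.01, 50.0, 40)
        np.testing.assert_allclose(it.h(it.h_inv(y)), y, rtol=1e-9)
        z = np.geomspace(0.01, 20.0, 40)
        np.testing.assert_allclose(it.h_inv(it.h(z)), z, rtol=1e-9)

    def test_lambda_is_derivative_of_h_inv(self, family, params):
        it = make_intensity(family, params)
        y = np.geomspace(0.1, 10.0, 25)
        eps = 1e-6 * y
        num = (it.h_inv(y + eps) - it.h_inv(y - eps)) / (2 * eps)
        np.testing.assert_allclose(it.lam(y), num, rtol=1e-5)

    def test_h_inv_finite_and_increasing_to_infinity(self, family, params):
        it = make_intensity(family, params)
        y = np.geomspace(1e-6, 50.0, 30)
        v = it.h_inv(y)
        assert np.all(np.isfinite(v))
        assert np.all(np.diff(v) > 0)


class TestIntensityDomains:
    @pytest.mark.parametrize("family,params", [
        ("pareto", (0.0,)), ("weibull", (-1.0,)), ("lognormal", (1.0,)),
        ("loglogistic", (0.0, 1.0)), ("gompertz", (0.0,)),
    ])
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValueError):
            make_intensity(family, params)


class TestLaplaceScalar:
    @pytest.mark.parametrize("fam", ALL_SCALINGS, ids=lambda f: f.family)
    def test_at_zero_is_one(self, fam):
        assert fam.laplace(0.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("fam", ALL_SCALINGS, ids=lambda f: f.family)
    def test_completely_monotone_on_grid(self, fam):
        u = np.linspace(0.0, 8.0, 200)
        L = fam.laplace(u)
        assert np.all(L > 0) and np.all(L <= 1.0 + 1e-12)
        assert np.all(np.diff(L) <= 1e-12)          # decreasing
        assert np.all(np.diff(L, 2) >= -1e-10)      # convex

    def test_gamma_value(self):
        assert GammaScaling(1.0).laplace(1.0) == pytest.approx(0.5)

    def test_stable_value(self):
        assert PositiveStable(0.5).laplace(4.0) == pytest.approx(
            math.exp(-2.0), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            PositiveStable(0.5).laplace(-0.1)
        # gamma admits u >= -1
        assert GammaScaling(2.0).laplace(-0.5) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            GammaScaling(2.0).laplace(-1.5)

    def test_compound_poisson_cure_mass(self):
        fam = CompoundPoissonGamma(2.0, 1.2)
        assert fam.laplace(1e6) == pytest.approx(math.exp(-2.0), rel=1e-4)

    def test_mml_mixing_laplace_is_mittag_leffler(self):
        # E[exp(-u S^-a)] = E_a(-u): check against the series for small u
        fam = InverseStable(0.7)
        for u in (0.1, 0.5, 1.5):
            k = np.arange(0, 120)
            from scipy.special import gamma as G
            series = np.sum((-u) ** k / G(0.7 * k + 1.0))
            assert fam.laplace(u) == pytest.approx(series, abs=1e-7)


class TestLaplaceDerivatives:
    def test_gamma_first_derivative_at_zero(self):
        assert GammaScaling(1.0).laplace_deriv(0.0, 1) == pytest.approx(-1.0)

    def test_gamma_second_derivative_moment(self):
        assert GammaScaling(1.5).laplace_deriv(0.0, 2) == pytest.approx(3.75)

    @pytest.mark.parametrize("fam", ALL_SCALINGS, ids=lambda f: f.family)
    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_matches_finite_differences(self, fam, d):
        # ladder check: L^(d) is the central difference of L^(d-1)
        u0, h = 0.8, 1e-4
        lower = (fam.laplace if d == 1
                 else lambda u: fam.laplace_deriv(u, d - 1))
        num = (lower(u0 + h) - lower(u0 - h)) / (2 * h)
        exact = fam.laplace_deriv(u0, d)
        assert num == pytest.approx(exact, rel=1e-5, abs=1e-9)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            PositiveStable(0.6).laplace_deriv(1.0, 5)


class TestLaplaceMatrix:
    def test_zero_matrix_gives_identity(self):
        for fam in (GammaScaling(2.0), PositiveStable(0.7)):
            np.testing.assert_allclose(
                fam.laplace_matrix(np.zeros((3, 3))), np.eye(3), atol=1e-9)

    def test_gamma_matrix_form(self, rng):
        fam = GammaScaling(1.3)
        A = rng.normal(size=(3, 3))
        A = A + 3.5 * np.eye(3)  # spectrum to the right of -1
        lhs = fam.laplace_matrix(A)
        lam, V = np.linalg.eig(A)
        rhs = (V * (1.0 + lam) ** (-1.3)) @ np.linalg.inv(V)
        np.testing.assert_allclose(lhs, rhs.real, atol=1e-9)

    def test_stable_two_route(self, ph3):
        # pi L(-c T) e equals pi exp(-(-T)^a c^a) e
        fam = PositiveStable(0.65)
        c = 1.7
        lhs = float(ph3.pi @ fam.laplace_matrix(-c * ph3.T) @ np.ones(3))
        frac = mat_frac_power(-ph3.T, 0.65)
        rhs = float(ph3.pi @ mat_exp(-frac * c**0.65) @ np.ones(3))
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_scalar_reduction(self):
        fam = GammaScaling(2.0)
        out = fam.laplace_matrix(np.array([[1.5]]))
        assert out[0, 0] == pytest.approx(fam.laplace(1.5), rel=1e-12)


class TestDensities:
    def test_gamma_density_value(self):
        assert GammaScaling(1.0).density(0.5) == pytest.approx(math.exp(-0.5))

    def test_inverse_gaussian_mean_identity(self):
        fam = InverseGaussianScaling(1.0)  # nu = 1, eta = 1
        val, err = quad(lambda t: t * fam.density(np.array(t)), 0, np.inf,
                        limit=200)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_stable_levy_closed_form(self):
        # alpha = 1/2: f(t) = (2 sqrt(pi))^-1 t^-3/2 exp(-1/(4t))
        fam = PositiveStable(0.5)
        t = np.array([0.2, 0.5, 1.0, 3.0])
        closed = t ** (-1.5) * np.exp(-1.0 / (4.0 * t)) / (2 * math.sqrt(math.pi))
        np.testing.assert_allclose(fam.density(t), closed, atol=1e-6)

    @pytest.mark.parametrize("fam", SCALINGS_WITH_DENSITY,
                             ids=lambda f: f.family)
    def test_density_integrates_to_one(self, fam):
        val, err = quad(lambda t: float(fam.density(np.array(t))),
                        0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_point_mass_families_signal_by_type(self):
        with pytest.raises(TypeError):
            Degenerate(2.0).density(1.0)
        pm = Degenerate(2.0).point_masses()
        assert pm.points == (2.0,) and pm.weights == (1.0,)
        with pytest.raises(TypeError):
            DiscreteScaling([1.0], [1.0]).density(1.0)


class TestSamplers:
    def test_degenerate(self, rng):
        np.testing.assert_array_equal(Degenerate(2.0).sample(3, rng),
                                      [2.0, 2.0, 2.0])

    def test_gamma_moment(self, rng):
        x = GammaScaling(2.0).sample(100_000, rng)
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - 2.0) < 3 * se

    def test_stable_laplace_transform_monte_carlo(self, rng):
        x = PositiveStable(0.6).sample(100_000, rng)
        emp = np.exp(-x)
        se = emp.std() / math.sqrt(x.size)
        assert abs(emp.mean() - math.exp(-1.0)) < 3 * se

    @pytest.mark.parametrize("fam", [GammaScaling(1.0),
                                     InverseGaussianScaling(0.7),
                                     InverseStable(0.8)],
                             ids=lambda f: f.family)
    def test_unit_scale_sample_mean(self, fam, rng):
        x = fam.sample(100_000, rng)
        assert np.all(x >= 0)
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - fam.mean()) < 3 * se

    def test_empirical_laplace_matches(self, rng):
        for fam in (GammaScaling(0.8), InverseGaussianScaling(1.3),
                    CompoundPoissonGamma(1.5, 1.0)):
            x = fam.sample(60_000, rng)
            for u in (0.3, 1.0, 2.5):
                emp = np.exp(-u * x)
                se = emp.std() / math.sqrt(x.size)
                assert abs(emp.mean() - fam.laplace(u)) < 3 * se + 1e-9

    def test_pvf_general_sampling_rejected(self, rng):
        with pytest.raises(NotImplementedError):
            PVFScaling(1.0, 0.4).sample(10, rng)

    def test_discrete_sampler(self, rng):
        fam = DiscreteScaling([0.5, 2.0], [0.25, 0.75])
        x = fam.sample(50_000, rng)
        assert set(np.unique(x)) == {0.5, 2.0}
        assert abs((x == 2.0).mean() - 0.75) < 0.01


class TestDiscreteKroneckerForm:
    def test_mixture_equals_block_form(self, ph2):
        fam = DiscreteScaling([0.5, 1.0, 2.5], [0.2, 0.5, 0.3])
        c = 1.3  # h^{-1}(y)
        mix = sum(
            w * float(ph2.pi @ mat_exp(eta * ph2.T * c) @ np.ones(2))
            for eta, w in zip(fam.support, fam.weights)
        )
        Tt = np.zeros((6, 6))
        for i, eta in enumerate(fam.support):
            Tt[2 * i:2 * i + 2, 2 * i:2 * i + 2] = eta * ph2.T
        alpha_pi = np.kron(fam.weights, ph2.pi)
        kron_form = float(alpha_pi @ mat_exp(Tt * c) @ np.ones(6))
        assert mix == pytest.approx(kron_form, abs=1e-10)


class TestFracMoment:
    def test_ordinary_mean(self):
        ph = PHRepresentation([1.0], [[-2.0]])
        assert ph_frac_moment(ph, 1.0) == pytest.approx(0.5)

    def test_scalar_gamma_identity(self):
        ph = PHRepresentation([1.0], [[-1.0]])
        assert ph_frac_moment(ph, 0.5) == pytest.approx(
            math.gamma(1.5), rel=1e-10)

    def test_against_monte_carlo(self, ph3, rng):
        z = ph3.sample(200_000, rng)
        m = (z ** 1.5).mean()
        se = (z ** 1.5).std() / math.sqrt(z.size)
        assert abs(ph_frac_moment(ph3, 1.5) - m) < 3 * se


class TestSerialization:
    @pytest.mark.parametrize("fam", ALL_SCALINGS, ids=lambda f: f.family)
    def test_scaling_roundtrip(self, fam):
        d = fam.to_dict()
        back = make_scaling(d["family"], d["params"])
        assert back.to_dict() == d

    @pytest.mark.parametrize("family,params", INTENSITIES)
    def test_intensity_roundtrip(self, family, params):
        it = make_intensity(family, params)
        d = it.to_dict()
        back = make_intensity(**d)
        assert back.to_dict() == d
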