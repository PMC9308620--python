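"""Generalized EM estimation: E-step oracles, M-step updates, full fits."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from siphtool import (
    Degenerate,
    GammaScaling,
    InverseGaussianScaling,
    ObservationSet,
    PHRepresentation,
    SharedSIPHModel,
    cph_estep,
    cph_mstep,
    correlated_em_fit,
    initialize,
    loglik,
    make_intensity,
    mml_em_fit,
    shared_em_fit,
    siph_em_fit,
    tail_dependence_upper,
)
from siphtool.estimation import _cond_stats, _update_ph
from siphtool.univariate import SIPHModel, matrix_mittag_leffler


def exp_model(rate=1.0, scaling=None):
    return SIPHModel(PHRepresentation([1.0], [[-rate]]),
                     make_intensity("constant"),
                     scaling or Degenerate(1.0))


class TestLoglik:
    def test_single_exponential_observation(self):
        data = ObservationSet(np.array([1.0]))
        assert loglik(exp_model(), data) == pytest.approx(-1.0)

    def test_all_but_one_censored_equals_density_plus_survivals(self):
        m = exp_model(scaling=GammaScaling(1.5))
        y = np.array([0.5, 1.0, 2.0, 4.0])
        status = np.array([1, 0, 0, 0])
        data = ObservationSet(y, status=status)
        expect = (np.log(m.density(y[0]))
                  + np.log(m.survival(y[1:])).sum())
        assert loglik(m, data) == pytest.approx(expect, rel=1e-12)


class TestEStepOracles:
    def test_degenerate_single_state(self):
        m = exp_model(rate=0.7)
        y = 1.9
        stats, post = cph_estep(m, ObservationSet(np.array([y])))
        assert stats.B[0][0] == pytest.approx(1.0, abs=1e-10)
        assert stats.Z[0][0] == pytest.approx(y, rel=1e-10)
        assert stats.Nexit[0][0] == pytest.approx(1.0, abs=1e-10)

    def test_gamma_posterior_is_conjugate_for_scalar_model(self):
        # p=1: posterior of Theta given y is Gamma(alpha+1, 1+lam0*y)
        alpha, lam0, y = 1.3, 0.7, 2.1
        m = exp_model(rate=lam0, scaling=GammaScaling(alpha))
        stats, post = cph_estep(m, ObservationSet(np.array([y])), n_nodes=64)
        mean = float((post["theta"] * post["weights"]).sum())
        assert mean == pytest.approx((alpha + 1) / (1 + lam0 * y), rel=1e-6)

    def test_censored_exponential_occupation(self):
        # E[Z | Z > v] = v + 1/rate for a single exponential phase
        rate, v = 0.8, 1.4
        m = exp_model(rate=rate)
        data = ObservationSet(np.array([0.5, v]), status=[1, 0])
        stats, _ = cph_estep(m, data)
        assert stats.Z[0][0] == pytest.approx(0.5 + v + 1.0 / rate, rel=1e-8)
        assert stats.Nexit[0][0] == pytest.approx(2.0, abs=1e-8)

    def test_censored_statistics_against_quadrature(self, ph2):
        # dual route: closed-form conditional stats vs direct integration
        v = 1.1
        st = _cond_stats(ph2, np.array([v]), observed=False)
        e = np.ones(2)
        t = ph2.exit
        g = float(ph2.pi @ expm(ph2.T * v) @ e)
        M = np.linalg.inv(-ph2.T)
        for k in range(2):
            def occ(s):
                return float((ph2.pi @ expm(ph2.T * s))[k]
                             * (expm(ph2.T * (v - s)) @ e)[k])
            J, _ = quad(occ, 0, v, limit=200)
            fut = float((ph2.pi @ expm(ph2.T * v) @ M)[k])
            assert st["Z"][0][k] == pytest.approx(J / g + fut / g, rel=1e-8)


class TestMStep:
    def test_exponential_mle_single_observation(self):
        m = exp_model(rate=0.3)
        y = 2.5
        stats, post = cph_estep(m, ObservationSet(np.array([y])))
        new = cph_mstep(stats, post, m)
        assert new.ph.T[0, 0] == pytest.approx(-1.0 / y, rel=1e-8)

    def test_pi_sums_to_one(self, ph3, rng):
        m = SIPHModel(ph3, make_intensity("constant"), GammaScaling(1.5))
        y = m.sample(200, seed=1)
        stats, post = cph_estep(m, ObservationSet(y))
        new = cph_mstep(stats, post, m)
        assert new.ph.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gamma_update_matches_grid_search(self, ph2):
        m = SIPHModel(ph2, make_intensity("constant"), GammaScaling(1.2))
        y = m.sample(300, seed=7)
        stats, post = cph_estep(m, ObservationSet(y))
        new = cph_mstep(stats, post, m)
        th, w = post["theta"], post["weights"]
        grid = np.linspace(0.3, 4.0, 2000)
        vals = [
            float((w * GammaScaling(a).log_density(th)).sum()) for a in grid
        ]
        assert new.scaling.alpha == pytest.approx(grid[int(np.argmax(vals))],
                                                  abs=1e-2)
        # refined check against a fine local grid
        fine = np.linspace(new.scaling.alpha - 0.01,
                           new.scaling.alpha + 0.01, 400)
        fvals = [float((w * GammaScaling(a).log_density(th)).sum())
                 for a in fine]
        assert abs(fine[int(np.argmax(fvals))]
                   - new.scaling.alpha) < 1e-4 + 3e-5


class TestClassicalPHReference:
    def test_one_iteration_matches_hand_rolled_em(self, ph2):
        """Degenerate scaling + constant intensity reduces to the classical
        phase-type EM; compare one E+M iteration with direct numerical
        integration of the conditional path-statistic formulas."""
        y = np.array([0.4, 1.0, 2.3])
        m = SIPHModel(ph2, make_intensity("constant"), Degenerate(1.0))
        stats, post = cph_estep(m, ObservationSet(y))
        p = 2
        t = ph2.exit
        B = np.zeros(p)
        Z = np.zeros(p)
        N = np.zeros((p, p))
        NE = np.zeros(p)
        for yi in y:
            a = float(ph2.pi @ expm(ph2.T * yi) @ t)
            for k in range(p):
                B[k] += ph2.pi[k] * float((expm(ph2.T * yi) @ t)[k]) / a
                NE[k] += float((ph2.pi @ expm(ph2.T * yi))[k]) * t[k] / a
                for l in range(p):
                    def integrand(s, k=k, l=l):
                        return float((ph2.pi @ expm(ph2.T * s))[k]
                                     * (expm(ph2.T * (yi - s)) @ t)[l])
                    J, _ = quad(integrand, 0, yi, limit=200, epsabs=1e-12,
                                epsrel=1e-12)
                    if k == l:
                        Z[k] += J / a
                    if k != l:
                        N[k, l] += ph2.T[k, l] * J / a
        np.testing.assert_allclose(stats.B[0], B, atol=1e-8)
        np.testing.assert_allclose(stats.Z[0], Z, atol=1e-8)
        np.testing.assert_allclose(stats.Nkl[0], N, atol=1e-8)
        np.testing.assert_allclose(stats.Nexit[0], NE, atol=1e-8)
        new = cph_mstep(stats, post, m)
        np.testing.assert_allclose(new.ph.pi, B / len(y), atol=1e-8)
        for k in range(p):
            for l in range(p):
                if k != l:
                    assert new.ph.T[k, l] == pytest.approx(N[k, l] / Z[k],
                                                           rel=1e-7)


class TestUnivariateFits:
    def test_pareto_recovery(self):
        truth = exp_model(scaling=GammaScaling(1.0))
        y = truth.sample(2000, seed=13)
        res = siph_em_fit(y, p=1, intensity="constant", scaling="gamma",
                          max_iter=120, tol=1e-8, seed=0, restarts=1)
        assert abs(res.model.scaling.alpha - 1.0) < 0.15
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)

    def test_status_column_of_ones_changes_nothing(self):
        truth = exp_model(scaling=GammaScaling(1.5))
        y = truth.sample(300, seed=3)
        r1 = siph_em_fit(ObservationSet(y), p=2, max_iter=25, seed=1,
                         restarts=1)
        r2 = siph_em_fit(ObservationSet(y, status=np.ones(len(y))), p=2,
                         max_iter=25, seed=1, restarts=1)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-6)

    def test_fit_with_real_censoring_is_monotone_and_reasonable(self):
        truth = exp_model(scaling=GammaScaling(2.0))
        rng = np.random.default_rng(17)
        y = truth.sample(1200, seed=rng)
        c = truth.sample(1200, seed=rng) * 2.0
        obs = y <= c
        data = ObservationSet(np.minimum(y, c), status=obs)
        res = siph_em_fit(data, p=1, intensity="constant", scaling="gamma",
                          max_iter=80, seed=0, restarts=1)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)
        assert 1.0 < res.model.scaling.alpha < 3.5

    @pytest.mark.parametrize("scaling,param,attr,tol", [
        ("gamma", 1.5, "alpha", 0.35),
        ("inverse_gaussian", 1.0, "sigma2", 0.6),
    ])
    def test_tail_parameter_recovery_replicates(self, ph2, scaling, param,
                                                attr, tol):
        """Replicated recovery of the tail-driving scaling parameter."""
        from siphtool import make_scaling

        truth = SIPHModel(ph2, make_intensity("constant"),
                          make_scaling(scaling, (param,)))
        ests = []
        for rep in range(5):
            y = truth.sample(1500, seed=100 + rep)
            res = siph_em_fit(y, p=2, intensity="constant", scaling=scaling,
                              max_iter=60, tol=1e-7, seed=rep, restarts=1)
            ests.append(getattr(res.model.scaling, attr))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - param) < max(3 * se, tol)


class TestMMLFit:
    def test_boundary_recovery_for_plain_ph_data(self, ph2):
        # data without heavy tail: alpha should pile up at 1
        y = ph2.sample(1200, np.random.default_rng(4))
        res = mml_em_fit(y, p=2, max_iter=20, seed=0, restarts=1)
        assert res.model.scaling.alpha >= 0.97

    def test_monotone_trace(self):
        m = matrix_mittag_leffler([0.5, 0.5],
                                  [[-1.0, 0.3], [0.2, -2.0]], 0.7)
        y = m.sample(400, seed=6)
        res = mml_em_fit(y, p=2, max_iter=15, seed=0, restarts=1)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)


class TestSharedFit:
    def test_degenerate_scaling_reduces_to_independent_estep(self, ph3, ph2):
        m = SharedSIPHModel(
            [(ph3, make_intensity("constant")),
             (ph2, make_intensity("constant"))],
            Degenerate(1.0))
        Y = m.sample(150, seed=2)
        stats, post = cph_estep(m, ObservationSet(Y))
        # against univariate E-steps margin by margin
        for i, ph in enumerate((ph3, ph2)):
            mu = SIPHModel(ph, make_intensity("constant"), Degenerate(1.0))
            s_i, _ = cph_estep(mu, ObservationSet(Y[:, i]))
            np.testing.assert_allclose(stats.B[i], s_i.B[0], atol=1e-10)
            np.testing.assert_allclose(stats.Z[i], s_i.Z[0], atol=1e-10)
            np.testing.assert_allclose(stats.Nkl[i], s_i.Nkl[0], atol=1e-10)
        # joint loglik equals the sum of marginal logliks
        assert loglik(m, ObservationSet(Y)) == pytest.approx(
            sum(loglik(m.margin(i), ObservationSet(Y[:, i]))
                for i in range(2)), rel=1e-10)

    def test_bivariate_gamma_recovery_of_tail_dependence(self):
        from siphtool import make_fixture

        data, truth = make_fixture("bivariate_gamma", n=2500, seed=5)
        res = shared_em_fit(data, p=(3, 2), intensity="constant",
                            scaling="gamma", max_iter=80, tol=1e-7,
                            seed=0, restarts=1)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)
        lam_fit = tail_dependence_upper(res.model)
        assert abs(lam_fit - tail_dependence_upper(truth)) < 0.08


class TestCorrelatedFit:
    def test_independent_margins_when_kappa0_fixed_to_zero(self, ph2):
        rng = np.random.default_rng(11)
        y1 = SIPHModel(ph2, make_intensity("constant"),
                       GammaScaling(1.5)).sample(250, seed=rng)
        y2 = exp_model(scaling=GammaScaling(2.0)).sample(250, seed=rng)
        data = ObservationSet(np.column_stack([y1, y2]))
        res = correlated_em_fit(data, p=(2, 1), fix_kappa0=0.0,
                                kappa1=1.5, kappa2=2.0, max_iter=10,
                                seed=0, restarts=1)
        assert res.model.kappa0 == 0.0
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)

    def test_recovers_positive_shared_component(self):
        margins = [(PHRepresentation([1.0], [[-1.0]]),
                    make_intensity("constant"))] * 2
        truth = __import__("siphtool").CorrelatedSIPHModel(
            margins, kappa0=2.0, kappa1=0.5, kappa2=0.5)
        Y = truth.sample(600, seed=21)
        res = correlated_em_fit(Y, p=(1, 1), kappa0=1.0, kappa1=1.0,
                                kappa2=1.0, max_iter=25, seed=0, restarts=1)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)
        assert res.model.theta_corr() > 0.25  # truth: 2/2.5 = 0.8


class TestInitialize:
    def test_coxian_pattern(self):
        ph = initialize(3, "coxian", seed=0)
        off = ph.T - np.diag(np.diag(ph.T))
        nz = np.nonzero(off)
        assert all(j == i + 1 for i, j in zip(*nz))

    def test_many_seeded_draws_are_valid(self):
        for s in range(200):
            ph = initialize(4, "general", seed=s)
            assert ph.pi.sum() == pytest.approx(1.0)
            assert np.all(ph.pi >= 0)
            assert ph.T.sum(axis=1).max() <= 1e-10

    def test_distinct_seeds_distinct_matrices(self):
        a = initialize(3, "general", seed=1)
        b = initialize(3, "general", seed=2)
        assert not np.allclose(a.T, b.T)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            initialize(3, "cyclic", seed=0)
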