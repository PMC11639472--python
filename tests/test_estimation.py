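"""Likelihood, score, distance objectives and the fitting harness."""

import numpy as np
import pytest

from nefr import (
    FrechetParams,
    NEFrParams,
    ObservationSet,
    ade_objective,
    fit,
    fit_frechet,
    loglik,
    lse_objective,
    mle_standard_errors,
    nefr_cdf,
    nefr_logpdf,
    nefr_quantile,
    nefr_rvs,
    score,
    wlse_objective,
)


class TestLoglik:
    def test_single_observation_against_oracle(self, mp_oracle):
        p = NEFrParams(0.5, 1.0, 2.0)
        expected = mp_oracle.logpdf(1.0, 0.5, 1.0, 2.0)  # -1.0121658468...
        assert loglik(ObservationSet([1.0]), p) == pytest.approx(expected, abs=1e-12)

    def test_equals_sum_of_log_density(self, pakistan):
        for p in (NEFrParams(1, 1, 1), NEFrParams(8.8, 0.064, 663.0), NEFrParams(0.3, 0.4, 0.3)):
            direct = float(np.sum(nefr_logpdf(pakistan.values, p)))
            assert loglik(pakistan, p) == pytest.approx(direct, rel=1e-10)

    def test_doubling_the_sample_doubles_the_loglik(self, pakistan):
        p = NEFrParams(1.0, 0.5, 2.0)
        doubled = ObservationSet(np.concatenate([pakistan.values, pakistan.values]))
        assert loglik(doubled, p) == pytest.approx(2 * loglik(pakistan, p), rel=1e-12)

    def test_returns_minus_inf_not_nan_on_underflow(self):
        # huge beta forces the log terms past double range
        val = loglik(ObservationSet([1e-9, 2.0]), NEFrParams(1.0, 300.0, 0.5))
        assert val == -np.inf


class TestScore:
    def _fd(self, data, p, h=1e-6):
        g = []
        for name in ("lam", "beta", "alpha"):
            kw = dict(alpha=p.alpha, beta=p.beta, lam=p.lam)
            kw[name] += h
            up = loglik(data, NEFrParams(**kw))
            kw[name] -= 2 * h
            dn = loglik(data, NEFrParams(**kw))
            g.append((up - dn) / (2 * h))
        return np.array(g)

    def test_matches_finite_differences_on_data(self, pakistan, bladder):
        for data, p in [
            (pakistan, NEFrParams(1.0, 1.0, 1.0)),
            (bladder, NEFrParams(4.8, 0.15, 32.0)),
            (pakistan, NEFrParams(0.7, 0.3, 2.5)),
        ]:
            s = score(data, p)
            fd = self._fd(data, p)
            np.testing.assert_allclose(s, fd, rtol=1e-5)

    def test_matches_symbolic_derivative_single_observation(self):
        # independent symbolic oracle for one observation at z = 1
        import sympy as sp

        a, b, l, z = sp.symbols("a b l z", positive=True)
        E = sp.exp(-2 * a * z**-b)
        L = (sp.log(2) + 2 * sp.log(l) + sp.log(a) + sp.log(b)
             - (b + 1) * sp.log(z) - 2 * a * z**-b
             + (l - 1) * sp.log(1 - E) - (l + 1) * sp.log(1 - (1 - l) * E))
        subs = {a: sp.Rational(1, 2), b: 1, l: 2, z: 1}
        expected = [float(sp.diff(L, v).subs(subs)) for v in (l, b, a)]
        got = score(ObservationSet([1.0]), NEFrParams(0.5, 1.0, 2.0))
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_near_zero_at_interior_optimum(self, bladder):
        res = fit(bladder, "mle", starts=12, seed=1)
        s = score(bladder, res.params)
        # standardized by parameter scale: flat-ridge lam direction included
        scaled = s * np.array([res.params.lam, res.params.beta, res.params.alpha])
        assert np.linalg.norm(scaled) < 1e-2


class TestDistanceObjectives:
    def test_perfect_plotting_positions_give_zero_lse(self):
        p = NEFrParams(0.5, 1.0, 2.0)
        n = 9
        z = nefr_quantile(np.arange(1, n + 1) / (n + 1.0), p)
        data = ObservationSet(z)
        assert lse_objective(data, p) == pytest.approx(0.0, abs=1e-16)
        assert wlse_objective(data, p) == pytest.approx(0.0, abs=1e-12)

    def test_wlse_weights_are_symmetric(self):
        n = 12
        i = np.arange(1, n + 1)
        w = (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))
        np.testing.assert_allclose(w, w[::-1])

    def test_three_point_hand_summed_oracle(self):
        p = NEFrParams(0.7, 1.2, 0.8)
        z = np.array([0.5, 1.5, 4.0])
        F = nefr_cdf(np.sort(z), p)
        lse_hand = sum((F[i] - (i + 1) / 4.0) ** 2 for i in range(3))
        w = [16.0 * 5 / (1 * 3), 16.0 * 5 / (2 * 2), 16.0 * 5 / (3 * 1)]
        wlse_hand = sum(w[i] * (F[i] - (i + 1) / 4.0) ** 2 for i in range(3))
        data = ObservationSet(z)
        assert lse_objective(data, p) == pytest.approx(lse_hand, rel=1e-12)
        assert wlse_objective(data, p) == pytest.approx(wlse_hand, rel=1e-12)

    def test_single_point_anderson_darling_closed_form(self):
        # n = 1: A^2 = -1 - [log F + log(1-F)], minimized at F = 1/2 -> 2 log 2 - 1
        p = NEFrParams(0.5, 1.0, 2.0)
        z_med = float(nefr_quantile(0.5, p))
        data = ObservationSet([z_med])
        assert ade_objective(data, p) == pytest.approx(2 * np.log(2) - 1, abs=1e-9)

    def test_anderson_darling_against_ecdf_integral_oracle(self):
        # A^2 = n * int (Fn - F)^2 / (F (1-F)) dF, evaluated numerically on the PIT scale
        from scipy.integrate import quad

        p = NEFrParams(0.5, 0.8, 0.3)
        data = nefr_rvs(50, p, seed=3)
        u = np.sort(nefr_cdf(data.sorted_values, p))

        def integrand(t):
            fn = np.searchsorted(u, t, side="right") / len(u)
            return (fn - t) ** 2 / (t * (1 - t))

        segs = np.concatenate([[0.0], u, [1.0]])
        total = sum(quad(integrand, lo, hi, limit=100)[0]
                    for lo, hi in zip(segs[:-1], segs[1:]))
        assert ade_objective(data, p) == pytest.approx(len(u) * total, rel=1e-6)

    def test_probability_integral_transform_invariance(self):
        # A^2 depends on the sample only through F(z_(i))
        p1 = NEFrParams(0.5, 1.0, 2.0)
        p2 = NEFrParams(2.0, 0.7, 0.6)
        u = np.linspace(0.08, 0.92, 15)
        d1 = ObservationSet(nefr_quantile(u, p1))
        d2 = ObservationSet(nefr_quantile(u, p2))
        assert ade_objective(d1, p1) == pytest.approx(ade_objective(d2, p2), rel=1e-9)


class TestFit:
    def test_deterministic_for_fixed_seed(self, pakistan):
        a = fit(pakistan, "lse", starts=6, seed=5)
        b = fit(pakistan, "lse", starts=6, seed=5)
        assert a.params == b.params and a.objective == b.objective

    def test_parameter_recovery_large_sample(self):
        truth = NEFrParams(0.5, 0.8, 0.3)
        data = nefr_rvs(5000, truth, seed=21)
        res = fit(data, "mle", starts=0, seed=0, init=[truth.as_tuple()])
        assert res.se is not None
        for est, se, tr in zip(res.params.as_tuple(), res.se, truth.as_tuple()):
            assert abs(est - tr) < 3 * se

    def test_distance_methods_recover_truth_roughly(self):
        truth = NEFrParams(0.5, 0.8, 0.3)
        data = nefr_rvs(2000, truth, seed=4)
        for method in ("lse", "wlse", "ade"):
            res = fit(data, method, starts=0, seed=0, init=[truth.as_tuple()])
            assert res.params.beta == pytest.approx(truth.beta, rel=0.3)

    def test_rejects_bad_arguments(self, pakistan):
        with pytest.raises(ValueError):
            fit(pakistan, "mom")
        with pytest.raises(ValueError):
            fit(pakistan, "mle", starts=0)

    def test_bladder_cancer_application(self, bladder):
        # published row: alpha 4.847 (SE 1.069), beta 0.154 (SE 0.052),
        # lam 32.157 (SE 36.035); the lam direction is nearly flat
        res = fit(bladder, "mle", starts=12, seed=1)
        assert res.params.alpha == pytest.approx(4.847, rel=0.01)
        assert res.params.beta == pytest.approx(0.154, rel=0.01)
        assert res.se is not None
        assert res.se[0] == pytest.approx(1.069, rel=0.05)
        assert res.se[1] == pytest.approx(0.052, rel=0.05)
        assert res.se[2] > res.params.lam  # flat ridge: SE(lam) exceeds lam itself

    def test_pakistan_fit_attains_published_likelihood(self, pakistan):
        # the likelihood ridge is unbounded in lam; the fit must do at least
        # as well as the published optimum -2 logL = 422.087
        res = fit(pakistan, "mle", starts=12, seed=1)
        assert -2 * res.objective <= 422.087 + 1e-6


class TestStandardErrors:
    def test_scaling_with_sample_size(self):
        truth = NEFrParams(0.5, 3.0, 2.0)  # well-identified corner of the space
        ses = []
        for n in (500, 2000, 8000):
            data = nefr_rvs(n, truth, seed=9)
            res = fit(data, "mle", starts=0, seed=0, init=[truth.as_tuple()])
            assert res.se is not None
            ses.append(res.se[1])  # beta
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.35)
        assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.35)

    def test_against_numerical_hessian_of_loglik(self, who):
        res = fit(who, "mle", starts=12, seed=1)
        p = res.params
        theta = np.array(p.as_tuple())

        def ll(t):
            return loglik(who, NEFrParams(*t))

        H = np.zeros((3, 3))
        h = 1e-4 * theta
        for i in range(3):
            for j in range(3):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[i] * h[j])
        se_ref = np.sqrt(np.diag(np.linalg.inv(-H)))
        np.testing.assert_allclose(res.se, se_ref, rtol=1e-2)


class TestFrechetBaseline:
    def test_published_frechet_fit_on_bladder_data(self, bladder):
        # published baseline row: alpha 2.432, beta 0.752, -2logL = 888.002
        res = fit_frechet(bladder, seed=0)
        assert isinstance(res.params, FrechetParams)
        assert res.params.alpha == pytest.approx(2.432, rel=0.01)
        assert res.params.beta == pytest.approx(0.752, rel=0.01)
        assert -2 * res.objective == pytest.approx(888.002, abs=0.01)
        assert res.k == 2
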