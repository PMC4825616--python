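"""Inference engine tests: analytic marginal vs brute-force integration,
quadrature convergence, scale invariance, parameter recovery, MCMC engine."""

import math

import numpy as np
import pytest

from quantpd import (
    EffectParams,
    KineticParams,
    McmcSettings,
    PriorSpec,
    QuadratureFitter,
    TimeCourse,
    anneal_mcmc,
    design_matrix,
    log_marginal_given_nonlinear,
    model_probabilities,
    model_signal,
    quadrature_evidence,
)
from quantpd.inference import _log_marginal_core

C_PEAK = 1 + 2 ** (-10 / 41) + 2 ** (-20 / 41) + 2 ** (-30 / 41)


def brute_force_log_marginal(y, X, g, n_beta=41, n_sigma=160, half_width=10.0):
    """Numerical-integration oracle for the analytic linear/sigma marginal.

    Integrates the Gaussian likelihood over a flat intercept, the Zellner
    g-prior on the centered remaining columns, and the Jeffreys sigma prior
    on dense tensor grids centered on the least-squares solution.
    """
    from scipy.special import logsumexp

    y = np.asarray(y, float)
    n, m = X.shape
    k = m - 1
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    sigma_hat = max(np.sqrt(resid @ resid / max(n - m, 1)), 1e-3 * np.std(y))
    if k:
        xc = X[:, 1:] - X[:, 1:].mean(axis=0)
        prec = xc.T @ xc  # prior covariance is g*sigma^2*prec^-1
        cov_chol = np.linalg.cholesky(np.linalg.inv(prec))
        _, prec_logdet = np.linalg.slogdet(prec)
    # grids: intercept and slopes around the LS fit, sigma log-spaced
    grids = [np.linspace(beta_hat[0] - half_width * sigma_hat,
                         beta_hat[0] + half_width * sigma_hat, n_beta)]
    for j in range(k):
        s_j = sigma_hat * np.sqrt(np.sum(cov_chol[j] ** 2))
        grids.append(np.linspace(beta_hat[1 + j] - half_width * s_j,
                                 beta_hat[1 + j] + half_width * s_j, n_beta))
    sigmas = np.geomspace(sigma_hat / 10, sigma_hat * 15, n_sigma)

    mesh = np.meshgrid(*grids, indexing="ij")
    betas = np.stack([m_.ravel() for m_ in mesh], axis=1)  # (B, m)
    rss = np.sum((y[None, :] - betas @ X.T) ** 2, axis=1)  # (B,)
    quad = np.einsum("bi,ij,bj->b", betas[:, 1:], prec, betas[:, 1:]) if k else 0.0

    # trapezoid weights per dimension
    log_w = np.zeros([n_beta] * m)
    for d, gr in enumerate(grids):
        shape = [1] * m
        shape[d] = n_beta
        log_w = log_w + np.log(np.gradient(gr)).reshape(shape)
    log_w = log_w.ravel()

    per_sigma = np.empty(n_sigma)
    for i, sig in enumerate(sigmas):
        loglik = -0.5 * n * np.log(2 * np.pi * sig**2) - rss / (2 * sig**2)
        if k:
            prior = (
                -0.5 * k * np.log(2 * np.pi * g * sig**2)
                + 0.5 * prec_logdet
                - quad / (2 * g * sig**2)
            )
        else:
            prior = 0.0
        per_sigma[i] = logsumexp(loglik + prior + log_w) - np.log(sig)
    return float(logsumexp(per_sigma + np.log(np.gradient(sigmas))))


class TestDesignMatrix:
    def test_shapes_and_intercept(self, times, make_curve):
        tc = make_curve(2.0, 0.5, seed=1)
        X = design_matrix(tc, {}, "baseline")
        assert X.shape == (161, 3)
        assert np.all(X[:, 0] == 1.0)
        assert design_matrix(tc, {}, "nosignal").shape == (161, 1)

    def test_full_model_effect_column(self, schedule, make_curve):
        tc = make_curve(2.0, 0.5, seed=1)
        nl = {"q": math.log10(2.0), "ts": 0.5, "t_half": 41.0}
        X = design_matrix(tc, nl, "full", schedule)
        i = np.argmin(np.abs(tc.times - 30.5))
        assert X[i, 3] == pytest.approx(C_PEAK / (2 + C_PEAK), abs=1e-6)
        assert X[i, 3] == pytest.approx(0.6124, abs=1e-3)

    def test_effect_column_vanishes_at_high_ec50(self, schedule, make_curve):
        tc = make_curve(2.0, 0.5, seed=1)
        X = design_matrix(tc, {"q": 1.3, "ts": 0.5, "t_half": 41.0}, "full", schedule)
        assert np.all(X[:, 3] < 0.14)

    def test_unknown_model_rejected(self, make_curve):
        with pytest.raises(ValueError, match="unknown model"):
            design_matrix(make_curve(2.0, 0.5), {}, "quadratic")


class TestAnalyticMarginal:
    @pytest.mark.parametrize("model,g", [("nosignal", 25.0), ("baseline", 25.0)])
    def test_against_brute_force_oracle(self, model, g):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 8, 9)
        y = 5.0 + 0.4 * t - 0.02 * t**2 + rng.normal(0, 0.5, t.size)
        tc = TimeCourse(times=t, values=y)
        X = design_matrix(tc, {}, model)
        ours = _log_marginal_core(y, X, g)
        oracle = brute_force_log_marginal(y, X, g, n_beta=61, n_sigma=240, half_width=12)
        assert ours == pytest.approx(oracle, abs=0.05)

    def test_full_model_against_oracle(self, schedule):
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 4.0)
        kin = KineticParams()
        from quantpd import BaselineParams

        clean = model_signal(
            t, schedule, kin, EffectParams.from_ec50(5, 2), BaselineParams(10, 0.1, 0)
        )
        y = np.asarray(clean) + rng.normal(0, 0.5, t.size)
        tc = TimeCourse(times=t, values=y)
        nl = {"q": math.log10(2.0), "ts": 0.5, "t_half": 41.0}
        X = design_matrix(tc, nl, "full", schedule)
        g = 9.0
        ours = _log_marginal_core(y, X, g)
        oracle = brute_force_log_marginal(y, X, g, n_beta=27, n_sigma=120, half_width=10)
        assert ours == pytest.approx(oracle, abs=0.15)

    def test_span_invariance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 40, 41)
        y = 3 + 0.1 * t + rng.normal(0, 1, t.size)
        X1 = np.column_stack([np.ones_like(t), t, t**2])
        X2 = np.column_stack([np.ones_like(t), 2 * t - 7, 3 * t**2 - t])  # same span
        assert _log_marginal_core(y, X1, 1e8) == pytest.approx(
            _log_marginal_core(y, X2, 1e8), abs=1e-8
        )

    def test_nested_fit_dominance_on_clean_drift(self, times):
        y = 1000 + 0.5 * times  # strong drift, no noise needed
        tc = TimeCourse(times=times, values=y + np.sin(times) * 1e-3)
        lb = log_marginal_given_nonlinear(tc, {}, "baseline")
        ln = log_marginal_given_nonlinear(tc, {}, "nosignal")
        assert lb > ln + 50

    def test_rank_deficient_design_rejected(self):
        t = np.linspace(0, 7, 8)
        y = np.arange(8.0)
        X = np.column_stack([np.ones(8), t, 2 * t])
        with pytest.raises(ValueError, match="rank-deficient"):
            _log_marginal_core(y, X, 1e8)

    def test_too_few_points_rejected(self, schedule):
        tc = TimeCourse(times=np.arange(5.0), values=np.arange(5.0) + 0.5)
        with pytest.raises(ValueError, match="at least"):
            log_marginal_given_nonlinear(tc, {}, "baseline")


class TestQuadratureEvidence:
    def test_matches_exact_for_linear_models(self, make_curve):
        tc = make_curve(2.0, 2.0, seed=5)
        for model in ("baseline", "nosignal"):
            assert quadrature_evidence(tc, model) == pytest.approx(
                log_marginal_given_nonlinear(tc, {}, model)
            )

    def test_resolution_convergence(self, schedule, make_curve):
        tc = make_curve(2.0, 2.0, seed=5)
        coarse = QuadratureFitter(tc.times, schedule, dq=0.025, dts=0.05)  # default
        fine = QuadratureFitter(tc.times, schedule, dq=0.0125, dts=0.025)
        lz_c = coarse.log_evidences(tc.values)["full"]
        lz_f = fine.log_evidences(tc.values)["full"]
        assert abs(lz_c - lz_f) < 0.01

    def test_evidence_ordering_on_signal_curve(self, schedule, make_curve):
        tc = make_curve(2.0, 0.5, seed=8)
        lz = QuadratureFitter(tc.times, schedule).log_evidences(tc.values)
        assert lz["full"] > lz["baseline"] > lz["nosignal"]


class TestModelProbabilities:
    def test_probabilities_sum_to_one(self, schedule, default_fitter, make_curve):
        for seed, ec50, sd in [(1, 2.0, 0.5), (2, None, 2.0), (3, 7.5, 10.0)]:
            res = default_fitter.fit(make_curve(ec50, sd, seed))
            assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-10)
            assert all(0 <= p <= 1 for p in res.probabilities.values())

    def test_noise_only_curve_not_detected(self, default_fitter, make_curve):
        for seed in range(5):
            res = default_fitter.fit(make_curve(None, 2.0, seed))
            assert res.prob_full < 0.5
            assert res.estimates is None

    def test_scale_invariance_of_probabilities(self, schedule, make_curve):
        tc = make_curve(2.0, 2.0, seed=9)
        fitter = QuadratureFitter(tc.times, schedule)
        p1 = fitter.fit(tc).probabilities
        scaled = TimeCourse(times=tc.times, values=tc.values * 37.5)
        p2 = fitter.fit(scaled).probabilities
        for m in p1:
            assert p1[m] == pytest.approx(p2[m], abs=1e-8)

    def test_clean_curve_parameter_recovery(self, default_fitter, make_curve):
        # near-noiseless curves: EC50 within 10%; ts to within one sampling
        # interval (between sample points a shift in ts is absorbed by e_max)
        for ec50 in (0.25, 0.6, 2.0, math.pi, 7.5):
            res = default_fitter.fit(make_curve(ec50, 0.01, seed=17))
            assert res.prob_full > 0.5
            est = res.estimates
            assert est["ec50"]["ml"] == pytest.approx(ec50, rel=0.10)
            assert est["ts"]["ml"] == pytest.approx(0.5, abs=0.25)
            assert est["e_max"]["ml"] == pytest.approx(10.0, rel=0.15)

    def test_residual_sd_tracks_noise(self, default_fitter, make_curve):
        res = default_fitter.fit(make_curve(2.0, 2.0, seed=21))
        assert res.residual_sd == pytest.approx(2.0, rel=0.25)

    def test_threshold_gates_estimates(self, schedule, make_curve):
        null = make_curve(None, 2.0, seed=4)
        assert model_probabilities(null, schedule).estimates is None
        forced = model_probabilities(null, schedule, threshold=-1.0)
        assert forced.estimates is not None  # threshold is configurable

    def test_posterior_mean_close_to_truth_at_high_snr(self, default_fitter, make_curve):
        res = default_fitter.fit(make_curve(2.0, 0.1, seed=31))
        assert res.estimates["q"]["mean"] == pytest.approx(math.log10(2.0), abs=0.1)


class TestMcmcEngine:
    def test_same_seed_identical_samples(self, schedule, make_curve):
        tc = make_curve(2.0, 2.0, seed=12)
        settings = McmcSettings(walkers=20, repeats=20, seed=77,
                                ladder=tuple(np.geomspace(1e-3, 1, 10)))
        a = anneal_mcmc(tc, "full", schedule=schedule, settings=settings)
        b = anneal_mcmc(tc, "full", schedule=schedule, settings=settings)
        assert np.array_equal(a["samples"], b["samples"])
        assert a["log_evidence"] == b["log_evidence"]

    def test_exact_for_linear_models(self, schedule, make_curve):
        tc = make_curve(2.0, 2.0, seed=12)
        run = anneal_mcmc(tc, "baseline", schedule=schedule)
        assert run["log_evidence"] == pytest.approx(
            log_marginal_given_nonlinear(tc, {}, "baseline")
        )

    def test_evidence_agrees_with_quadrature(self, schedule, make_curve):
        tc = make_curve(2.0, 2.0, seed=13)
        lz_q = QuadratureFitter(tc.times, schedule).log_evidences(tc.values)["full"]
        run = anneal_mcmc(tc, "full", schedule=schedule, settings=McmcSettings(seed=5))
        assert abs(run["log_evidence"] - lz_q) < 0.5

    def test_full_result_object(self, schedule, make_curve):
        tc = make_curve(2.0, 1.0, seed=14)
        res = model_probabilities(tc, schedule, engine="mcmc",
                                  settings=McmcSettings(seed=3))
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-10)
        assert res.prob_full > 0.5
        assert res.estimates["ec50"]["ml"] == pytest.approx(2.0, rel=0.5)

    def test_bad_ladder_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            McmcSettings(ladder=(0.5, 0.2, 1.0))


class TestPriorSpec:
    def test_defaults(self):
        p = PriorSpec()
        assert p.q_range == (-3.0, 1.3)
        assert p.ts_range == (0.0, 1.0)
        assert p.t_half == 41.0 and not p.t_half_free
        assert PriorSpec(t_half=(2.0, 60.0)).t_half_free

    @pytest.mark.parametrize(
        "kwargs",
        [dict(q_range=(1.0, 1.0)), dict(t_half=0.0), dict(t_half=(5.0, 2.0)), dict(g=0)],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            PriorSpec(**kwargs)
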