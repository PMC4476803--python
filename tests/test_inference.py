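"""Likelihood, full conditionals, ARMS, the Gibbs cycle and summaries."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import norm

import sprbayes as sb
from sprbayes.inference import SamplerError

KM = 3.15e7
THETA = sb.KineticState(ka=3e6, kd=3e-3, A0=30e-9, Rmax=31.5, R0=25.0, sigma2=2.25)


def _sensorgram(times, responses, stop):
    return sb.Sensorgram(times=np.asarray(times, float),
                         responses=np.asarray(responses, float),
                         injection_stop=stop)


class TestLogLikelihood:
    def test_single_exact_point(self):
        # one association point at t=0 where the model is exactly 0
        data = _sensorgram([0.0], [0.0], 1.0)
        theta = dataclasses.replace(THETA, sigma2=1.0)
        assert sb.log_likelihood(theta, data, KM) == pytest.approx(
            -0.5 * math.log(2 * math.pi), rel=1e-12)

    def test_matches_pointwise_gaussian_sum(self, toy_sensorgram):
        # independent oracle: per-point normal log-density summed directly
        curve = sb.predict_sensorgram(
            THETA, KM,
            sb.PhaseGrid(times=toy_sensorgram.times,
                         injection_stop=toy_sensorgram.injection_stop))
        expected = norm.logpdf(toy_sensorgram.responses, loc=curve,
                               scale=math.sqrt(THETA.sigma2)).sum()
        assert sb.log_likelihood(THETA, toy_sensorgram, KM) == pytest.approx(
            expected, rel=1e-10)

    def test_sigma2_doubling_identity(self, toy_sensorgram):
        # ll(2 s2) - ll(s2) = SSR/(4 s2) - n/2 log 2
        curve = sb.predict_sensorgram(
            THETA, KM,
            sb.PhaseGrid(times=toy_sensorgram.times,
                         injection_stop=toy_sensorgram.injection_stop))
        ssr = float(np.sum((toy_sensorgram.responses - curve) ** 2))
        n = toy_sensorgram.times.size
        delta = (sb.log_likelihood(dataclasses.replace(THETA, sigma2=4.5),
                                   toy_sensorgram, KM)
                 - sb.log_likelihood(THETA, toy_sensorgram, KM))
        assert delta == pytest.approx(ssr / (4 * 2.25) - n / 2 * math.log(2), rel=1e-10)

    def test_invalid_r0_rejected_not_raised(self, toy_sensorgram):
        bad = dataclasses.replace(THETA, R0=1e5)
        assert sb.log_likelihood(bad, toy_sensorgram, KM) == -math.inf


class TestLogFullConditional:
    def test_flat_prior_limit_matches_likelihood_differences(self, toy_sensorgram):
        flat = sb.PriorSpec(normal={**sb.PriorSpec().normal,
                                    "ka": (5e11, 1e15, 1e2, 1e12)})
        lc = [sb.log_full_conditional("ka", v, THETA, toy_sensorgram, KM, flat)
              for v in (2e6, 4e6)]
        ll = [sb.log_likelihood(dataclasses.replace(THETA, ka=v), toy_sensorgram, KM)
              for v in (2e6, 4e6)]
        assert lc[1] - lc[0] == pytest.approx(ll[1] - ll[0], abs=1e-6)

    def test_zero_data_reduces_to_prior_kernel(self):
        empty = _sensorgram([], [], 0.0)
        priors = sb.PriorSpec()
        for v in (10.0, 50.0, 90.0):
            assert sb.log_full_conditional("A0", v, THETA, empty, KM, priors) == \
                pytest.approx(priors.log_kernel("A0", v), abs=1e-12)

    def test_arms_on_prior_recovers_center(self, rng):
        # sampling the A0 conditional with no data draws from the
        # (effectively untruncated) N(50, 10^2) prior
        empty = _sensorgram([], [], 0.0)
        priors = sb.PriorSpec()

        def logp(v):
            return sb.log_full_conditional("A0", v, THETA, empty, KM, priors)

        draws = np.empty(4000)
        x = 30.0
        for i in range(draws.size):
            x = sb.arms_draw(logp, (1e-3, 1e6), init=[20, 35, 50, 65, 80],
                             previous_value=x, rng=rng)
            draws[i] = x
        assert draws.mean() == pytest.approx(50.0, abs=1.0)
        assert draws.std() == pytest.approx(10.0, abs=1.0)

    def test_default_A0_prior_is_printed_kernel(self):
        mu, sd, lo, hi = sb.PriorSpec().normal["A0"]
        assert (mu, sd) == (50.0, 10.0)

    def test_unknown_coordinate(self, toy_sensorgram):
        with pytest.raises(ValueError):
            sb.log_full_conditional("sigma2", 1.0, THETA, toy_sensorgram, KM)


class TestDrawSigma2:
    def test_no_data_draws_from_prior(self, rng):
        from scipy.stats import invgamma, kstest
        empty = _sensorgram([], [], 0.0)
        draws = np.array([sb.draw_sigma2(THETA, empty, KM, rng=rng)
                          for _ in range(2000)])
        # InvGamma(0.1, 0.1) has no mean, so compare whole distributions
        assert kstest(draws, invgamma(0.1, scale=0.1).cdf).pvalue > 0.01

    def test_posterior_mean_formula(self, toy_sensorgram):
        # mean of InvGamma(a + n/2, b + SSR/2) is rate/(shape-1)
        rng = np.random.default_rng(7)
        draws = np.array([sb.draw_sigma2(THETA, toy_sensorgram, KM, rng=rng)
                          for _ in range(100_000)])
        curve = sb.predict_sensorgram(
            THETA, KM, sb.PhaseGrid(times=toy_sensorgram.times,
                                    injection_stop=toy_sensorgram.injection_stop))
        ssr = float(np.sum((toy_sensorgram.responses - curve) ** 2))
        n = toy_sensorgram.times.size
        expected = (0.1 + ssr / 2) / (0.1 + n / 2 - 1)
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_concentrates_at_residual_variance(self):
        # large n with SSR = n*c: draws pile up at c
        rng = np.random.default_rng(8)
        t = np.arange(2000.0)
        data = _sensorgram(t, np.zeros_like(t), 1000.0)
        theta = sb.KineticState(ka=1e6, kd=1e-3, A0=0.0, Rmax=31.5, R0=1e-6,
                                sigma2=1.0)
        # model curve ~ 0 everywhere; inject residuals of variance c
        c = 4.0
        data.responses[:] = math.sqrt(c)
        draws = np.array([sb.draw_sigma2(theta, data, KM, rng=rng)
                          for _ in range(200)])
        assert draws.mean() == pytest.approx(c, rel=0.1)


class TestArmsDraw:
    def test_truncated_standard_normal_moments(self, rng):
        draws = np.empty(10_000)
        x = 0.5
        for i in range(draws.size):
            x = sb.arms_draw(lambda z: -0.5 * z * z, (-10.0, 10.0), init=7,
                             previous_value=x, rng=rng)
            draws[i] = x
        assert abs(draws.mean()) < 0.05
        assert draws.var() == pytest.approx(1.0, abs=0.05)

    def test_exponential_mean(self, rng):
        # Exp(1) on [0, 50] is log-linear, so the envelope is exact
        draws = np.empty(10_000)
        x = 1.0
        for i in range(draws.size):
            x = sb.arms_draw(lambda z: -z, (0.0, 50.0), init=7,
                             previous_value=x, rng=rng)
            draws[i] = x
        assert draws.mean() == pytest.approx(1.0, abs=0.03)

    def test_non_log_concave_target(self, rng):
        # equal-weight normal mixture at +/-3: the Metropolis correction
        # must preserve symmetry even though the envelope cannot dominate
        def logp(z):
            return np.logaddexp(-0.5 * (z + 3) ** 2, -0.5 * (z - 3) ** 2)

        draws = np.empty(10_000)
        x = -3.0
        for i in range(draws.size):
            x = sb.arms_draw(logp, (-12.0, 12.0), init=9, previous_value=x, rng=rng)
            draws[i] = x
        assert (draws > 0).mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_support(self):
        with pytest.raises(ValueError):
            sb.arms_draw(lambda z: -z * z, (1.0, 1.0), init=5)

    def test_no_finite_density(self, rng):
        with pytest.raises(SamplerError):
            sb.arms_draw(lambda z: -math.inf, (0.0, 1.0), init=5, rng=rng)


class TestGibbsAndSummaries:
    def test_smoke_run_structure(self, toy_sensorgram):
        cfg = sb.SamplerConfig(n_iterations=3, burn_in=0, seed=4)
        chain = sb.gibbs_run(toy_sensorgram, KM, init=THETA, cfg=cfg)
        assert len(chain) == 3
        priors = sb.PriorSpec()
        for j, name in enumerate(("ka", "kd", "A0", "Rmax", "R0")):
            lo, hi = priors.support(name)
            col = chain.samples[:, j]
            assert np.all((col >= lo) & (col <= hi))
        assert np.all(chain.samples[:, 5] > 0)

    def test_seeded_chains_identical(self, toy_sensorgram):
        cfg = sb.SamplerConfig(n_iterations=25, burn_in=0, seed=12)
        a = sb.gibbs_run(toy_sensorgram, KM, init=THETA, cfg=cfg)
        b = sb.gibbs_run(toy_sensorgram, KM, init=THETA, cfg=cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_data_numerically_stable(self, case_iv_scenario):
        # sigma2 initialised tiny on exact data: no NaN for 500 iterations
        scn = dataclasses.replace(case_iv_scenario, noise_sd=0.0)
        sg = sb.simulate_sensorgram(scn)
        init = dataclasses.replace(
            scn.theta_true,
            R0=float(sg.responses[sg.assoc_mask][-1]), sigma2=1e-8)
        cfg = sb.SamplerConfig(n_iterations=500, burn_in=0, seed=3, rk4_substeps=1)
        chain = sb.gibbs_run(sg, scn.kM, init=init, cfg=cfg)
        assert np.all(np.isfinite(chain.samples))

    def test_summarize_constant_chain(self):
        samples = np.tile([1e6, 1e-3, 30.0, 31.5, 28.0, 2.25], (10, 1))
        s = sb.summarize(sb.Chain(samples=samples), burn_in=0)
        assert s.mean("ka") == pytest.approx(1e6)
        assert s.interval("ka") == (pytest.approx(1e6), pytest.approx(1e6))
        assert s.mean("KD_nM") == pytest.approx(1.0)

    def test_summarize_percentiles_linear_interpolation(self):
        col = np.arange(1.0, 101.0)
        samples = np.tile(col[:, None], (1, 6))
        s = sb.summarize(sb.Chain(samples=samples), burn_in=0)
        assert s.mean("Rmax") == pytest.approx(50.5)
        lo, hi = s.interval("Rmax")
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_summarize_rejects_empty_segment(self):
        samples = np.ones((5, 6))
        with pytest.raises(ValueError):
            sb.summarize(sb.Chain(samples=samples), burn_in=5)

    def test_burn_in_must_leave_samples(self):
        with pytest.raises(ValueError):
            sb.SamplerConfig(n_iterations=10, burn_in=10)
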