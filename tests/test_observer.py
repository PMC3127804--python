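import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import grid_posterior, ks_critical_value
from sizedist import (
    HAPTIC,
    MAP,
    NO_HAPTIC,
    SAMPLE_AVERAGE,
    DecisionPolicy,
    NoiseModel,
    ObserverKnowledge,
    ParameterError,
    PosteriorBelief,
    SceneStimulus,
    Sensations,
    ValidationError,
    compute_posterior,
    decide,
    get_model,
    response_likelihood,
    sense,
    simulate_responses,
)
from sizedist.observer import (
    ResponseRecord,
    expand_theta,
    haptic_weights,
    no_haptic_weights,
    response_loglik,
    response_moments,
)

KNOWLEDGE = ObserverKnowledge(
    sigma_phi=0.05, sigma_h=0.1, mu_d=6.1300143837, sigma_d=0.3,
    mu_s=3.2869757626, sigma_s=0.3,
)

positive_sd = st.floats(min_value=0.01, max_value=2.0, allow_nan=False)


# ---------------------------------------------------------------------------
# sense
# ---------------------------------------------------------------------------


class TestSense:
    def test_zero_noise_exact(self, rng):
        st_ = SceneStimulus(d_true=6.0, s_true=3.0, condition=HAPTIC)
        noise = NoiseModel(sigma_phi_true=0.0, sigma_h_true=0.0, sigma_m=0.0)
        sens = sense(st_, noise, rng)
        assert sens.phi == -3.0
        assert sens.h == 3.0

    def test_no_haptic_trial_has_no_h(self, rng):
        st_ = SceneStimulus(d_true=6.0, s_true=3.0, condition=NO_HAPTIC)
        noise = NoiseModel(sigma_phi_true=0.1, sigma_h_true=0.5, sigma_m=0.0)
        assert sense(st_, noise, rng).h is None

    def test_monte_carlo_moments(self, rng):
        n = 100_000
        st_ = SceneStimulus(d_true=6.0, s_true=3.0, condition=HAPTIC)
        noise = NoiseModel(sigma_phi_true=0.12, sigma_h_true=0.07, sigma_m=0.0)
        phis = np.array([sense(st_, noise, rng).phi for _ in range(n)])
        se_mean = noise.sigma_phi_true / math.sqrt(n)
        se_sd = noise.sigma_phi_true / math.sqrt(2 * n)
        assert abs(phis.mean() - (-3.0)) < 4 * se_mean
        assert abs(phis.std(ddof=1) - noise.sigma_phi_true) < 4 * se_sd

    def test_non_finite_stimulus_rejected(self):
        with pytest.raises(ValidationError):
            SceneStimulus(d_true=math.nan, s_true=3.0, condition=HAPTIC)
        with pytest.raises(ValidationError):
            SceneStimulus(d_true=6.0, s_true=math.inf, condition=HAPTIC)


# ---------------------------------------------------------------------------
# compute_posterior
# ---------------------------------------------------------------------------


class TestComputePosterior:
    def test_frozen_weights(self):
        """Weights for (0.05, 0.1, 0.3, 0.3), certified by grid integration.

        (The sum-to-one identity pins these: w_h + w_s + w_d = 1 exactly.)
        """
        w = haptic_weights(0.05**2, 0.1**2, 0.3**2, 0.3**2)
        expected = (0.8866995074, 0.7980295567, 0.0886699507, 0.1133004926)
        assert np.allclose(w, expected, atol=1e-9)
        assert w[1] + w[2] + w[3] == pytest.approx(1.0, abs=1e-12)

    def test_grid_oracle_haptic(self):
        sens = Sensations(phi=-3.0, h=3.0)
        belief = compute_posterior(sens, KNOWLEDGE, use_haptic=True)
        mu_g, var_g = grid_posterior(
            sens.phi, sens.h, KNOWLEDGE.sigma_phi, KNOWLEDGE.sigma_h,
            KNOWLEDGE.mu_s, KNOWLEDGE.sigma_s, KNOWLEDGE.mu_d, KNOWLEDGE.sigma_d,
        )
        assert belief.mu_post == pytest.approx(mu_g, rel=1e-4)
        assert belief.var_post == pytest.approx(var_g, rel=1e-3)
        assert belief.mu_post == pytest.approx(6.0401768205, abs=1e-9)
        assert belief.var_post == pytest.approx(0.0101970443, abs=1e-9)

    def test_grid_oracle_no_haptic(self):
        sens = Sensations(phi=-3.1)
        belief = compute_posterior(sens, KNOWLEDGE, use_haptic=False)
        mu_g, var_g = grid_posterior(
            sens.phi, None, KNOWLEDGE.sigma_phi, KNOWLEDGE.sigma_h,
            KNOWLEDGE.mu_s, KNOWLEDGE.sigma_s, KNOWLEDGE.mu_d, KNOWLEDGE.sigma_d,
        )
        assert belief.mu_post == pytest.approx(mu_g, rel=1e-4)
        assert belief.var_post == pytest.approx(var_g, rel=1e-3)

    def test_sigma_h_inf_reduces_to_no_haptic(self):
        sens = Sensations(phi=-3.0, h=3.0)
        wide = ObserverKnowledge(
            sigma_phi=0.05, sigma_h=1e6, mu_d=6.0, sigma_d=0.3, mu_s=3.0, sigma_s=0.3
        )
        hap = compute_posterior(sens, wide, use_haptic=True)
        noh = compute_posterior(sens, wide, use_haptic=False)
        assert hap.mu_post == pytest.approx(noh.mu_post, abs=1e-6)
        assert hap.var_post == pytest.approx(noh.var_post, abs=1e-6)
        w_hap, w_noh = hap.weights, noh.weights
        assert w_hap[0] == pytest.approx(w_noh[0], abs=1e-6)
        assert w_hap[1] == pytest.approx(0.0, abs=1e-6)

    def test_flat_distance_prior_limit(self):
        sens = Sensations(phi=-3.0, h=3.0)
        flat = ObserverKnowledge(
            sigma_phi=0.05, sigma_h=0.1, mu_d=6.0, sigma_d=1e6, mu_s=3.0, sigma_s=0.3
        )
        belief = compute_posterior(sens, flat, use_haptic=True)
        w_phi, w_h, w_s, w_d = belief.weights
        assert w_d == pytest.approx(0.0, abs=1e-9)
        # mean driven by cues and size prior only
        assert belief.mu_post == pytest.approx(
            -w_phi * sens.phi + w_h * sens.h + w_s * 3.0, abs=1e-3
        )

    def test_missing_h_rejected(self):
        with pytest.raises(ValidationError):
            compute_posterior(Sensations(phi=-3.0), KNOWLEDGE, use_haptic=True)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ParameterError):
            ObserverKnowledge(
                sigma_phi=0.0, sigma_h=0.1, mu_d=6.0, sigma_d=0.3, mu_s=3.0, sigma_s=0.3
            )

    @given(
        v=st.tuples(positive_sd, positive_sd, positive_sd, positive_sd),
    )
    @settings(max_examples=200, deadline=None)
    def test_weight_normalization_property(self, v):
        sphi, sh, ss, sd = v
        w_phi, w_h, w_s, w_d = haptic_weights(sphi**2, sh**2, ss**2, sd**2)
        assert w_h + w_s + w_d == pytest.approx(1.0, abs=1e-10)
        assert w_phi == pytest.approx(w_h + w_s, abs=1e-10)
        w0_phi, w0_d = no_haptic_weights(sphi**2, ss**2, sd**2)
        assert w0_phi + w0_d == pytest.approx(1.0, abs=1e-10)

    @given(
        v=st.tuples(positive_sd, positive_sd, positive_sd, positive_sd),
    )
    @settings(max_examples=100, deadline=None)
    def test_haptic_benefit_property(self, v):
        """Touch strictly reduces posterior variance for any finite sigma_h."""
        sphi, sh, ss, sd = v
        _, _, _, w_d = haptic_weights(sphi**2, sh**2, ss**2, sd**2)
        var_h = sd**2 * w_d
        var_0 = sd**2 * (sphi**2 + ss**2) / (sd**2 + sphi**2 + ss**2)
        assert var_h < var_0

    def test_oracle_equivalence_random_tuples(self):
        """100 random parameter/sensation tuples vs grid integration, coarser
        grid than the acceptance run to keep the unit suite quick."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            sphi, sh, ss, sd = rng.uniform(0.05, 0.35, size=4)
            mu_s, mu_d = rng.uniform(2.5, 6.5, size=2)
            phi = rng.normal(mu_s - mu_d, 0.3)
            h = float(rng.normal(mu_s, 0.3)) if rng.random() < 0.5 else None
            know = ObserverKnowledge(
                sigma_phi=sphi, sigma_h=sh, mu_d=mu_d, sigma_d=sd, mu_s=mu_s, sigma_s=ss
            )
            belief = compute_posterior(Sensations(phi=phi, h=h), know, use_haptic=h is not None)
            mu_g, var_g = grid_posterior(phi, h, sphi, sh, mu_s, ss, mu_d, sd, step=0.004)
            assert belief.mu_post == pytest.approx(mu_g, rel=1e-3, abs=1e-3)
            assert belief.var_post == pytest.approx(var_g, rel=1e-3)


# ---------------------------------------------------------------------------
# decide
# ---------------------------------------------------------------------------


class TestDecide:
    BELIEF = PosteriorBelief(mu_post=6.0, var_post=0.01, weights=(0.8, 0.7, 0.1, 0.2))

    def test_map_zero_motor_noise_deterministic(self, rng):
        r = decide(self.BELIEF, DecisionPolicy(rule=MAP), sigma_m=0.0, rng=rng)
        assert r == 6.0

    def test_single_sample_variance(self, rng):
        sigma_m = 0.05
        n = 100_000
        rs = np.array([
            decide(self.BELIEF, DecisionPolicy(rule=SAMPLE_AVERAGE, K=1), sigma_m, rng)
            for _ in range(n)
        ])
        expected_var = self.BELIEF.var_post + sigma_m**2
        se = expected_var * math.sqrt(2.0 / n)
        assert abs(rs.var(ddof=1) - expected_var) < 4 * se

    def test_k4_variance(self, rng):
        sigma_m = 0.03
        n = 100_000
        rs = np.array([
            decide(self.BELIEF, DecisionPolicy(rule=SAMPLE_AVERAGE, K=4), sigma_m, rng)
            for _ in range(n)
        ])
        expected_sd = math.sqrt(self.BELIEF.var_post / 4 + sigma_m**2)
        se_sd = expected_sd / math.sqrt(2 * n)
        assert abs(rs.std(ddof=1) - expected_sd) < 4 * se_sd

    def test_k_below_one_rejected(self):
        with pytest.raises(ParameterError):
            DecisionPolicy(rule=SAMPLE_AVERAGE, K=0)

    def test_exponentiated_posterior_identity(self, rng):
        """Mean of K draws ~ one draw from the K-th-power posterior.

        Analytically both are N(mu, var/K); checked by a two-sample KS test.
        """
        k, n = 5, 50_000
        mu, var = self.BELIEF.mu_post, self.BELIEF.var_post
        means_of_k = rng.normal(mu, math.sqrt(var), size=(n, k)).mean(axis=1)
        power_draws = rng.normal(mu, math.sqrt(var / k), size=n)
        stat = stats.ks_2samp(means_of_k, power_draws).statistic
        assert stat < 1.628 * math.sqrt(2.0 / n)  # two-sample 1% critical value


# ---------------------------------------------------------------------------
# response_likelihood
# ---------------------------------------------------------------------------


def _random_theta(model, rng):
    full = {
        "sigma_phi_true": rng.uniform(0.05, 0.15),
        "sigma_phi": rng.uniform(0.05, 0.2),
        "sigma_h_true": rng.uniform(0.04, 0.12),
        "sigma_h": rng.uniform(0.05, 0.3),
        "mu_d": rng.uniform(5.5, 6.5),
        "sigma_d": rng.uniform(0.15, 0.4),
        "mu_s": rng.uniform(2.8, 3.6),
        "sigma_s": rng.uniform(0.2, 0.5),
        "sigma_m": rng.uniform(0.01, 0.05),
        # integer K so forward simulation and the continuous-K likelihood agree
        "K": float(rng.integers(1, 9)),
    }
    from sizedist.mcmc import active_parameters

    return {n: full[n] for n in active_parameters(model)}


class TestResponseLikelihood:
    def test_degenerate_mean(self):
        """With all noise at (test-only) zero and MAP, the response equals the
        closed-form mean built from the haptic weights."""
        model = get_model(8)  # haptic, MAP
        theta = {
            "sigma_phi": 1e-9, "sigma_h_true": 1e-9, "sigma_h": 0.1,
            "mu_d": 6.1, "sigma_d": 0.3, "mu_s": 3.3, "sigma_s": 0.3,
            "sigma_m": 1e-9,
        }
        d_true, s_true = 6.0, 3.0
        m, v = response_moments(model, theta, d_true, s_true, True)
        w_phi, w_h, w_s, w_d = haptic_weights(
            theta["sigma_phi"] ** 2, theta["sigma_h"] ** 2,
            theta["sigma_s"] ** 2, theta["sigma_d"] ** 2,
        )
        expected = (
            w_phi * d_true - w_s * s_true + w_s * theta["mu_s"] + w_d * theta["mu_d"]
        )
        assert float(m) == pytest.approx(expected, abs=1e-12)
        assert float(v) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model_id,condition", [(7, HAPTIC), (7, NO_HAPTIC), (3, HAPTIC)])
    def test_simulation_matches_closed_form(self, model_id, condition):
        rng = np.random.default_rng(model_id * 100 + (condition == HAPTIC))
        model = get_model(model_id)
        theta = _random_theta(model, rng)
        st_ = SceneStimulus(d_true=6.1, s_true=3.2, condition=condition)
        n = 100_000
        recs = simulate_responses([st_] * n, theta, model, rng)
        rs = np.array([rec.r for rec in recs])
        m, v = response_moments(model, theta, st_.d_true, st_.s_true, condition == HAPTIC)
        m, sd = float(m), math.sqrt(float(v))
        assert abs(rs.mean() - m) < 4 * sd / math.sqrt(n)
        assert abs(rs.std(ddof=1) - sd) < 4 * sd / math.sqrt(2 * n)
        stat = stats.kstest(rs, "norm", args=(m, sd)).statistic
        assert stat < ks_critical_value(n)

    def test_haptic_sigma_h_inf_equals_no_haptic_model(self):
        rng = np.random.default_rng(5)
        m_hap = get_model(5)   # haptic, both knowledges inaccurate, sampling
        m_noh = get_model(1)   # no-haptic, image knowledge inaccurate, sampling
        theta_noh = _random_theta(m_noh, rng)
        theta_hap = dict(theta_noh, sigma_h_true=1e6, sigma_h=1e6)
        st_ = SceneStimulus(d_true=6.1, s_true=3.2, condition=HAPTIC)
        rec = ResponseRecord(stimulus=st_, r=6.05)
        ll_h = response_likelihood(rec, theta_hap, m_hap)
        ll_0 = response_likelihood(rec, theta_noh, m_noh)
        # w_h ~ v_d*v_s/v_h^2 -> 0, w_h^2 * sigma_h_true^2 ~ 1/v_h -> 0
        assert ll_h == pytest.approx(ll_0, abs=1e-6)

    def test_non_finite_response_rejected(self):
        st_ = SceneStimulus(d_true=6.0, s_true=3.0, condition=HAPTIC)
        with pytest.raises(ValidationError):
            ResponseRecord(stimulus=st_, r=math.nan)

    def test_likelihood_consistency_grid(self, model7):
        """Average log-likelihood of data simulated at theta* peaks at theta*
        on a coarse multiplicative grid around it."""
        rng = np.random.default_rng(11)
        from sizedist.experiment import reference_theta

        theta_star = reference_theta(model7)
        d = rng.uniform(math.log(300), math.log(640), size=4000)
        s = rng.uniform(math.log(14), math.log(42), size=4000)
        hap = rng.random(4000) < 0.5
        stimuli = [
            SceneStimulus(d_true=d[i], s_true=s[i], condition=HAPTIC if hap[i] else NO_HAPTIC)
            for i in range(4000)
        ]
        recs = simulate_responses(stimuli, theta_star, model7, rng)
        r = np.array([rec.r for rec in recs])
        ll_star = response_loglik(model7, theta_star, d, s, hap, r)
        for name in ("sigma_phi", "sigma_h_true", "sigma_m", "mu_d"):
            for factor in (0.6, 1.6):
                theta = dict(theta_star)
                theta[name] = theta_star[name] * factor
                assert response_loglik(model7, theta, d, s, hap, r) < ll_star


# ---------------------------------------------------------------------------
# simulate_responses
# ---------------------------------------------------------------------------


class TestSimulateResponses:
    def test_seeded_determinism(self, model7, theta7):
        stim = [
            SceneStimulus(d_true=6.0, s_true=3.0, condition=HAPTIC),
            SceneStimulus(d_true=6.2, s_true=3.4, condition=NO_HAPTIC),
        ]
        a = simulate_responses(stim, theta7, model7, np.random.default_rng(42))
        b = simulate_responses(stim, theta7, model7, np.random.default_rng(42))
        assert a == b

    def test_empty_stimuli_rejected(self, model7, theta7, rng):
        with pytest.raises(ValidationError):
            simulate_responses([], theta7, model7, rng)

    # strongly informative haptic observer: accurate haptic knowledge, few samples
    STRONG = {
        "sigma_phi": 0.1, "sigma_h": 0.05, "mu_d": 6.13, "sigma_d": 0.2156,
        "mu_s": 3.287, "sigma_s": 0.3079, "sigma_m": 0.02, "K": 1.0,
    }

    def _variances(self, model, theta, rng, n=4000):
        hap_st = SceneStimulus(d_true=6.1, s_true=3.2, condition=HAPTIC)
        noh_st = SceneStimulus(d_true=6.1, s_true=3.2, condition=NO_HAPTIC)
        v_h = np.var([rec.r for rec in simulate_responses([hap_st] * n, theta, model, rng)])
        v_0 = np.var([rec.r for rec in simulate_responses([noh_st] * n, theta, model, rng)])
        return v_h, v_0

    def test_sampling_observer_haptic_less_variable(self, rng):
        model = get_model(11)  # haptic, accurate knowledge, sampling
        v_h, v_0 = self._variances(model, self.STRONG, rng)
        assert v_h < v_0
        # closed-form v agrees on the ordering
        m_h, vv_h = response_moments(model, self.STRONG, 6.1, 3.2, True)
        m_0, vv_0 = response_moments(model, self.STRONG, 6.1, 3.2, False)
        assert float(vv_h) < float(vv_0)

    def test_map_observer_haptic_more_variable(self, rng):
        """MAP flips the ordering: the prior does not vary between trials,
        so vision-only responses fluctuate less than haptic ones."""
        theta = {k: v for k, v in self.STRONG.items() if k != "K"}
        model = get_model(12)  # haptic, accurate knowledge, MAP
        v_h, v_0 = self._variances(model, theta, rng)
        assert v_0 < v_h
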