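"""Network primitives, rollout semantics and the free-energy objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvrnn_attenuation import (NetworkConfig, accuracy_term, compute_posterior,
                               compute_prior, emit_prediction, executive_prior,
                               free_energy, gaussian_kl, rollout,
                               sample_latent, step_deterministic)
from pvrnn_attenuation.training import draw_noise, init_adaptive, init_parameters

from conftest import micro_config


def zero_params(cfg, N=1):
    params = init_parameters(cfg, N, seed=0, bias_variance=0.0)
    return {k: np.zeros_like(v) for k, v in params.items()}


class TestStepDeterministic:
    def test_zero_fixed_point(self):
        h, d = step_deterministic(np.zeros(3), np.zeros(3), np.array([2., 2., 4.]))
        assert np.all(h == 0) and np.all(d == 0)

    def test_pure_leak(self):
        v = np.array([1.0, -2.0])
        tau = np.array([2.0, 4.0])
        h, _ = step_deterministic(v, np.zeros(2), tau)
        assert h == pytest.approx((1 - 1 / tau) * v)

    def test_unit_drive_tau2(self):
        h, d = step_deterministic(np.zeros(1), np.ones(1), np.array([2.0]))
        assert h == pytest.approx(0.5)
        assert d == pytest.approx(np.tanh(0.5))


class TestBeliefs:
    def test_prior_at_zero_history_is_standard_normal(self):
        w = np.random.default_rng(0).normal(size=(2, 4))
        mu, sg = compute_prior(np.zeros(4), w, w)
        assert np.all(mu == 0) and np.all(sg == 1)

    def test_prior_sigma_exp_head(self):
        # sigma pre-activation of -2 gives e^-2
        w_sigma = np.array([[-2.0]])
        mu, sg = compute_prior(np.ones(1), np.zeros((1, 1)), w_sigma)
        assert sg == pytest.approx(np.exp(-2), rel=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(deadline=None)
    def test_prior_sigma_strictly_positive(self, w, d):
        _, sg = compute_prior(np.array([d]), np.array([[w]]), np.array([[w]]))
        assert sg > 0

    def test_posterior_examples(self):
        mu, sg = compute_posterior(np.zeros(2), np.zeros(2))
        assert np.all(mu == 0) and np.all(sg == 1)
        mu, sg = compute_posterior(np.array([0.5]), np.array([-1.0]))
        assert mu == pytest.approx(np.tanh(0.5))
        assert sg == pytest.approx(np.exp(-1))

    def test_posterior_saturates_inside_unit_interval(self):
        mu, _ = compute_posterior(np.array([40.0]), np.array([0.0]))
        assert 0.999 < mu[0] <= 1.0

    def test_posterior_rejects_non_finite(self):
        with pytest.raises(FloatingPointError):
            compute_posterior(np.array([np.nan]), np.zeros(1))

    def test_sample_latent(self):
        assert sample_latent(0.3, 0.7, 0.0) == pytest.approx(0.3)
        assert sample_latent(0.2, 0.5, 1.0) == pytest.approx(0.7)
        assert sample_latent(0.2, 0.0, 5.0) == pytest.approx(0.2)


class TestPredictionAndObjective:
    def test_zero_readout(self):
        assert np.all(emit_prediction(np.ones(4), np.zeros((2, 4))) == 0)

    def test_single_unit_readout(self):
        out = emit_prediction(np.array([0.3]), np.array([[2.0]]))
        assert out == pytest.approx(np.tanh(0.6))

    def test_accuracy_zero_at_perfect_prediction(self):
        x = np.random.default_rng(1).normal(size=5)
        assert accuracy_term(x, x) == 0

    def test_accuracy_dimension_normalized(self):
        # extero error (0.2, 0): 0.5 * 0.04 / 2
        assert accuracy_term(np.array([0.2, 0.0]), np.zeros(2)) == \
            pytest.approx(0.01)

    def test_accuracy_quadratic_scaling(self):
        e = np.array([0.1, -0.3, 0.2])
        assert accuracy_term(3 * e, np.zeros(3)) == \
            pytest.approx(9 * accuracy_term(e, np.zeros(3)))

    def test_kl_identity_zero(self):
        mu = np.array([0.3, -0.1]); sg = np.array([0.5, 2.0])
        assert gaussian_kl(mu, sg, mu, sg) == pytest.approx(0.0, abs=1e-15)

    def test_kl_unit_shift(self):
        # KL(N(1,1) || N(0,1)) = 1/2
        assert gaussian_kl(np.array([1.0]), np.array([1.0]),
                           np.array([0.0]), np.array([1.0])) == \
            pytest.approx(0.5)

    @given(st.floats(-0.9, 0.9), st.floats(0.2, 3), st.floats(-0.9, 0.9),
           st.floats(0.2, 3))
    @settings(deadline=None)
    def test_kl_nonnegative(self, mq, sq, mp, sp):
        kl = gaussian_kl(np.array([mq]), np.array([sq]),
                         np.array([mp]), np.array([sp]))
        assert kl >= -1e-12

    def test_kl_rejects_zero_prior_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kl(np.zeros(1), np.ones(1), np.zeros(1), np.zeros(1))

    def test_kl_monte_carlo_oracle(self):
        """Closed form agrees with a 10^6-sample Monte-Carlo KL estimate."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            mq, mp = rng.uniform(-0.8, 0.8, 2)
            sq, sp = rng.uniform(0.3, 1.5, 2)
            z = rng.normal(mq, sq, size=1_000_000)
            log_q = -0.5 * ((z - mq) / sq) ** 2 - np.log(sq)
            log_p = -0.5 * ((z - mp) / sp) ** 2 - np.log(sp)
            mc = np.mean(log_q - log_p)
            closed = gaussian_kl(np.array([mq]), np.array([sq]),
                                 np.array([mp]), np.array([sp]))
            assert closed == pytest.approx(mc, abs=0.01)


def test_executive_prior_only_at_first_step():
    assert executive_prior(1) == (0.0, 1.0)
    assert executive_prior(2) is None
    assert executive_prior(200) is None


class TestRollout:
    def test_zero_network_single_step(self, micro_cfg):
        params = zero_params(micro_cfg)
        adaptive = init_adaptive(micro_cfg, 1, 1, 1)
        eps = draw_noise(micro_cfg, 1, 1, 1, None)
        x = {"E": np.zeros((1, 1, 1, 2)), "P": np.zeros((1, 1, 1, 3))}
        ro = rollout(params, adaptive, eps, x, micro_cfg)
        for m in ("E", "P"):
            assert np.all(ro.xhat[m] == 0)
        for a in ("E", "P", "A"):
            assert np.all(ro.mu_p[a] == 0) and np.all(ro.sg_p[a] == 1)
            assert np.all(ro.mu_q[a] == 0) and np.all(ro.sg_q[a] == 1)

    def test_deterministic_given_injected_noise(self, micro_cfg):
        params = init_parameters(micro_cfg, 2, seed=4, bias_variance=1.0)
        adaptive = init_adaptive(micro_cfg, 2, 3, 7)
        rng = np.random.default_rng(0)
        for k in adaptive:
            adaptive[k] += rng.normal(0, 0.2, adaptive[k].shape)
        eps = draw_noise(micro_cfg, 7, 2, 3, np.random.default_rng(9))
        x = {"E": rng.normal(size=(7, 1, 3, 2)) * 0.2,
             "P": rng.normal(size=(7, 1, 3, 3)) * 0.2}
        r1 = rollout(params, adaptive, eps, x, micro_cfg)
        r2 = rollout(params, adaptive, eps, x, micro_cfg)
        assert np.array_equal(r1.f_t, r2.f_t)
        assert np.array_equal(r1.xhat["E"], r2.xhat["E"])

    def test_executive_posterior_constant_over_sequence(self):
        cfg = NetworkConfig()
        params = init_parameters(cfg, 1, seed=2)
        adaptive = init_adaptive(cfg, 1, 2, 50)
        adaptive["a_mu_C"] += 0.37
        adaptive["a_sg_C"] -= 0.21
        eps = draw_noise(cfg, 50, 1, 2, np.random.default_rng(1))
        x = {"E": np.zeros((50, 1, 2, 2)), "P": np.zeros((50, 1, 2, 3))}
        ro = rollout(params, adaptive, eps, x, cfg)
        # exactly equal at every pair of steps
        assert np.all(ro.mu_q["C"] == ro.mu_q["C"][0])
        assert np.all(ro.sg_q["C"] == ro.sg_q["C"][0])

    def test_executive_complexity_only_at_first_step(self):
        cfg = micro_config()
        params = init_parameters(cfg, 1, seed=2, bias_variance=0.1)
        adaptive = init_adaptive(cfg, 1, 1, 5)
        adaptive["a_mu_C"] += 0.5
        eps = draw_noise(cfg, 5, 1, 1, None)
        x = {"E": np.zeros((5, 1, 1, 2)), "P": np.zeros((5, 1, 1, 3))}
        ro = rollout(params, adaptive, eps, x, cfg)
        assert ro.kl["C"][0] > 0
        assert np.all(ro.kl["C"][1:] == 0)
        # a window that does not contain global step 1 has no executive term
        ro2 = rollout(params, adaptive, eps, x, cfg, t_offset=3)
        assert np.all(ro2.kl["C"] == 0)


class TestFreeEnergy:
    def _setup(self, W):
        cfg = micro_config().with_overrides(meta_priors=W)
        params = init_parameters(cfg, 1, seed=5, bias_variance=0.3)
        adaptive = init_adaptive(cfg, 1, 2, 6)
        rng = np.random.default_rng(6)
        for k in adaptive:
            adaptive[k] += rng.normal(0, 0.3, adaptive[k].shape)
        eps = draw_noise(cfg, 6, 1, 2, np.random.default_rng(2))
        x = {"E": rng.uniform(-0.4, 0.4, (6, 1, 2, 2)),
             "P": rng.uniform(-0.4, 0.4, (6, 1, 2, 3))}
        return cfg, params, adaptive, eps, x

    def test_zero_meta_priors_leave_pure_prediction_error(self):
        cfg, params, adaptive, eps, x = self._setup((0.0, 0.0, 0.0))
        ro = rollout(params, adaptive, eps, x, cfg)
        assert ro.f_t == pytest.approx(ro.acc["E"] + ro.acc["P"])

    def test_linear_in_level2_meta_prior(self):
        cfg, params, adaptive, eps, x = self._setup((0.01, 0.02, 0.03))
        ro = rollout(params, adaptive, eps, x, cfg)
        cfg2 = cfg.with_overrides(meta_priors=(0.01, 0.04, 0.03))
        ro2 = rollout(params, adaptive, eps, x, cfg2)
        delta = ro2.f_t.sum() - ro.f_t.sum()
        assert delta == pytest.approx(0.02 * ro.kl["A"].sum(), rel=1e-9)

    def test_breakdown_reassembles_total(self):
        cfg, params, adaptive, eps, x = self._setup((0.01, 0.02, 0.03))
        ro = rollout(params, adaptive, eps, x, cfg)
        fb = free_energy(ro, cfg)
        W1, W2, W3 = cfg.meta_priors
        total = (fb.accuracy_extero + fb.accuracy_proprio
                 + W1 * fb.complexity[1] + W2 * fb.complexity[2]
                 + W3 * fb.complexity[3])
        assert total == pytest.approx(fb.weighted_total)
        assert np.all(fb.complexity[1] >= 0)

    def test_trace_export_covers_all_quantities(self, micro_cfg):
        from pvrnn_attenuation.core import rollout_to_frame
        params = zero_params(micro_cfg)
        adaptive = init_adaptive(micro_cfg, 1, 1, 4)
        eps = draw_noise(micro_cfg, 4, 1, 1, None)
        x = {"E": np.zeros((4, 1, 1, 2)), "P": np.zeros((4, 1, 1, 3))}
        df = rollout_to_frame(rollout(params, adaptive, eps, x, micro_cfg))
        assert set(df.columns) == {"step", "area", "quantity", "value"}
        assert df.step.max() == 4
        assert {"mu_p", "sigma_q", "kl", "free_energy"} <= \
            set(q.split("_0")[0] for q in df.quantity.unique())

    def test_perfect_fit_with_matched_beliefs_gives_zero(self, micro_cfg):
        params = zero_params(micro_cfg)
        adaptive = init_adaptive(micro_cfg, 1, 1, 4)
        eps = draw_noise(micro_cfg, 4, 1, 1, None)
        x = {"E": np.zeros((4, 1, 1, 2)), "P": np.zeros((4, 1, 1, 3))}
        ro = rollout(params, adaptive, eps, x, micro_cfg)
        # q = p = N(0,1) everywhere except the executive (KL vs N(0,1) = 0)
        assert ro.f_t.sum() == pytest.approx(0.0, abs=1e-12)
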