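"""Learning phase: initialization contracts, optimizer correctness and the
free-energy descent property."""

import numpy as np
import pandas as pd
import pytest

from pvrnn_attenuation import Adam, GeneratorConfig, NetworkConfig, \
    TrainingConfig, build_dataset, rollout, backward
from pvrnn_attenuation.training import (draw_noise, init_adaptive,
                                        init_parameters, learning_metrics,
                                        make_training_data, train)
from pvrnn_attenuation.analysis import moving_average
from pvrnn_attenuation.datagen import SELF_PRODUCED, EXTERNALLY_PRODUCED

from conftest import micro_config


class TestInitialization:
    def test_same_seed_identical(self):
        cfg = NetworkConfig()
        p1 = init_parameters(cfg, 3, seed=9)
        p2 = init_parameters(cfg, 3, seed=9)
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)
        p3 = init_parameters(cfg, 3, seed=10)
        assert not np.array_equal(p1["w_dd_A"], p3["w_dd_A"])

    def test_bias_variance_matches_spec(self):
        # pool ~1e5 bias draws across networks: sample variance near 10
        cfg = NetworkConfig()
        params = init_parameters(cfg, 2300, seed=1)
        biases = np.concatenate([params[f"b_{a}"].ravel()
                                 for a in ("E", "P", "A")])
        assert biases.size >= 1e5
        assert np.var(biases) == pytest.approx(10.0, rel=0.05)
        assert np.mean(biases) == pytest.approx(0.0, abs=0.05)

    def test_weight_bounds_scale_with_fan_in(self):
        cfg = NetworkConfig()
        params = init_parameters(cfg, 50, seed=2)
        assert np.max(np.abs(params["w_dd_A"])) <= 1 / np.sqrt(15)
        assert np.max(np.abs(params["w_dz_A"])) <= 1 / np.sqrt(3)

    def test_initial_posteriors_standard_normal(self, micro_cfg):
        a = init_adaptive(micro_cfg, 1, 2, 5)
        assert all(np.all(v == 0) for v in a.values())
        # tanh(0)=0, exp(0)=1 -> N(0,1) at every step
        assert a["a_mu_C"].shape == (1, 2, 1)  # one pair per sequence

    def test_adaptive_shapes_follow_architecture(self):
        cfg = NetworkConfig()
        a = init_adaptive(cfg, 2, 48, 200)
        assert a["a_mu_A"].shape == (200, 2, 48, 3)
        assert a["a_sg_E"].shape == (200, 2, 48, 1)
        assert a["a_mu_C"].shape == (2, 48, 1)


@pytest.fixture(scope="module")
def tiny_training_setup():
    gcfg = GeneratorConfig(n_train_sequences=4, n_test_extero=1,
                           cycles_per_sequence=2, seed=21)
    self_ds, ext_ds, _ = build_dataset(gcfg)
    data = make_training_data(self_ds, ext_ds)
    return data


class TestTrain:
    def test_zero_learning_rate_is_identity(self, tiny_training_setup):
        data = tiny_training_setup
        cfg = micro_config()
        params = init_parameters(cfg, 1, seed=0)
        adaptive = init_adaptive(cfg, 1, data.n_sequences, data.T)
        snap_p = {k: v.copy() for k, v in params.items()}
        snap_a = {k: v.copy() for k, v in adaptive.items()}
        t_cfg = TrainingConfig(epochs=5, learning_rate=1e-300, seed=0)
        train(data, params, adaptive, t_cfg, cfg)
        for k in params:
            assert params[k] == pytest.approx(snap_p[k], abs=1e-290)
        for k in adaptive:
            assert adaptive[k] == pytest.approx(snap_a[k], abs=1e-290)

    def test_biases_frozen_through_training(self, tiny_training_setup):
        data = tiny_training_setup
        cfg = micro_config()
        params = init_parameters(cfg, 1, seed=1)
        adaptive = init_adaptive(cfg, 1, data.n_sequences, data.T)
        before = {a: params[f"b_{a}"].copy() for a in ("E", "P", "A")}
        train(data, params, adaptive,
              TrainingConfig(epochs=100, seed=1), cfg)
        for a in ("E", "P", "A"):
            assert np.array_equal(params[f"b_{a}"], before[a])
        # weights did move
        assert not np.allclose(params["w_out_P"],
                               init_parameters(cfg, 1, seed=1)["w_out_P"])

    def test_one_adam_step_matches_reference(self, tiny_training_setup):
        """A training step equals an independently coded Adam update applied
        to the same free-energy gradients."""
        data = tiny_training_setup
        cfg = micro_config()
        params = init_parameters(cfg, 1, seed=3)
        adaptive = init_adaptive(cfg, 1, data.n_sequences, data.T)
        # gradients at the initial point, using the same noise stream
        rng = np.random.default_rng([7, 17])
        eps = draw_noise(cfg, data.T, 1, data.n_sequences, rng)
        ro = rollout(params, adaptive, eps, data.x, cfg)
        gp, ga = backward(ro, params, data.x, cfg)
        grads = {**gp, **ga}
        alpha, b1, b2, eeps = 0.001, 0.9, 0.999, 1e-8
        expected = {}
        for k, v in {**params, **adaptive}.items():
            if k.startswith("b_"):
                expected[k] = v.copy()
                continue
            g = grads[k]
            m = (1 - b1) * g / (1 - b1)          # bias-corrected first step
            vv = (1 - b2) * g * g / (1 - b2)
            expected[k] = v - alpha * m / (np.sqrt(vv) + eeps)
        train(data, params, adaptive, TrainingConfig(epochs=1, seed=7), cfg)
        for k, v in expected.items():
            got = params[k] if k in params else adaptive[k]
            assert got == pytest.approx(v, abs=1e-6), k

    def test_free_energy_decreases_over_two_thousand_epochs(
            self, tiny_training_setup):
        """100-epoch-smoothed objective decreases over a 2000-epoch scaled
        run on a fixed seed."""
        data = tiny_training_setup
        cfg = NetworkConfig()
        params = init_parameters(cfg, 1, seed=5, dtype=np.float32)
        adaptive = init_adaptive(cfg, 1, data.n_sequences, data.T,
                                 dtype=np.float32)
        data32 = make_training_data_like(data)
        fes = []
        t_cfg = TrainingConfig(epochs=2000, seed=5, metric_logging_interval=1)
        train(data32, params, adaptive, t_cfg, cfg,
              callback=lambda e, ro: fes.append(float(ro.f_t.sum())))
        sm = moving_average(np.array(fes), window=100)
        assert sm[-1] < sm[99]
        assert sm[-1] < 0.5 * sm[99]  # substantial descent, not a wiggle


def make_training_data_like(data):
    from pvrnn_attenuation.training import TrainingData
    return TrainingData(x={k: v.astype(np.float32) for k, v in data.x.items()},
                        contexts=data.contexts)


class TestLearningMetrics:
    def test_posterior_response_arithmetic(self):
        # mu sequence [0, 1, 0] for a single latent: mean |delta| = 1
        mu = np.array([0.0, 1.0, 0.0])
        assert np.abs(np.diff(mu)).mean() == 1.0

    def test_metrics_on_fresh_network(self, tiny_training_setup):
        data = tiny_training_setup
        cfg = micro_config()
        params = init_parameters(cfg, 2, seed=8)
        adaptive = init_adaptive(cfg, 2, data.n_sequences, data.T)
        df = learning_metrics(params, adaptive, data, cfg)
        assert set(df.context) == {SELF_PRODUCED, EXTERNALLY_PRODUCED}
        assert len(df) == 4  # 2 networks x 2 contexts
        # zero adaptive state: constant posterior means -> zero response
        assert np.all(df.posterior_response == 0)
        # all sigma pre-activations zero at t=1 only; sigma values positive
        assert np.all(df.prior_sigma > 0)

    def test_curve_epochs_increase(self, tiny_training_setup):
        data = tiny_training_setup
        cfg = micro_config()
        params = init_parameters(cfg, 1, seed=8)
        adaptive = init_adaptive(cfg, 1, data.n_sequences, data.T)
        curves = train(data, params, adaptive,
                       TrainingConfig(epochs=30, seed=8,
                                      metric_logging_interval=10), cfg)
        per_ctx = curves[curves.context == SELF_PRODUCED]
        assert list(per_ctx.epoch) == sorted(per_ctx.epoch)
        assert {"posterior_response", "prior_sigma",
                "free_energy"} <= set(curves.columns)
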