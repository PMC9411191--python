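"""Test phase: online sliding-window posterior inference with fixed weights,
closed-loop action via PID control, and a scripted context switch.

Per trial step t the adaptive variables of the window [t-H+1, t] (truncated
at the sequence start) are re-optimized for a fixed number of Adam
iterations against the windowed free energy ("error regression" /
postdiction); the network then generates the prior for t+1, the posterior at
t+1 is initialized from that prior, the proprioceptive prediction is sent to
the PID controller as the target posture, and the next 5-D sensation is
observed. The executive area keeps a single sequence-constant posterior that
is updated inside every window but never re-initialized.

Trials are batched: N trained networks each run the same J exteroceptive
test sequences, laid out as the rollout's (network, sequence) axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .config import (NetworkConfig, TrialConfig, DETERMINISTIC_AREAS,
                     SENSORY_AREAS)
from .core import Arrays, backward, rollout, _zeros_state
from .datagen import SELF_PRODUCED, EXTERNALLY_PRODUCED
from .environment import arm_at_posture, pid_step
from .kinematics import ANGLE_RANGE
from .optim import Adam
from .perf import tune_malloc
from .training import draw_noise


@dataclass
class TrialLog:
    """Per-step record of a batch of trials (time-major; batch axes (N, J))."""

    x: Arrays                    # observations: "E" (T,N,J,2), "P" (T,N,J,3)
    xhat: Arrays                 # online one-step-ahead predictions
    mu_q: Arrays                 # posterior beliefs per area (T,N,J,z),
    sg_q: Arrays                 # final (postdicted) values
    mu_p: Arrays                 # priors per deterministic area
    sg_p: Arrays
    f_t: np.ndarray              # final-rollout free energy per step (T,N,J)
    f_window: np.ndarray         # online windowed free energy after updates
    exec_mu_online: np.ndarray   # executive posterior mean while step t was
    exec_sg_online: np.ndarray   # current (the belief evolves across steps,
                                 # though it is constant within each window)
    sg_p_online: Arrays          # prior sigma of step t in the window whose
                                 # right edge was t (per deterministic area)
    contexts: np.ndarray         # (T,) labels

    @property
    def total_steps(self) -> int:
        return self.f_t.shape[0]


def init_trial_adaptive(trained_adaptive: Arrays, self_mask: np.ndarray
                        ) -> Dict[str, np.ndarray]:
    """Initial adaptive state for a trial: the elementwise median, across the
    self-produced training sequences, of each first-step adaptive variable
    (all areas, including the sequence-constant executive pair)."""
    if not np.any(self_mask):
        raise ValueError("no self-produced sequences in the trained state")
    out = {}
    for name, arr in trained_adaptive.items():
        if name.endswith("_C"):
            out[name] = np.median(arr[:, self_mask], axis=1)      # (N, z)
        else:
            out[name] = np.median(arr[0][:, self_mask], axis=1)   # (N, z)
    return out


def optimize_window(params: Arrays, a_win: Arrays, x_win: Arrays,
                    frozen: Arrays, net_cfg: NetworkConfig, cfg: TrialConfig,
                    t_offset: int, rng=None):
    """Error regression over one window: fixed-weight Adam iterations on the
    windowed free energy, updating only the window's adaptive variables (and
    the shared executive pair). Returns the final rollout."""
    Tw = x_win["P"].shape[0]
    N, S = frozen["h_A"].shape[:2]
    dtype = params["w_dd_A"].dtype
    opt = Adam(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2,
               eps=cfg.adam_eps)
    for _ in range(cfg.updates_per_step):
        eps = draw_noise(net_cfg, Tw, N, S, rng, dtype)
        ro = rollout(params, a_win, eps, x_win, net_cfg,
                     init_state=frozen, t_offset=t_offset)
        if not np.isfinite(ro.f_t).all():
            raise FloatingPointError("non-finite windowed free energy")
        _, ga = backward(ro, params, x_win, net_cfg, weight_grads=False)
        opt.step(a_win, ga)
    eps0 = draw_noise(net_cfg, Tw, N, S, rng=None, dtype=dtype)
    return rollout(params, a_win, eps0, x_win, net_cfg,
                   init_state=frozen, t_offset=t_offset)


def _window_views(a: Arrays, lo: int, hi: int) -> Arrays:
    return {k: (v if k.endswith("_C") else v[lo:hi]) for k, v in a.items()}


def run_trial(params: Arrays, trained_adaptive: Arrays, self_mask: np.ndarray,
              test_extero: np.ndarray, net_cfg: NetworkConfig,
              cfg: TrialConfig, *, set_posture=(0.0, 0.0, 0.0)) -> TrialLog:
    """Run J closed-loop test trials for each of N trained networks.

    Parameters
    ----------
    params:
        Trained weights with network axis N.
    trained_adaptive, self_mask:
        Learning-phase adaptive state and the boolean mask of its
        self-produced sequences (source of the initial condition).
    test_extero:
        (J, T, 2) exteroceptive test sequences driving the externally
        produced phase; every network runs all J of them.
    """
    T, H = cfg.total_steps, cfg.window
    N = params["w_dd_A"].shape[0]
    J = test_extero.shape[0]
    dtype = params["w_dd_A"].dtype
    tune_malloc()
    if test_extero.shape[1] < T:
        raise ValueError("test exteroception shorter than the trial")
    a1 = init_trial_adaptive(trained_adaptive, self_mask)

    zd = net_cfg.latent_dims
    a: Arrays = {}
    for area in DETERMINISTIC_AREAS:
        a[f"a_mu_{area}"] = np.zeros((T, N, J, zd[area]), dtype=dtype)
        a[f"a_sg_{area}"] = np.zeros((T, N, J, zd[area]), dtype=dtype)
        a[f"a_mu_{area}"][0] = a1[f"a_mu_{area}"][:, None]
        a[f"a_sg_{area}"][0] = a1[f"a_sg_{area}"][:, None]
    a["a_mu_C"] = np.broadcast_to(a1["a_mu_C"][:, None],
                                  (N, J, zd["C"])).copy().astype(dtype)
    a["a_sg_C"] = np.broadcast_to(a1["a_sg_C"][:, None],
                                  (N, J, zd["C"])).copy().astype(dtype)

    x = {"E": np.zeros((T, N, J, net_cfg.extero_dim), dtype=dtype),
         "P": np.zeros((T, N, J, net_cfg.proprio_dim), dtype=dtype)}
    xhat = {"E": np.zeros((T, N, J, net_cfg.extero_dim), dtype=dtype),
            "P": np.zeros((T, N, J, net_cfg.proprio_dim), dtype=dtype)}
    f_window = np.zeros((T, N, J), dtype=dtype)
    exec_mu = np.zeros((T, N, J, zd["C"]), dtype=dtype)
    exec_sg = np.zeros((T, N, J, zd["C"]), dtype=dtype)
    sg_p_online = {a: np.zeros((T, N, J, zd[a]), dtype=dtype)
                   for a in DETERMINISTIC_AREAS}
    contexts = np.array([SELF_PRODUCED if t <= cfg.switch_step
                         else EXTERNALLY_PRODUCED for t in range(1, T + 1)])

    rng = (np.random.default_rng([cfg.seed, 23]) if cfg.sample_noise else None)
    arm = arm_at_posture(set_posture, batch_shape=(N, J))
    x["P"][0] = arm.proprio
    x["E"][0] = arm.hand  # step 1 is self-produced

    frozen = _zeros_state(net_cfg, N, J, dtype)
    for t in range(1, T + 1):
        L = max(1, t - H + 1)
        ro = optimize_window(params, _window_views(a, L - 1, t),
                             {m: x[m][L - 1:t] for m in SENSORY_AREAS},
                             frozen, net_cfg, cfg, t_offset=L - 1, rng=rng)
        f_window[t - 1] = ro.total_free_energy()
        for area in DETERMINISTIC_AREAS:
            sg_p_online[area][t - 1] = ro.sg_p[area][-1]
        exec_mu[t - 1] = np.tanh(a["a_mu_C"])
        exec_sg[t - 1] = np.exp(np.clip(a["a_sg_C"],
                                        -net_cfg.sigma_preact_clip,
                                        net_cfg.sigma_preact_clip))

        if t < T:
            # prior at t+1 from the current deterministic state initializes
            # the posterior at t+1 (identity on the belief parameters)
            end = ro.end_state()
            clip = net_cfg.sigma_preact_clip
            for area in DETERMINISTIC_AREAS:
                pm = end[f"d_{area}"] @ params[f"w_pm_{area}"].swapaxes(-1, -2)
                ps = end[f"d_{area}"] @ params[f"w_ps_{area}"].swapaxes(-1, -2)
                a[f"a_mu_{area}"][t] = pm
                a[f"a_sg_{area}"][t] = np.clip(ps, -clip, clip)
            # one-step-ahead prediction from the prior-initialized posterior
            ro1 = rollout(params, _window_views(a, t, t + 1),
                          draw_noise(net_cfg, 1, N, J, None, dtype), None,
                          net_cfg, init_state=end, t_offset=t)
            for m in SENSORY_AREAS:
                xhat[m][t] = ro1.xhat[m][0]
            # active inference: proprioceptive prediction -> PID target
            # (commands saturate at the normalized joint range)
            target = np.clip(xhat["P"][t], -ANGLE_RANGE, ANGLE_RANGE)
            arm = pid_step(arm, target, cfg.gains)
            x["P"][t] = arm.proprio
            if t + 1 <= cfg.switch_step:
                x["E"][t] = arm.hand
            else:
                x["E"][t] = test_extero[None, :, t, :]
            # slide the frozen left edge once the window is full
            if t >= H:
                frozen = _advance_frozen(frozen, params, a, L, net_cfg)

    # final reconstruction pass over the whole trial with the final
    # (postdicted) adaptive variables
    ro = rollout(params, a, draw_noise(net_cfg, T, N, J, None, dtype), x, net_cfg)
    return TrialLog(
        x=x, xhat=xhat,
        mu_q=ro.mu_q, sg_q=ro.sg_q, mu_p=ro.mu_p, sg_p=ro.sg_p,
        f_t=ro.f_t, f_window=f_window, exec_mu_online=exec_mu,
        exec_sg_online=exec_sg, sg_p_online=sg_p_online, contexts=contexts,
    )


def _advance_frozen(frozen: Arrays, params: Arrays, a: Arrays, step: int,
                    net_cfg: NetworkConfig) -> Arrays:
    """Advance the stored left-edge deterministic state through global
    ``step`` using that step's (now final) adaptive variables."""
    N, S = frozen["h_A"].shape[:2]
    dtype = frozen["h_A"].dtype
    ro = rollout(params, _window_views(a, step - 1, step),
                 draw_noise(net_cfg, 1, N, S, None, dtype), None, net_cfg,
                 init_state=frozen, t_offset=step - 1)
    return ro.end_state()
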