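"""Hierarchical variational RNN: dynamics, beliefs, free energy, gradients.

The generative model has three deterministic areas (exteroceptive 'E',
proprioceptive 'P', association 'A') of multiple-timescale leaky-integrator
units, and four latent areas ('E', 'P', 'A', 'C'): diagonal-Gaussian beliefs
whose prior is computed from the same area's previous deterministic state
(tanh mean head, exp sigma head) and whose posterior is parameterized by
per-step adaptive variables ``a`` (the executive 'C' area has a single
sequence-constant posterior and a standard-normal prior at the first step
only).

Per step t (leaky-integrator update; d = tanh(h), h_0 = d_0 = 0):

    h_A,t = (1/tau)(W d_A,t-1 + W z_A,t + W z_C,t + b) + (1 - 1/tau) h_A,t-1
    h_S,t = (1/tau)(W d_S,t-1 + W z_S,t + W d_A,t  + b) + (1 - 1/tau) h_S,t-1

for S in {E, P}; the top-down drive uses the association state of the
*current* step, so within a step the association area is evaluated first.
Predictions are per-modality tanh readouts of that modality's deterministic
units. The free energy per step is

    F_t = err_E/2 + err_P/3 + sum_l W^(l) * KL_l / dim_l

with err_m = 1/2 |x_m - xhat_m|^2, the KL divergence taken between posterior
and prior per latent area (executive only at t = 1), each term normalized by
its dimension, and W^(l) the per-level meta-priors.

Everything is batched over a leading network axis N and a sequence axis S:
states are (N, S, dim) and weights (N, out, in). Gradients of the summed
free energy with respect to all synaptic weights, biases and adaptive
variables are computed by an explicit reverse pass (backpropagation through
time); the test suite checks them against central finite differences. In
posterior mode neither the latent samples nor the deterministic trajectory
depend on the priors, so beliefs, samples, predictions, prediction errors
and KL terms are evaluated vectorized over time and only the leaky
recurrence itself runs step by step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .config import NetworkConfig, DETERMINISTIC_AREAS, SENSORY_AREAS

Arrays = Dict[str, np.ndarray]

#: parameter names whose gradients are never applied (frozen biases)
FROZEN = ("b_E", "b_P", "b_A")


# ---------------------------------------------------------------------------
# Elementary operations (the rollout applies the same formulas on batched
# time-major arrays).

def compute_prior(d_prev: np.ndarray, w_mu: np.ndarray, w_sigma: np.ndarray,
                  clip: float = 10.0):
    """Prior belief from the previous deterministic state of the same area:
    mu = tanh(w_mu d), sigma = exp(w_sigma d)."""
    mu = np.tanh(np.einsum("...ij,...j->...i", w_mu, d_prev))
    sg = np.exp(np.clip(np.einsum("...ij,...j->...i", w_sigma, d_prev),
                        -clip, clip))
    return mu, sg


def compute_posterior(a_mu: np.ndarray, a_sigma: np.ndarray, clip: float = 10.0):
    """Posterior belief from adaptive variables: mu = tanh(a_mu),
    sigma = exp(a_sigma)."""
    if not (np.all(np.isfinite(a_mu)) and np.all(np.isfinite(a_sigma))):
        raise FloatingPointError("non-finite adaptive variables")
    return np.tanh(a_mu), np.exp(np.clip(a_sigma, -clip, clip))


def sample_latent(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray):
    """Reparameterized draw z = mu + sigma * eps (single sample)."""
    return mu + sigma * eps


def step_deterministic(h_prev: np.ndarray, drive: np.ndarray,
                       tau: np.ndarray):
    """Leaky-integrator update h_t = drive/tau + (1 - 1/tau) h_prev."""
    inv = 1.0 / tau
    h = inv * drive + (1.0 - inv) * h_prev
    return h, np.tanh(h)


def emit_prediction(d: np.ndarray, w_out: np.ndarray):
    """Per-modality sensory prediction xhat = tanh(W d)."""
    return np.tanh(np.einsum("...ij,...j->...i", w_out, d))


def accuracy_term(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """Dimension-normalized squared prediction error 1/2 |x - xhat|^2 / dim."""
    d = x.shape[-1]
    return 0.5 * np.sum((x - xhat) ** 2, axis=-1) / d


def gaussian_kl(mu_q, sg_q, mu_p, sg_p) -> np.ndarray:
    """Closed-form KL(q || p) between diagonal Gaussians, summed over the
    last axis and divided by its dimension."""
    sg_p = np.asarray(sg_p)
    if np.any(sg_p <= 0):
        raise ValueError("prior sigma must be strictly positive")
    d = np.shape(mu_q)[-1]
    term = (np.log(sg_p / sg_q)
            + ((mu_p - mu_q) ** 2 + sg_q ** 2) / (2.0 * sg_p ** 2) - 0.5)
    return np.sum(term, axis=-1) / d


def executive_prior(t: int):
    """Executive-area prior: standard normal at the first step, absent later."""
    return (0.0, 1.0) if t == 1 else None


# ---------------------------------------------------------------------------
# Rollout

@dataclass
class Rollout:
    """Cache of one posterior (or prior) rollout over a window of T steps.

    Time-major arrays: ``h[a]``/``d[a]`` are (T+1, N, S, det) with index 0
    holding the initial state; latent caches are (T, N, S, z); predictions
    ``xhat[m]`` are (T, N, S, out). Free-energy pieces are (T, N, S).
    """

    h: Arrays
    d: Arrays
    mu_p: Arrays
    sg_p: Arrays
    ps_pre: Arrays
    mu_q: Arrays
    sg_q: Arrays
    z: Arrays
    eps: Arrays
    xhat: Arrays
    acc: Arrays           # per modality (T, N, S)
    kl: Arrays            # per latent area, dimension-normalized (T, N, S)
    f_t: np.ndarray       # weighted total per step (T, N, S)
    t_offset: int         # global index of the step before the window
    qs_mask: Arrays       # where the a_sigma exp-clamp is inactive

    @property
    def T(self) -> int:
        return self.f_t.shape[0]

    def total_free_energy(self) -> np.ndarray:
        """Window free energy per (network, sequence): sum_t F_t."""
        return self.f_t.sum(axis=0)

    def end_state(self) -> Arrays:
        return {f"{nm}_{a}": getattr(self, nm)[a][self.T]
                for nm in ("h", "d") for a in DETERMINISTIC_AREAS}


def _zeros_state(cfg: NetworkConfig, N: int, S: int, dtype=float) -> Arrays:
    state = {}
    for a in DETERMINISTIC_AREAS:
        state[f"h_{a}"] = np.zeros((N, S, cfg.det_dims[a]), dtype=dtype)
        state[f"d_{a}"] = np.zeros((N, S, cfg.det_dims[a]), dtype=dtype)
    return state


def _wt(params: Arrays, name: str) -> np.ndarray:
    """Weight transposed for right-multiplication: (N, in, out)."""
    return np.ascontiguousarray(params[name].swapaxes(-1, -2))


def rollout(params: Arrays, adaptive: Arrays, eps: Arrays, x: Optional[Arrays],
            cfg: NetworkConfig, *, mode: str = "posterior",
            init_state: Optional[Arrays] = None, t_offset: int = 0) -> Rollout:
    """Unfold the network over a window of T steps and score free energy.

    Parameters
    ----------
    params:
        Weight dict, each array with leading network axis N.
    adaptive:
        ``a_mu_<area>``/``a_sg_<area>`` arrays (T, N, S, z) for areas E, P, A
        and (N, S, z) for the sequence-constant executive C.
    eps:
        Standard-normal draws matching the posterior shapes per step:
        (T, N, S, z) per area including C. Pass zeros for mean propagation.
    x:
        Observed sensations ``{"E": (T, N, S, 2), "P": (T, N, S, 3)}``
        (network axis may be 1, broadcast). None skips the accuracy terms.
    mode:
        "posterior" samples z from the adaptive posterior; "prior" replays
        the generative model from its own priors (generative replay; the
        executive z is held at its first-step draw, since the executive has
        a prior only at step 1).
    init_state, t_offset:
        Deterministic state at the window's left edge and the global index
        of that edge (0 for a full-sequence rollout). The executive
        complexity term applies only when the window contains global step 1.
    """
    if mode == "prior":
        return _rollout_prior(params, eps, x, cfg, init_state, t_offset)
    if mode != "posterior":
        raise ValueError(mode)
    T, N, S = eps["A"].shape[:3]
    dt = params["w_dd_A"].dtype
    clip = cfg.sigma_preact_clip
    zd = cfg.latent_dims

    # --- beliefs, samples and clamp masks, vectorized over time
    mu_q, sg_q, z, qs_mask = {}, {}, {}, {}
    for a in DETERMINISTIC_AREAS:
        mu_q[a] = np.tanh(adaptive[f"a_mu_{a}"])
        sg_q[a] = np.exp(np.clip(adaptive[f"a_sg_{a}"], -clip, clip))
        qs_mask[a] = np.abs(adaptive[f"a_sg_{a}"]) < clip
        z[a] = mu_q[a] + sg_q[a] * eps[a]
    # executive: one belief, broadcast over the window
    muC = np.tanh(adaptive["a_mu_C"])
    sgC = np.exp(np.clip(adaptive["a_sg_C"], -clip, clip))
    qs_mask["C"] = np.abs(adaptive["a_sg_C"]) < clip
    mu_q["C"] = np.broadcast_to(muC, (T, N, S, zd["C"]))
    sg_q["C"] = np.broadcast_to(sgC, (T, N, S, zd["C"]))
    z["C"] = muC + sgC * eps["C"]

    if not all(np.isfinite(z[a]).all() for a in z):
        raise FloatingPointError("non-finite latent state in rollout")

    # --- latent-driven input currents, vectorized over time
    zdrive = {
        "A": z["A"] @ _wt(params, "w_dz_A") + params["b_A"][:, None],
        "E": z["E"] @ _wt(params, "w_dz_E") + params["b_E"][:, None],
        "P": z["P"] @ _wt(params, "w_dz_P") + params["b_P"][:, None],
    }
    if zd["C"] > 0:
        zdrive["A"] = zdrive["A"] + z["C"] @ _wt(params, "w_dc_A")
    wdd = {a: _wt(params, f"w_dd_{a}") for a in DETERMINISTIC_AREAS}
    wtd = {m: _wt(params, f"w_td_{m}") for m in SENSORY_AREAS}

    h = {a: np.empty((T + 1, N, S, cfg.det_dims[a]), dtype=dt)
         for a in DETERMINISTIC_AREAS}
    d = {a: np.empty_like(h[a]) for a in DETERMINISTIC_AREAS}
    state = init_state if init_state is not None else _zeros_state(cfg, N, S, dt)
    for a in DETERMINISTIC_AREAS:
        h[a][0] = state[f"h_{a}"]
        d[a][0] = state[f"d_{a}"]

    inv_tau = {a: (1.0 / cfg.tau(a)).astype(dt) for a in DETERMINISTIC_AREAS}
    one_minus = {a: 1.0 - inv_tau[a] for a in DETERMINISTIC_AREAS}

    # --- the leaky recurrence (the only sequential part)
    for t in range(T):
        hA = (inv_tau["A"] * (d["A"][t] @ wdd["A"] + zdrive["A"][t])
              + one_minus["A"] * h["A"][t])
        h["A"][t + 1] = hA
        dA = np.tanh(hA)
        d["A"][t + 1] = dA
        for m in SENSORY_AREAS:
            hm = (inv_tau[m] * (d[m][t] @ wdd[m] + dA @ wtd[m] + zdrive[m][t])
                  + one_minus[m] * h[m][t])
            h[m][t + 1] = hm
            d[m][t + 1] = np.tanh(hm)

    # --- priors, predictions and free energy, vectorized over time
    mu_p, sg_p, ps_pre, kl = {}, {}, {}, {}
    for a in DETERMINISTIC_AREAS:
        pm = d[a][:T] @ _wt(params, f"w_pm_{a}")
        ps = d[a][:T] @ _wt(params, f"w_ps_{a}")
        mu_p[a] = np.tanh(pm)
        sg_p[a] = np.exp(np.clip(ps, -clip, clip))
        ps_pre[a] = ps
        kl[a] = gaussian_kl(mu_q[a], sg_q[a], mu_p[a], sg_p[a]) \
            if zd[a] > 0 else np.zeros((T, N, S), dtype=dt)
    kl["C"] = np.zeros((T, N, S), dtype=dt)
    if zd["C"] > 0 and t_offset == 0:
        kl["C"][0] = gaussian_kl(muC, sgC, np.zeros(1, dtype=dt),
                                 np.ones(1, dtype=dt))
    xhat, acc = {}, {}
    for m in SENSORY_AREAS:
        xhat[m] = np.tanh(d[m][1:] @ _wt(params, f"w_out_{m}"))
        acc[m] = (accuracy_term(x[m], xhat[m]) if x is not None
                  else np.zeros((T, N, S), dtype=dt))

    W1, W2, W3 = cfg.meta_priors
    f_t = (acc["E"] + acc["P"] + W1 * (kl["E"] + kl["P"])
           + W2 * kl["A"] + W3 * kl["C"])
    return Rollout(h=h, d=d, mu_p=mu_p, sg_p=sg_p, ps_pre=ps_pre, mu_q=mu_q,
                   sg_q=sg_q, z=z, eps=eps, xhat=xhat, acc=acc, kl=kl,
                   f_t=f_t, t_offset=t_offset, qs_mask=qs_mask)


def _rollout_prior(params: Arrays, eps: Arrays, x: Optional[Arrays],
                   cfg: NetworkConfig, init_state, t_offset: int) -> Rollout:
    """Generative replay: z sampled from the priors step by step."""
    T, N, S = eps["A"].shape[:3]
    dt = params["w_dd_A"].dtype
    clip = cfg.sigma_preact_clip
    zd = cfg.latent_dims
    h = {a: np.empty((T + 1, N, S, cfg.det_dims[a]), dtype=dt)
         for a in DETERMINISTIC_AREAS}
    d = {a: np.empty_like(h[a]) for a in DETERMINISTIC_AREAS}
    state = init_state if init_state is not None else _zeros_state(cfg, N, S, dt)
    for a in DETERMINISTIC_AREAS:
        h[a][0] = state[f"h_{a}"]
        d[a][0] = state[f"d_{a}"]
    shp = lambda a: (T, N, S, zd[a])
    mu_p = {a: np.empty(shp(a), dtype=dt) for a in DETERMINISTIC_AREAS}
    sg_p = {a: np.empty(shp(a), dtype=dt) for a in DETERMINISTIC_AREAS}
    ps_pre = {a: np.empty(shp(a), dtype=dt) for a in DETERMINISTIC_AREAS}
    z = {a: np.empty(shp(a), dtype=dt) for a in ("E", "P", "A", "C")}
    inv_tau = {a: (1.0 / cfg.tau(a)).astype(dt) for a in DETERMINISTIC_AREAS}
    for t in range(T):
        for a in DETERMINISTIC_AREAS:
            mu_p[a][t], sg_p[a][t] = compute_prior(
                d[a][t], params[f"w_pm_{a}"], params[f"w_ps_{a}"], clip)
            ps_pre[a][t] = 0.0
            z[a][t] = mu_p[a][t] + sg_p[a][t] * eps[a][t]
        # executive: N(0,1) prior at global step 1 only, then held constant
        z["C"][t] = eps["C"][0] if (t == 0 and t_offset == 0) else z["C"][t - 1] \
            if t > 0 else np.zeros((N, S, zd["C"]), dtype=dt)
        drive_A = (d["A"][t] @ _wt(params, "w_dd_A")
                   + z["A"][t] @ _wt(params, "w_dz_A") + params["b_A"][:, None])
        if zd["C"] > 0:
            drive_A = drive_A + z["C"][t] @ _wt(params, "w_dc_A")
        h["A"][t + 1], d["A"][t + 1] = step_deterministic(
            h["A"][t], drive_A, cfg.tau("A"))
        for m in SENSORY_AREAS:
            drive = (d[m][t] @ _wt(params, f"w_dd_{m}")
                     + z[m][t] @ _wt(params, f"w_dz_{m}")
                     + d["A"][t + 1] @ _wt(params, f"w_td_{m}")
                     + params[f"b_{m}"][:, None])
            h[m][t + 1], d[m][t + 1] = step_deterministic(
                h[m][t], drive, cfg.tau(m))
    xhat = {m: np.tanh(d[m][1:] @ _wt(params, f"w_out_{m}"))
            for m in SENSORY_AREAS}
    acc = {m: (accuracy_term(x[m], xhat[m]) if x is not None
               else np.zeros((T, N, S), dtype=dt)) for m in SENSORY_AREAS}
    zero = np.zeros((T, N, S), dtype=dt)
    return Rollout(h=h, d=d, mu_p=mu_p, sg_p=sg_p, ps_pre=ps_pre,
                   mu_q=mu_p, sg_q=sg_p, z=z, eps=eps, xhat=xhat, acc=acc,
                   kl={a: zero for a in ("E", "P", "A", "C")},
                   f_t=acc["E"] + acc["P"], t_offset=t_offset,
                   qs_mask={})


# ---------------------------------------------------------------------------
# Backward pass

def backward(ro: Rollout, params: Arrays, x: Arrays, cfg: NetworkConfig,
             *, weight_grads: bool = True):
    """Gradients of the summed window free energy sum_{t,n,s} F_t.

    Returns ``(grad_params, grad_adaptive)``; the adaptive gradients follow
    the layout of the ``adaptive`` dict passed to :func:`rollout`. With
    ``weight_grads=False`` only adaptive gradients are computed (test-phase
    inference, where synaptic weights are frozen).
    """
    T = ro.T
    N, S = ro.f_t.shape[1], ro.f_t.shape[2]
    dt = ro.f_t.dtype
    W_meta = {"E": cfg.meta_priors[0], "P": cfg.meta_priors[0],
              "A": cfg.meta_priors[1], "C": cfg.meta_priors[2]}
    zd = cfg.latent_dims
    inv_tau = {a: (1.0 / cfg.tau(a)).astype(dt) for a in DETERMINISTIC_AREAS}

    # --- vectorized pieces: output error and KL derivatives
    gd_out = {}
    go = {}
    for m in SENSORY_AREAS:
        e = (ro.xhat[m] - x[m]) / x[m].shape[-1]
        g = (e * (1.0 - ro.xhat[m] ** 2))
        if g.shape[1] != N:  # x broadcast over networks
            g = np.broadcast_to(g, (T, N, S, g.shape[-1]))
        go[m] = g
        gd_out[m] = g @ params[f"w_out_{m}"]
    gmu_q_kl, gsg_q_kl, gpm_pre, gps_pre, gd_prior = {}, {}, {}, {}, {}
    for a in DETERMINISTIC_AREAS:
        c = W_meta[a] / zd[a] if zd[a] > 0 else 0.0
        diff = ro.mu_q[a] - ro.mu_p[a]
        inv_sp2 = 1.0 / ro.sg_p[a] ** 2
        gmu_q_kl[a] = c * diff * inv_sp2
        gsg_q_kl[a] = c * (ro.sg_q[a] * inv_sp2 - 1.0 / ro.sg_q[a])
        gmu_p = -c * diff * inv_sp2
        gsg_p = c * (1.0 / ro.sg_p[a]
                     - (diff ** 2 + ro.sg_q[a] ** 2) * inv_sp2 / ro.sg_p[a])
        gpm_pre[a] = gmu_p * (1.0 - ro.mu_p[a] ** 2)
        gps_pre[a] = gsg_p * ro.sg_p[a] * (np.abs(ro.ps_pre[a])
                                           < cfg.sigma_preact_clip)
        gd_prior[a] = (gpm_pre[a] @ params[f"w_pm_{a}"]
                       + gps_pre[a] @ params[f"w_ps_{a}"])

    # --- reverse recurrence: accumulate gradient into each pre-activation
    pre = {a: np.empty((T, N, S, cfg.det_dims[a]), dtype=dt)
           for a in DETERMINISTIC_AREAS}
    gh_next = {a: np.zeros((N, S, cfg.det_dims[a]), dtype=dt)
               for a in DETERMINISTIC_AREAS}
    gd_next = {a: np.zeros_like(gh_next[a]) for a in DETERMINISTIC_AREAS}
    wdd = {a: params[f"w_dd_{a}"] for a in DETERMINISTIC_AREAS}
    wtd = {m: params[f"w_td_{m}"] for m in SENSORY_AREAS}
    for t in range(T - 1, -1, -1):
        gd_A = gd_next["A"]
        for m in SENSORY_AREAS:
            gd = gd_out[m][t] + gd_next[m]
            gh = gd * (1.0 - ro.d[m][t + 1] ** 2) + gh_next[m]
            p = gh * inv_tau[m]
            pre[m][t] = p
            gd_A = gd_A + p @ wtd[m]
            gd_next[m] = p @ wdd[m] + gd_prior[m][t]
            gh_next[m] = gh * (1.0 - inv_tau[m])
        gh = gd_A * (1.0 - ro.d["A"][t + 1] ** 2) + gh_next["A"]
        p = gh * inv_tau["A"]
        pre["A"][t] = p
        gd_next["A"] = p @ wdd["A"] + gd_prior["A"][t]
        gh_next["A"] = gh * (1.0 - inv_tau["A"])

    # --- adaptive-variable gradients, vectorized over time
    ga: Arrays = {}
    gz = {a: pre[a] @ params[f"w_dz_{a}"] for a in DETERMINISTIC_AREAS}
    for a in DETERMINISTIC_AREAS:
        gmu_q = gz[a] + gmu_q_kl[a]
        gsg_q = gz[a] * ro.eps[a] + gsg_q_kl[a]
        ga[f"a_mu_{a}"] = gmu_q * (1.0 - ro.mu_q[a] ** 2)
        ga[f"a_sg_{a}"] = gsg_q * ro.sg_q[a] * ro.qs_mask[a]
    if zd["C"] > 0:
        gzC = pre["A"] @ params["w_dc_A"]
        muC, sgC = ro.mu_q["C"][0], ro.sg_q["C"][0]
        gmuC = gzC.sum(axis=0)
        gsgC = (gzC * ro.eps["C"]).sum(axis=0)
        if ro.t_offset == 0:
            cC = W_meta["C"] / zd["C"]
            gmuC = gmuC + cC * muC
            gsgC = gsgC + cC * (sgC - 1.0 / sgC)
        ga["a_mu_C"] = gmuC * (1.0 - muC ** 2)
        ga["a_sg_C"] = gsgC * sgC * ro.qs_mask["C"]
    else:
        ga["a_mu_C"] = np.zeros((N, S, 0), dtype=dt)
        ga["a_sg_C"] = np.zeros((N, S, 0), dtype=dt)

    if not weight_grads:
        return {}, ga

    # --- synaptic-weight gradients: time-summed outer products
    def contract(left: np.ndarray, right: np.ndarray) -> np.ndarray:
        out = left[0].swapaxes(-1, -2) @ right[0]
        for t in range(1, left.shape[0]):
            out += left[t].swapaxes(-1, -2) @ right[t]
        return out

    gp: Arrays = {}
    for a in DETERMINISTIC_AREAS:
        gp[f"w_dd_{a}"] = contract(pre[a], ro.d[a][:T])
        gp[f"w_dz_{a}"] = contract(pre[a], ro.z[a])
        gp[f"w_pm_{a}"] = contract(gpm_pre[a], ro.d[a][:T])
        gp[f"w_ps_{a}"] = contract(gps_pre[a], ro.d[a][:T])
        gp[f"b_{a}"] = pre[a].sum(axis=(0, 2))
    for m in SENSORY_AREAS:
        gp[f"w_td_{m}"] = contract(pre[m], ro.d["A"][1:])
        gp[f"w_out_{m}"] = contract(go[m], ro.d[m][1:])
    gp["w_dc_A"] = (contract(pre["A"], ro.z["C"]) if zd["C"] > 0
                    else np.zeros_like(params["w_dc_A"]))
    return gp, ga


# ---------------------------------------------------------------------------
# Free-energy breakdown

@dataclass
class FreeEnergyBreakdown:
    """Per-step decomposition of the free energy of one rollout."""

    accuracy_extero: np.ndarray   # (T, N, S)
    accuracy_proprio: np.ndarray
    complexity: Dict[int, np.ndarray]  # level (1..3) -> (T, N, S)
    weighted_total: np.ndarray    # F_t, (T, N, S)

    def sequence_sum(self) -> np.ndarray:
        return self.weighted_total.sum(axis=0)


def free_energy(ro: Rollout, cfg: NetworkConfig) -> FreeEnergyBreakdown:
    """Assemble the accuracy/complexity decomposition from a posterior
    rollout (complexity per level is already dimension-normalized)."""
    return FreeEnergyBreakdown(
        accuracy_extero=ro.acc["E"],
        accuracy_proprio=ro.acc["P"],
        complexity={1: ro.kl["E"] + ro.kl["P"], 2: ro.kl["A"], 3: ro.kl["C"]},
        weighted_total=ro.f_t,
    )


def rollout_to_frame(ro: Rollout, network: int = 0, sequence: int = 0):
    """Long-format (step, area, quantity, value) trace of one rollout's
    beliefs, predictions and free-energy terms, for CSV export."""
    import pandas as pd

    rows = []
    T = ro.T

    def add(area, quantity, arr):
        for t in range(T):
            vals = np.atleast_1d(arr[t])
            for i, v in enumerate(vals):
                rows.append({"step": t + 1, "area": area,
                             "quantity": f"{quantity}_{i}" if vals.size > 1
                             else quantity, "value": float(v)})

    for a in DETERMINISTIC_AREAS:
        add(a, "mu_p", ro.mu_p[a][:, network, sequence])
        add(a, "sigma_p", ro.sg_p[a][:, network, sequence])
        add(a, "mu_q", ro.mu_q[a][:, network, sequence])
        add(a, "sigma_q", ro.sg_q[a][:, network, sequence])
        add(a, "kl", ro.kl[a][:, network, sequence])
    add("C", "kl", ro.kl["C"][:, network, sequence])
    for m in SENSORY_AREAS:
        add(m, "xhat", ro.xhat[m][:, network, sequence])
        add(m, "accuracy", ro.acc[m][:, network, sequence])
    add("total", "free_energy", ro.f_t[:, network, sequence])
    return pd.DataFrame(rows)
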