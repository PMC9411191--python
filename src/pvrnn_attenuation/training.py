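"""Learning phase: joint optimization of synaptic weights and per-sequence
adaptive posterior variables by minimizing the summed free energy over all
training sequences, with developmental metric tracking.

Training is full-batch: every epoch performs one posterior rollout of all
sequences (fresh single-sample noise draws), one backpropagation-through-time
pass, and one Adam update of all weights and adaptive variables; the
deterministic-unit biases are frozen at their initial values. Multiple
networks (different weight initializations) are trained simultaneously along
a leading batch axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (NetworkConfig, TrainingConfig, DETERMINISTIC_AREAS,
                     SENSORY_AREAS)
from .core import Arrays, FROZEN, backward, rollout
from .datagen import ContextDataset, SELF_PRODUCED, EXTERNALLY_PRODUCED
from .optim import Adam
from .perf import tune_malloc

#: (name, input-area-dims) table of all weight pathways
_PATHWAYS = (
    ("w_dd_E", "det:E", "det:E"), ("w_dd_P", "det:P", "det:P"),
    ("w_dd_A", "det:A", "det:A"),
    ("w_dz_E", "det:E", "lat:E"), ("w_dz_P", "det:P", "lat:P"),
    ("w_dz_A", "det:A", "lat:A"), ("w_dc_A", "det:A", "lat:C"),
    ("w_td_E", "det:E", "det:A"), ("w_td_P", "det:P", "det:A"),
    ("w_pm_E", "lat:E", "det:E"), ("w_ps_E", "lat:E", "det:E"),
    ("w_pm_P", "lat:P", "det:P"), ("w_ps_P", "lat:P", "det:P"),
    ("w_pm_A", "lat:A", "det:A"), ("w_ps_A", "lat:A", "det:A"),
    ("w_out_E", "out:E", "det:E"), ("w_out_P", "out:P", "det:P"),
)


def _dim(cfg: NetworkConfig, spec: str) -> int:
    kind, area = spec.split(":")
    if kind == "det":
        return cfg.det_dims[area]
    if kind == "lat":
        return cfg.latent_dims[area]
    return cfg.out_dim(area)


@dataclass
class TrainingData:
    """Stacked training targets for both contexts.

    ``x`` holds time-major observation arrays (T, 1, S, dim) per modality
    (the singleton axis broadcasts over networks); ``contexts`` labels each
    of the S sequences.
    """

    x: Arrays
    contexts: np.ndarray

    @property
    def T(self) -> int:
        return self.x["P"].shape[0]

    @property
    def n_sequences(self) -> int:
        return self.x["P"].shape[2]

    def context_mask(self, context: str) -> np.ndarray:
        return self.contexts == context


def make_training_data(self_ds: ContextDataset, ext_ds: ContextDataset,
                       dtype=np.float64) -> TrainingData:
    seqs = list(self_ds.sequences) + list(ext_ds.sequences)
    proprio = np.stack([s.proprio for s in seqs])   # (S, T, 3)
    extero = np.stack([s.extero for s in seqs])     # (S, T, 2)
    x = {"P": proprio.transpose(1, 0, 2)[:, None].astype(dtype),
         "E": extero.transpose(1, 0, 2)[:, None].astype(dtype)}
    contexts = np.array([s.context for s in seqs])
    return TrainingData(x=x, contexts=contexts)


def init_parameters(cfg: NetworkConfig, n_networks: int, seed: int,
                    bias_variance: float = 10.0, dtype=np.float64) -> Arrays:
    """Seeded initialization: weights uniform on +-1/sqrt(fan_in) per
    pathway; deterministic-unit biases N(0, bias_variance), frozen."""
    rng = np.random.default_rng([seed, 13])
    params: Arrays = {}
    for name, out_spec, in_spec in _PATHWAYS:
        out_d, in_d = _dim(cfg, out_spec), _dim(cfg, in_spec)
        bound = 1.0 / np.sqrt(in_d) if in_d > 0 else 0.0
        params[name] = rng.uniform(
            -bound, bound, size=(n_networks, out_d, in_d)).astype(dtype)
    for a in DETERMINISTIC_AREAS:
        params[f"b_{a}"] = rng.normal(
            0.0, np.sqrt(bias_variance),
            size=(n_networks, cfg.det_dims[a])).astype(dtype)
    return params


def init_adaptive(cfg: NetworkConfig, n_networks: int, n_sequences: int,
                  T: int, dtype=np.float64) -> Arrays:
    """Adaptive variables at their pre-learning prior pre-activations.

    With zero deterministic history the prior heads output zero, so every
    initial posterior is N(0, 1); the executive area gets a single
    (sequence-constant) pair of variables per sequence.
    """
    a: Arrays = {}
    for area in DETERMINISTIC_AREAS:
        z = cfg.latent_dims[area]
        a[f"a_mu_{area}"] = np.zeros((T, n_networks, n_sequences, z), dtype=dtype)
        a[f"a_sg_{area}"] = np.zeros((T, n_networks, n_sequences, z), dtype=dtype)
    zc = cfg.latent_dims["C"]
    a["a_mu_C"] = np.zeros((n_networks, n_sequences, zc), dtype=dtype)
    a["a_sg_C"] = np.zeros((n_networks, n_sequences, zc), dtype=dtype)
    return a


def draw_noise(cfg: NetworkConfig, T: int, n_networks: int, n_sequences: int,
               rng: Optional[np.random.Generator], dtype=np.float64) -> Arrays:
    """One standard-normal draw per latent unit per step (or zeros)."""
    dims = [cfg.latent_dims[a] for a in ("E", "P", "A", "C")]
    if rng is None:
        block = np.zeros((T, n_networks, n_sequences, sum(dims)), dtype=dtype)
    else:
        block = rng.standard_normal(
            (T, n_networks, n_sequences, sum(dims)), dtype=dtype)
    eps, lo = {}, 0
    for area, z in zip(("E", "P", "A", "C"), dims):
        eps[area] = block[..., lo:lo + z]
        lo += z
    return eps


def _metric_rows(epoch: int, ro, adaptive: Arrays, data: TrainingData,
                 rows: List[dict]) -> None:
    mu_E = np.tanh(adaptive["a_mu_E"])
    mu_P = np.tanh(adaptive["a_mu_P"])
    resp = np.concatenate([np.abs(np.diff(mu_E, axis=0)),
                           np.abs(np.diff(mu_P, axis=0))], axis=-1)
    sig = np.concatenate([ro.sg_p["E"], ro.sg_p["P"]], axis=-1)
    fe_seq = ro.f_t.sum(axis=0)  # (N, S)
    for context in (SELF_PRODUCED, EXTERNALLY_PRODUCED):
        m = data.context_mask(context)
        if not m.any():
            continue
        r = resp[:, :, m].mean(axis=(0, 2, 3))
        s = sig[:, :, m].mean(axis=(0, 2, 3))
        f = fe_seq[:, m].mean(axis=1)
        for n in range(r.shape[0]):
            rows.append({"epoch": epoch, "network": n, "context": context,
                         "posterior_response": r[n], "prior_sigma": s[n],
                         "free_energy": f[n]})


def train(data: TrainingData, params: Arrays, adaptive: Arrays,
          t_cfg: TrainingConfig, net_cfg: NetworkConfig,
          callback=None) -> pd.DataFrame:
    """Run the learning phase in place; returns the learning curves.

    ``callback(epoch, ro)`` is invoked at logging points with the epoch's
    rollout, for custom tracking.
    """
    T, S = data.T, data.n_sequences
    N = params["w_dd_A"].shape[0]
    dtype = params["w_dd_A"].dtype
    tune_malloc()
    rng = np.random.default_rng([t_cfg.seed, 17])
    opt = Adam(lr=t_cfg.learning_rate, beta1=t_cfg.beta1, beta2=t_cfg.beta2,
               eps=t_cfg.adam_eps, frozen=FROZEN)
    merged = {**params, **adaptive}
    rows: List[dict] = []
    for epoch in range(t_cfg.epochs):
        eps = draw_noise(net_cfg, T, N, S, rng, dtype)
        ro = rollout(params, adaptive, eps, data.x, net_cfg)
        if not np.isfinite(ro.f_t).all():
            raise FloatingPointError(
                "non-finite free energy at epoch %d; per-term maxima: %s"
                % (epoch, {k: float(np.nanmax(v)) for k, v in
                           {**ro.acc, **{f"kl_{a}": ro.kl[a] for a in ro.kl}}.items()}))
        gp, ga = backward(ro, params, data.x, net_cfg)
        opt.step(merged, {**gp, **ga})
        if epoch % t_cfg.metric_logging_interval == 0 or epoch == t_cfg.epochs - 1:
            _metric_rows(epoch, ro, adaptive, data, rows)
            if callback is not None:
                callback(epoch, ro)
    return pd.DataFrame(rows)


def learning_metrics(params: Arrays, adaptive: Arrays, data: TrainingData,
                     net_cfg: NetworkConfig) -> pd.DataFrame:
    """Per-context developmental metrics of the current training state.

    Uses a deterministic (mean-propagation) rollout. Returns one row per
    (network, context) with the sensory-level posterior response
    mean |mu_q(t) - mu_q(t-1)|, the mean sensory-level prior sigma, and the
    mean sequence free energy.
    """
    T, S = data.T, data.n_sequences
    N = params["w_dd_A"].shape[0]
    eps = draw_noise(net_cfg, T, N, S, rng=None)
    ro = rollout(params, adaptive, eps, data.x, net_cfg)
    rows: List[dict] = []
    _metric_rows(-1, ro, adaptive, data, rows)
    return pd.DataFrame(rows).drop(columns=["epoch"])
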