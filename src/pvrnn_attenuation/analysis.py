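"""Metrics, statistics and experiment drivers.

Quantifies sensory attenuation as the contrast, between the self-produced and
externally produced contexts, of (i) the sensory-level posterior response
(mean per-step change of the sensory latent posterior means) and (ii) the
mean sensory-level prior sigma, aggregated per trained network and compared
with two-tailed paired t-tests across networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig, NetworkConfig, TrainingConfig, TrialConfig
from .datagen import (SELF_PRODUCED, EXTERNALLY_PRODUCED, build_dataset)
from .inference import TrialLog, run_trial
from .training import (init_adaptive, init_parameters, make_training_data,
                       train)


# ---------------------------------------------------------------------------
# Trial metrics

def _step_slice(steps: range) -> slice:
    """1-based inclusive step range -> 0-based array slice."""
    if len(steps) == 0:
        raise ValueError("empty step range")
    return slice(steps.start - 1, steps.stop - 1)


def posterior_response(trial: TrialLog, steps: range) -> np.ndarray:
    """Mean |mu_q(t) - mu_q(t-1)| of the sensory latents over a 1-based step
    range (differences taken within the range), per (network, trial)."""
    sl = _step_slice(steps)
    mu = np.concatenate([trial.mu_q["E"][sl], trial.mu_q["P"][sl]], axis=-1)
    if mu.shape[0] < 2:
        raise ValueError("need at least two steps for a response")
    return np.abs(np.diff(mu, axis=0)).mean(axis=(0, -1))


def mean_prior_sigma(trial: TrialLog, steps: range) -> np.ndarray:
    """Mean sensory-level prior sigma over a 1-based step range."""
    sl = _step_slice(steps)
    sg = np.concatenate([trial.sg_p["E"][sl], trial.sg_p["P"][sl]], axis=-1)
    return sg.mean(axis=(0, -1))


def moving_average(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Trailing moving average; within the first ``window - 1`` entries the
    average runs from the first element to the current one."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = np.asarray(series, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(s, axis=0)])
    n = np.arange(1, len(s) + 1)
    lo = np.maximum(n - window, 0)
    return (c[n] - c[lo]) / (n - lo)


# ---------------------------------------------------------------------------
# Statistics

@dataclass(frozen=True)
class TestResult:
    """Two-tailed paired t-test summary."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_difference: float
    degenerate: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical paired t-test on x - y (two-tailed, df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(np.nan, n - 1, np.nan, float(d.mean()), degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), n - 1, float(p), float(d.mean()))


def context_comparison(metrics: pd.DataFrame) -> Dict[str, TestResult]:
    """Paired self-vs-external tests with the network as the pairing unit.

    ``metrics`` has one row per (network, trial, context) with columns
    ``posterior_response`` and ``prior_sigma``; trials are averaged within
    each (network, context) cell before testing.
    """
    cell = metrics.groupby(["network", "context"], as_index=False)[
        ["posterior_response", "prior_sigma"]].mean()
    wide = cell.pivot(index="network", columns="context")
    counts = metrics.groupby(["network", "context"]).size()
    if counts.nunique() != 1 or wide.isna().any().any():
        raise ValueError("unbalanced design: every network needs the same "
                         "number of trials in both contexts")
    out = {}
    for metric in ("posterior_response", "prior_sigma"):
        out[metric] = paired_t_test(wide[(metric, SELF_PRODUCED)],
                                    wide[(metric, EXTERNALLY_PRODUCED)])
    return out


# ---------------------------------------------------------------------------
# Experiment driver

@dataclass(frozen=True)
class ExperimentConfig:
    """One full design: data -> training (N networks) -> test trials ->
    context statistics. Lesions and meta-prior manipulations are expressed
    through ``network`` overrides."""

    generator: GeneratorConfig = GeneratorConfig()
    network: NetworkConfig = NetworkConfig()
    training: TrainingConfig = TrainingConfig(epochs=20_000)
    trial: TrialConfig = TrialConfig()
    n_networks: int = 10
    n_trials: int = 8
    seed: int = 0
    #: float32 roughly halves training time at no cost to the statistics
    dtype: type = np.float64


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    tests: Dict[str, TestResult]
    learning_curves: pd.DataFrame
    learning_metrics: pd.DataFrame
    trial: TrialLog
    params: dict
    adaptive: dict


def trial_metrics_table(trial: TrialLog, cfg: TrialConfig) -> pd.DataFrame:
    """MetricsTable rows from a batched trial log: one row per
    (network, trial, context)."""
    pre = range(1, cfg.switch_step + 1)
    post = range(cfg.switch_step + 1, cfg.total_steps + 1)
    rows = []
    for context, steps in ((SELF_PRODUCED, pre), (EXTERNALLY_PRODUCED, post)):
        resp = posterior_response(trial, steps)
        sig = mean_prior_sigma(trial, steps)
        fe = trial.f_t[_step_slice(steps)].mean(axis=0)
        for n in range(resp.shape[0]):
            for j in range(resp.shape[1]):
                rows.append({"network": n, "trial": j, "context": context,
                             "posterior_response": float(resp[n, j]),
                             "prior_sigma": float(sig[n, j]),
                             "free_energy": float(fe[n, j])})
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Drive the full pipeline for one hyperparameter setting."""
    self_ds, ext_ds, test_extero = build_dataset(cfg.generator)
    data = make_training_data(self_ds, ext_ds, cfg.dtype)
    params = init_parameters(cfg.network, cfg.n_networks, cfg.seed,
                             cfg.training.bias_variance, cfg.dtype)
    adaptive = init_adaptive(cfg.network, cfg.n_networks, data.n_sequences,
                             data.T, cfg.dtype)
    t_cfg = replace(cfg.training, seed=cfg.seed)
    curves = train(data, params, adaptive, t_cfg, cfg.network)
    from .training import learning_metrics as _lm
    lm = _lm(params, adaptive, data, cfg.network)

    n_trials = min(cfg.n_trials, len(test_extero))
    test_b = np.stack(test_extero[:n_trials])
    self_mask = data.context_mask(SELF_PRODUCED)
    trial = run_trial(params, adaptive, self_mask, test_b, cfg.network,
                      replace(cfg.trial, seed=cfg.seed),
                      set_posture=cfg.generator.set_posture)
    metrics = trial_metrics_table(trial, cfg.trial)
    tests = context_comparison(metrics)
    return ExperimentResult(metrics=metrics, tests=tests,
                            learning_curves=curves, learning_metrics=lm,
                            trial=trial, params=params, adaptive=adaptive)


def lesion_config(base: NetworkConfig, *, association_latents: Optional[int] = None,
                  executive_latents: Optional[int] = None) -> NetworkConfig:
    """Reduced-latent-dimension variants of the architecture."""
    lat = dict(base.latent_dims)
    if association_latents is not None:
        lat["A"] = association_latents
    if executive_latents is not None:
        lat["C"] = executive_latents
    return base.with_overrides(latent_dims=lat)


def meta_prior_config(base: NetworkConfig,
                      W: Tuple[float, float, float]) -> NetworkConfig:
    """Per-level meta-prior override."""
    return base.with_overrides(meta_priors=tuple(float(w) for w in W))
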