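"""Configuration objects for the network, data generator, training and test phases.

The defaults throughout reproduce the baseline simulation: a three-level
predictive-coding-inspired variational RNN (sensory / association / executive)
with multiple-timescale leaky-integrator dynamics, driving a planar three-link
arm in a [-1, 1]^2 workspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

import numpy as np

#: Area keys: exteroceptive, proprioceptive, association, executive.
SENSORY_AREAS: Tuple[str, str] = ("E", "P")
DETERMINISTIC_AREAS: Tuple[str, str, str] = ("E", "P", "A")
LATENT_AREAS: Tuple[str, str, str, str] = ("E", "P", "A", "C")

#: Network level of each latent area (meta-prior index l-1).
AREA_LEVEL: Mapping[str, int] = {"E": 0, "P": 0, "A": 1, "C": 2}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the hierarchical variational RNN.

    The executive area carries latent units only (its single sequence-constant
    posterior acts as a context switch); the other three areas combine
    deterministic leaky-integrator units with Gaussian latent units.
    """

    det_dims: Mapping[str, int] = field(
        default_factory=lambda: {"E": 15, "P": 15, "A": 15}
    )
    latent_dims: Mapping[str, int] = field(
        default_factory=lambda: {"E": 1, "P": 1, "A": 3, "C": 1}
    )
    #: fast/slow time constants of deterministic units; within each area the
    #: first ``n_fast`` units use tau_fast, the remainder tau_slow.
    tau_fast: float = 2.0
    tau_slow: float = 4.0
    n_fast: Mapping[str, int] | None = None
    #: meta-priors (W1, W2, W3): complexity weight per network level
    #: (sensory, association, executive).
    meta_priors: Tuple[float, float, float] = (0.005, 0.005, 0.005)
    extero_dim: int = 2
    proprio_dim: int = 3
    #: numerical guard on sigma pre-activations before exp (implementation
    #: tolerance, not model content).
    sigma_preact_clip: float = 10.0

    def n_fast_for(self, area: str) -> int:
        n = self.det_dims[area]
        if self.n_fast is not None and area in self.n_fast:
            return self.n_fast[area]
        # default split: 8 fast / 7 slow at n=15, ceil(n/2) in general
        return (n + 1) // 2

    def tau(self, area: str) -> np.ndarray:
        """Per-unit time constants for a deterministic area."""
        n = self.det_dims[area]
        nf = self.n_fast_for(area)
        if not 0 <= nf <= n:
            raise ValueError(f"n_fast={nf} outside [0, {n}] for area {area}")
        out = np.full(n, self.tau_slow, dtype=float)
        out[:nf] = self.tau_fast
        return out

    def out_dim(self, area: str) -> int:
        if area == "E":
            return self.extero_dim
        if area == "P":
            return self.proprio_dim
        raise KeyError(area)

    def with_overrides(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic sensorimotor data: cyclic 'random movement then return to
    set posture' joint trajectories plus forward-kinematics exteroception."""

    n_train_sequences: int = 24
    n_test_extero: int = 8
    cycles_per_sequence: int = 10
    steps_per_cycle: int = 20
    random_phase_steps: int = 14
    set_posture: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    smoothing_coefficient: float = 0.6
    step_scale: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.random_phase_steps < self.steps_per_cycle:
            raise ValueError("random_phase_steps must lie in (0, steps_per_cycle)")
        if not 0 < self.smoothing_coefficient <= 1:
            raise ValueError("smoothing_coefficient must lie in (0, 1]")
        if self.step_scale < 0:
            raise ValueError("step_scale must be >= 0")
        if not all(-0.8 <= v <= 0.8 for v in self.set_posture):
            raise ValueError("set_posture must lie in [-0.8, 0.8]^3")

    @property
    def sequence_length(self) -> int:
        return self.cycles_per_sequence * self.steps_per_cycle


@dataclass(frozen=True)
class TrainingConfig:
    """Learning-phase settings: joint Adam optimization of synaptic weights
    and per-sequence adaptive posterior variables."""

    epochs: int = 200_000
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    bias_variance: float = 10.0
    seed: int = 0
    metric_logging_interval: int = 100

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass(frozen=True)
class PIDGains:
    """Joint-space PID gains (normalized-angle units).

    The plant is kinematic (joints move by the control signal directly), so
    a high proportional gain with light derivative damping settles within a
    few steps; an integral term only adds windup on such a plant and
    defaults to zero.
    """

    kp: float = 0.95
    ki: float = 0.0
    kd: float = 0.05

    def __post_init__(self):
        if self.kp <= 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("require kp > 0 and ki, kd >= 0")


@dataclass(frozen=True)
class TrialConfig:
    """Test-phase protocol: sliding-window posterior inference with fixed
    weights, and a scripted self-produced -> externally-produced switch."""

    total_steps: int = 200
    switch_step: int = 100
    window: int = 10
    updates_per_step: int = 50
    learning_rate: float = 0.09
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    #: epsilon handling during window optimization; mean propagation by default
    sample_noise: bool = False
    seed: int = 0
    gains: PIDGains = field(default_factory=PIDGains)

    def __post_init__(self):
        if not 0 < self.switch_step < self.total_steps:
            raise ValueError("switch_step must lie in (0, total_steps)")
        if self.window < 1:
            raise ValueError("window must be >= 1")
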