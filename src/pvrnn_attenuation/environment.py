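"""Simulated square world: three-joint arm with PID control and the
context-dependent object.

Active inference is realized by feeding the network's proprioceptive
predictions to a PID controller as target joint angles; the plant is
kinematic (joints move exactly by the control signal each step, no inertia).
All controller arithmetic happens in normalized-angle units; joints are
clipped to their physical range after every update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PIDGains
from .datagen import SELF_PRODUCED, EXTERNALLY_PRODUCED
from .kinematics import ANGLE_RANGE, forward_kinematics, normalize_angle, denormalize_angle


@dataclass
class ArmState:
    """Joint configuration plus PID memory. Supports a leading batch axis:
    ``joints`` is (..., 3) in actual radians [0, pi]."""

    joints: np.ndarray
    integral: np.ndarray = None
    prev_error: np.ndarray = None

    def __post_init__(self):
        self.joints = np.clip(np.asarray(self.joints, dtype=float), 0.0, np.pi)
        if self.integral is None:
            self.integral = np.zeros_like(self.joints)
        if self.prev_error is None:
            self.prev_error = np.zeros_like(self.joints)

    @property
    def proprio(self) -> np.ndarray:
        """Normalized joint angles in [-0.8, 0.8]."""
        return normalize_angle(self.joints)

    @property
    def hand(self) -> np.ndarray:
        return forward_kinematics(self.proprio)


def arm_at_posture(posture_normalized, batch_shape=()) -> ArmState:
    """Arm resting at a normalized posture (optionally batched)."""
    j = denormalize_angle(np.asarray(posture_normalized, dtype=float))
    return ArmState(np.broadcast_to(j, (*batch_shape, 3)).copy())


def pid_step(state: ArmState, target_normalized: np.ndarray,
             gains: PIDGains = PIDGains()) -> ArmState:
    """One control step toward a normalized joint-angle target.

    control = kp*e + ki*sum(e) + kd*(e - e_prev), applied directly to the
    normalized joint angles and clipped to the physical range.
    """
    target = np.asarray(target_normalized, dtype=float)
    # tolerance covers float32 rounding of the range bound itself
    if np.any(np.abs(target) > ANGLE_RANGE + 1e-6):
        raise ValueError("PID target outside [-0.8, 0.8]")
    target = np.clip(target, -ANGLE_RANGE, ANGLE_RANGE)
    err = target - state.proprio
    integral = state.integral + err
    control = gains.kp * err + gains.ki * integral + gains.kd * (err - state.prev_error)
    new_norm = np.clip(state.proprio + control, -ANGLE_RANGE, ANGLE_RANGE)
    return ArmState(denormalize_angle(new_norm), integral, err)


def observe(state: ArmState, context: str,
            external_extero_seq: np.ndarray | None = None,
            t: int | None = None):
    """The 5-D sensation at the current step: (proprio 3, extero 2).

    In the self-produced context the object sits at the hand; in the
    externally produced context it follows the given exteroceptive test
    sequence (1-based step index ``t``).
    """
    proprio = state.proprio
    if context == SELF_PRODUCED:
        extero = state.hand
    elif context == EXTERNALLY_PRODUCED:
        if external_extero_seq is None or t is None:
            raise ValueError("externally produced context needs a sequence and step")
        if not 1 <= t <= external_extero_seq.shape[-2]:
            raise IndexError(f"step {t} outside external sequence")
        extero = external_extero_seq[..., t - 1, :]
    else:
        raise ValueError(context)
    return proprio, extero
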