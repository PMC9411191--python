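"""Planar three-link arm: angle normalization and forward kinematics.

Joint angles are physically limited to [0, pi] rad and mapped linearly onto
[-0.8, 0.8] to match the tanh output range of the network. The link lengths
are 0.1, 0.3 and 0.5, so the hand always stays within radius 0.9 of the base,
inside the [-1, 1]^2 workspace. The base sits at the origin and link
orientations accumulate from the +x axis.
"""

from __future__ import annotations

import numpy as np

LINK_LENGTHS = np.array([0.1, 0.3, 0.5])
ANGLE_RANGE = 0.8  # normalized half-range


def normalize_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Map actual joint angles in [0, pi] rad to normalized [-0.8, 0.8]."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("actual joint angle outside [0, pi]")
    out = (theta / np.pi) * (2 * ANGLE_RANGE) - ANGLE_RANGE
    return out if out.ndim else float(out)


def denormalize_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`normalize_angle`."""
    a = np.asarray(a, dtype=float)
    if np.any(np.abs(a) > ANGLE_RANGE + 1e-12):
        raise ValueError("normalized joint angle outside [-0.8, 0.8]")
    out = (a + ANGLE_RANGE) / (2 * ANGLE_RANGE) * np.pi
    return out if out.ndim else float(out)


def forward_kinematics(proprio_normalized: np.ndarray) -> np.ndarray:
    """Hand position of the three-link arm.

    Parameters
    ----------
    proprio_normalized:
        Array of shape (..., 3) of normalized joint angles in [-0.8, 0.8].

    Returns
    -------
    Array of shape (..., 2): (x, y) hand position.
    """
    ang = denormalize_angle(np.asarray(proprio_normalized, dtype=float))
    phi = np.cumsum(ang, axis=-1)  # cumulative link orientation from +x axis
    x = np.sum(LINK_LENGTHS * np.cos(phi), axis=-1)
    y = np.sum(LINK_LENGTHS * np.sin(phi), axis=-1)
    return np.stack([x, y], axis=-1)
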