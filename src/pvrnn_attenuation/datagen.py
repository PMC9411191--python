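"""Synthetic sensorimotor datasets.

Each training sequence is 10 cycles of 20 steps: a smoothed random walk of
the three joints (imprecise movement) followed by a linear return that lands
exactly on the set posture at the cycle's last step (precise movement).
Exteroception is the 2-D object position: in the self-produced context it is
the arm's hand position via forward kinematics of the paired joint sequence;
in the externally produced context the same 24 exteroceptive sequences are
re-paired by a seeded derangement, so the two contexts share identical
proprioception and an identical multiset of exteroception, differing only in
their correlation structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .kinematics import forward_kinematics, ANGLE_RANGE

SELF_PRODUCED = "self_produced"
EXTERNALLY_PRODUCED = "externally_produced"


@dataclass
class SensorimotorSequence:
    """Paired proprioceptive (T x 3) and exteroceptive (T x 2) time series."""

    proprio: np.ndarray
    extero: np.ndarray
    context: str

    def __post_init__(self):
        self.proprio = np.asarray(self.proprio, dtype=float)
        self.extero = np.asarray(self.extero, dtype=float)
        if self.proprio.ndim != 2 or self.proprio.shape[1] != 3:
            raise ValueError("proprio must be T x 3")
        if self.extero.shape != (self.proprio.shape[0], 2):
            raise ValueError("extero must be T x 2, aligned with proprio")
        if np.any(np.abs(self.proprio) > ANGLE_RANGE + 1e-12):
            raise ValueError("proprio outside [-0.8, 0.8]")
        if np.any(np.abs(self.extero) > 1 + 1e-12):
            raise ValueError("extero outside [-1, 1]^2")

    @property
    def T(self) -> int:
        return self.proprio.shape[0]


@dataclass
class ContextDataset:
    """All sequences of one context plus the proprio->extero pairing."""

    sequences: List[SensorimotorSequence]
    pairing: np.ndarray
    manifest: dict = field(default_factory=dict)

    def proprio_array(self) -> np.ndarray:
        return np.stack([s.proprio for s in self.sequences])

    def extero_array(self) -> np.ndarray:
        return np.stack([s.extero for s in self.sequences])


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def generate_joint_trajectory(config: GeneratorConfig, seq_index: int) -> np.ndarray:
    """One T x 3 joint-angle trajectory, deterministic given (seed, seq_index).

    Per cycle the first ``random_phase_steps`` steps are a smoothed Gaussian
    random walk clipped to [-0.8, 0.8]; the remaining steps interpolate
    linearly back to the set posture.
    """
    rng = _rng(config.seed, 7, seq_index)
    set_posture = np.asarray(config.set_posture, dtype=float)
    c = config.smoothing_coefficient
    n_rand = config.random_phase_steps
    n_ret = config.steps_per_cycle - n_rand
    traj = np.empty((config.sequence_length, 3))
    pos = set_posture.copy()
    k = 0
    for _ in range(config.cycles_per_sequence):
        vel = np.zeros(3)
        for _ in range(n_rand):
            vel = (1 - c) * vel + c * rng.normal(0.0, config.step_scale, size=3) \
                if config.step_scale > 0 else np.zeros(3)
            pos = np.clip(pos + vel, -ANGLE_RANGE, ANGLE_RANGE)
            traj[k] = pos
            k += 1
        start = pos.copy()
        for j in range(1, n_ret + 1):
            traj[k] = start + (j / n_ret) * (set_posture - start)
            k += 1
        pos = set_posture.copy()
        traj[k - 1] = set_posture  # land exactly, no rounding residue
    return traj


def sample_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random fixed-point-free permutation of range(n), by rejection."""
    if n < 2:
        raise ValueError("derangement requires n >= 2")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def build_dataset(config: GeneratorConfig):
    """Build both training contexts and the held-out test exteroception.

    Returns
    -------
    (self_produced, externally_produced, test_extero):
        two :class:`ContextDataset` objects sharing proprioception verbatim,
        and a list of ``n_test_extero`` T x 2 arrays from held-out joint
        trajectories.
    """
    n = config.n_train_sequences
    proprio = [generate_joint_trajectory(config, i) for i in range(n)]
    extero = [forward_kinematics(p) for p in proprio]

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config_hash(config),
    }
    self_ds = ContextDataset(
        sequences=[
            SensorimotorSequence(p, e, SELF_PRODUCED)
            for p, e in zip(proprio, extero)
        ],
        pairing=np.arange(n),
        manifest={**manifest, "context": SELF_PRODUCED},
    )
    pairing = sample_derangement(n, _rng(config.seed, 11))
    ext_ds = ContextDataset(
        sequences=[
            SensorimotorSequence(proprio[i], extero[pairing[i]], EXTERNALLY_PRODUCED)
            for i in range(n)
        ],
        pairing=pairing,
        manifest={**manifest, "context": EXTERNALLY_PRODUCED},
    )
    test_extero = [
        forward_kinematics(generate_joint_trajectory(config, n + j))
        for j in range(config.n_test_extero)
    ]
    return self_ds, ext_ds, test_extero


def config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV / JSON export and import

def save_dataset(out_dir: str | Path, self_ds: ContextDataset,
                 ext_ds: ContextDataset,
                 test_extero: Sequence[np.ndarray]) -> Path:
    """Write one CSV per sequence plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for ds, tag in ((self_ds, "self"), (ext_ds, "external")):
        for i, seq in enumerate(ds.sequences):
            name = f"{tag}_{i:02d}.csv"
            _write_sequence_csv(out / name, seq.proprio, seq.extero)
            files.append({"file": name, "context": seq.context, "index": i})
    for j, ext in enumerate(test_extero):
        name = f"test_extero_{j:02d}.csv"
        df = pd.DataFrame({
            "step": np.arange(1, ext.shape[0] + 1),
            "obj_x": ext[:, 0], "obj_y": ext[:, 1],
        })
        df.to_csv(out / name, index=False)
        files.append({"file": name, "context": "test_extero", "index": j})
    manifest = {
        **self_ds.manifest,
        "context": None,
        "pairing_external": ext_ds.pairing.tolist(),
        "files": files,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _write_sequence_csv(path: Path, proprio: np.ndarray, extero: np.ndarray):
    df = pd.DataFrame({
        "step": np.arange(1, proprio.shape[0] + 1),
        "joint1": proprio[:, 0], "joint2": proprio[:, 1], "joint3": proprio[:, 2],
        "obj_x": extero[:, 0], "obj_y": extero[:, 1],
    })
    df.to_csv(path, index=False)


def load_dataset(data_dir: str | Path):
    """Inverse of :func:`save_dataset`."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    pairing = np.asarray(manifest["pairing_external"], dtype=int)
    self_seqs, ext_seqs, test = [], [], []
    for entry in manifest["files"]:
        df = pd.read_csv(data_dir / entry["file"])
        if entry["context"] == "test_extero":
            test.append(df[["obj_x", "obj_y"]].to_numpy())
        else:
            p = df[["joint1", "joint2", "joint3"]].to_numpy()
            e = df[["obj_x", "obj_y"]].to_numpy()
            (self_seqs if entry["context"] == SELF_PRODUCED else ext_seqs).append(
                SensorimotorSequence(p, e, entry["context"]))
    n = len(self_seqs)
    self_ds = ContextDataset(self_seqs, np.arange(n), manifest)
    ext_ds = ContextDataset(ext_seqs, pairing, manifest)
    return self_ds, ext_ds, test
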