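"""Checkpoint serialization: trained weights + adaptive state in one file."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .core import Arrays

_AD = "adaptive__"


def save_checkpoint(path: str | Path, params: Arrays, adaptive: Arrays,
                    net_cfg: NetworkConfig, meta: dict | None = None) -> Path:
    """Write a single .npz with weights, adaptive variables and config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = json.dumps({"config": _cfg_dict(net_cfg), "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **params, **{_AD + k: v for k, v in adaptive.items()})
    return path


def load_checkpoint(path: str | Path):
    """Returns (params, adaptive, NetworkConfig, meta)."""
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        params = {k: z[k] for k in z.files
                  if not k.startswith(_AD) and k != "__header__"}
        adaptive = {k[len(_AD):]: z[k] for k in z.files if k.startswith(_AD)}
    cd = header["config"]
    cfg = NetworkConfig(det_dims=cd["det_dims"], latent_dims=cd["latent_dims"],
                        tau_fast=cd["tau_fast"], tau_slow=cd["tau_slow"],
                        n_fast=cd["n_fast"],
                        meta_priors=tuple(cd["meta_priors"]),
                        extero_dim=cd["extero_dim"],
                        proprio_dim=cd["proprio_dim"],
                        sigma_preact_clip=cd["sigma_preact_clip"])
    return params, adaptive, cfg, header["meta"]


def _cfg_dict(cfg: NetworkConfig) -> dict:
    d = asdict(cfg)
    d["det_dims"] = dict(cfg.det_dims)
    d["latent_dims"] = dict(cfg.latent_dims)
    return d
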