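"""Adam optimizer over dictionaries of named arrays."""

from __future__ import annotations

from typing import Dict, Iterable

import numpy as np


class Adam:
    """Standard Adam with bias correction.

    Operates in place on a dict of parameter arrays; names listed in
    ``frozen`` are never updated (used for the fixed deterministic-unit
    biases). Parameter arrays may be views (e.g. a sliding time window of
    adaptive variables); updates are written through.
    """

    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 frozen: Iterable[str] = ()):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.frozen = frozenset(frozen)
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for name, p in params.items():
            if name in self.frozen or name not in grads:
                continue
            g = grads[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            m, v = self.m[name], self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
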