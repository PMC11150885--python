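"""Adam optimizer over a model's named parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(self, model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        for name, arr, _, _ in model.named_params():
            self.m[name] = np.zeros_like(arr)
            self.v[name] = np.zeros_like(arr)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, arr, grads, key in self.model.named_params():
            g = grads.get(key)
            if g is None:
                continue
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            arr -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
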