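"""Adam optimizer (in-place updates on the model's parameter arrays)."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive moment estimation with bias correction.

    Defaults follow the study configuration: learning rate 2e-4. Moment
    decay rates are the customary 0.9 / 0.999 with eps 1e-7.
    """

    def __init__(self, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params) -> None:
        """Apply one update. ``named_params`` yields (name, param, grad)."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p, g in named_params:
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
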