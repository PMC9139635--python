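"""Adam optimizer for :class:`~buspool.nn.layers.Param` collections."""

from __future__ import annotations

import numpy as np

from ._kernels import HAVE_NUMBA, njit


@njit(cache=True, fastmath=True)
def _adam_update_nb(p, g, m, v, lr, b1, b2, bc1, bc2, eps):  # pragma: no cover - compiled
    for i in range(p.size):
        mi = b1 * m[i] + (1.0 - b1) * g[i]
        vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        m[i] = mi
        v[i] = vi
        p[i] -= lr * (mi / bc1) / (np.sqrt(vi / bc2) + eps)


def _adam_update_np(p, g, m, v, lr, b1, b2, bc1, bc2, eps):
    m *= b1
    m += (1.0 - b1) * g
    v *= b2
    v += (1.0 - b2) * g * g
    p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


class Adam:
    """Adam with bias-corrected first/second moment estimates.

    Defaults follow the training recipe used throughout this package:
    beta1 = 0.5, beta2 = 0.99, learning rate 1e-4.
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.5, beta2: float = 0.99, eps: float = 1e-8):
        if not 0.0 < beta1 < 1.0 or not 0.0 < beta2 < 1.0:
            raise ValueError("beta1 and beta2 must lie strictly between 0 and 1")
        self.params = list(params)
        self.lr = float(lr)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        update = _adam_update_nb if HAVE_NUMBA else _adam_update_np
        for p, m, v in zip(self.params, self._m, self._v):
            update(p.data.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                   self.lr, b1, b2, bc1, bc2, self.eps)
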