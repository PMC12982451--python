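"""Adam optimizer and the binary cross-entropy objective."""

from __future__ import annotations

import numpy as np

from bosbench.nn.layers import Param


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(logits) against y in {0, 1}.

    Returns ``(loss, dloss/dlogits)``; the gradient is the numerically
    exact ``(sigmoid(z) - y) / n``.
    """
    z = logits.astype(np.float64)
    # log(1 + e^-|z|) formulation avoids overflow
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = np.asarray((sigmoid(z) - y) / len(z), dtype=logits.dtype)
    return loss, grad


class Adam:
    """Adaptive-moment gradient descent over a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        """Apply one update from accumulated gradients, then zero them."""
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                # decoupled decay, applied only to multi-dim params (not biases)
                if p.value.ndim > 1:
                    p.value -= self.lr * self.weight_decay * p.value
            p.grad[...] = 0.0
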