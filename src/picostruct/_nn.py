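"""Minimal neural-net utilities shared by the desk-scale backends."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "softmax_rows", "cross_entropy_rows", "sinusoid_table"]


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_rows(logits: np.ndarray, targets: np.ndarray):
    """Mean token-level cross entropy and its gradient w.r.t. the logits."""
    probs = softmax_rows(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


def sinusoid_table(length: int, dim: int, base: float = 30.0) -> np.ndarray:
    """Fixed sin/cos positional features; low frequencies make nearby
    positions similar, which the compatibility model exploits."""
    assert dim % 2 == 0
    pos = np.arange(length)[:, None]
    freqs = base ** (-np.arange(dim // 2) / max(dim // 2 - 1, 1))
    ang = pos * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        self.t += 1
        lr = self.lr if lr is None else lr
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
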