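"""Minimal numpy building blocks for the dilated-convolution classifier.

Forward and backward passes are written explicitly; the networks involved are
small enough (tens of channels, hundreds of timepoints) that BLAS-backed
``matmul``/``einsum`` calls are fast on a single CPU, and an explicit
implementation keeps every numerical step inspectable and exactly
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dilated_conv1d",
    "dilated_conv1d_backward",
    "asinh",
    "asinh_grad",
    "softmax",
    "cross_entropy",
    "Adam",
]


def dilated_conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray, dilation: int):
    """Causal dilated 1-D convolution preserving temporal length.

    Parameters
    ----------
    x : (B, Cin, T) input.
    W : (Cout, Cin, k) kernel; tap ``j`` looks ``(k-1-j)*dilation`` samples back.
    b : (Cout,) bias.
    dilation : spacing between taps.

    Returns ``(y, x_padded)`` where y is (B, Cout, T) and x_padded is the
    left-padded input cached for the backward pass.  Left padding by
    ``(k-1)*dilation`` zeros makes the convolution causal and
    length-preserving.
    """
    k = W.shape[2]
    T = x.shape[2]
    pad = (k - 1) * dilation
    xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
    y = np.zeros((x.shape[0], W.shape[0], T), dtype=x.dtype)
    for j in range(k):
        # tap j reads xp[:, :, j*dilation : j*dilation + T]
        y += np.matmul(W[:, :, j], xp[:, :, j * dilation : j * dilation + T])
    y += b[None, :, None]
    return y, xp


def dilated_conv1d_backward(dy: np.ndarray, xp: np.ndarray, W: np.ndarray, dilation: int):
    """Gradients of :func:`dilated_conv1d` w.r.t. input, kernel and bias."""
    k = W.shape[2]
    T = dy.shape[2]
    pad = (k - 1) * dilation
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for j in range(k):
        sl = slice(j * dilation, j * dilation + T)
        dxp[:, :, sl] += np.matmul(W[:, :, j].T, dy)
        dW[:, :, j] = np.einsum("bot,bit->oi", dy, xp[:, :, sl], optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = dxp[:, :, pad:] if pad else dxp
    return dx, dW, db


def asinh(x: np.ndarray) -> np.ndarray:
    return np.arcsinh(x)


def asinh_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(1.0 + x * x)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits


class Adam:
    """Adam with the standard moment defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m = self.m[name]
            v = self.v[name]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
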