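"""Minimal 3-D convolutional networks in numpy with manual backprop.

Supplies the desk-scale patch-to-patch dose generator (three 3x3x3 conv
layers with leaky-ReLU, receptive field 7 cubed) and an optional tiny patch
discriminator for the adversarial training profile.  Convolutions use
'same' zero padding and are evaluated as 27 shifted matrix products so the
arithmetic stays in BLAS.  Optimisation is Adam on mean-squared error.

Everything is seeded and deterministic: identical data, config and seed
produce bit-identical weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet3D", "PatchDiscriminator", "Adam"]

_K = 3  # kernel size
_LEAK = 0.1  # leaky-ReLU negative slope (plain ReLU units die under Adam here)


def _lrelu(z):
    return np.where(z > 0, z, _LEAK * z)


def _dlrelu(z):
    return np.where(z > 0, 1.0, _LEAK)


def _conv3d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (B,Cin,D,H,W), w (Cout,Cin,3,3,3), b (Cout,) -> (B,Cout,D,H,W)."""
    B, Cin, D, H, W = x.shape
    Cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((B, Cout, D * H * W))
    for i in range(_K):
        for j in range(_K):
            for k in range(_K):
                sl = xp[:, :, i : i + D, j : j + H, k : k + W].reshape(B, Cin, -1)
                out += w[:, :, i, j, k][None] @ sl
    out = out.reshape(B, Cout, D, H, W)
    return out + b[None, :, None, None, None]


def _conv3d_backward(x, w, dout):
    """Gradients of _conv3d_same w.r.t. x, w, b."""
    B, Cin, D, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    dflat = dout.reshape(B, w.shape[0], -1)
    for i in range(_K):
        for j in range(_K):
            for k in range(_K):
                sl = xp[:, :, i : i + D, j : j + H, k : k + W].reshape(B, Cin, -1)
                # dW: sum_b dout (B,Co,N) x slice (B,Ci,N) -> (Co,Ci)
                dw[:, :, i, j, k] = np.einsum("bon,bcn->oc", dflat, sl, optimize=True)
                contrib = (w[:, :, i, j, k].T[None] @ dflat).reshape(B, Cin, D, H, W)
                dxp[:, :, i : i + D, j : j + H, k : k + W] += contrib
    db = dflat.sum(axis=(0, 2))
    dx = dxp[:, :, 1:-1, 1:-1, 1:-1]
    return dx, dw, db


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvNet3D:
    """conv(1->c) LReLU conv(c->c) LReLU conv(c->1): the patch dose generator."""

    def __init__(self, channels: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channels = channels

        def he(cout, cin):
            scale = np.sqrt(2.0 / (cin * _K**3))
            return rng.normal(0.0, scale, size=(cout, cin, _K, _K, _K))

        self.w1, self.b1 = he(channels, 1), np.zeros(channels)
        self.w2, self.b2 = he(channels, channels), np.zeros(channels)
        # zero-init output layer: the residual correction starts at exactly 0
        self.w3, self.b3 = np.zeros((1, channels, _K, _K, _K)), np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x (B,1,D,H,W) -> (B,1,D,H,W); optionally returns the cache."""
        z1 = _conv3d_same(x, self.w1, self.b1)
        a1 = _lrelu(z1)
        z2 = _conv3d_same(a1, self.w2, self.b2)
        a2 = _lrelu(z2)
        y = _conv3d_same(a2, self.w3, self.b3)
        if want_cache:
            return y, (x, z1, a1, z2, a2)
        return y

    def backward(self, cache, dy: np.ndarray):
        """Gradient of the loss w.r.t. every parameter (and the input)."""
        x, z1, a1, z2, a2 = cache
        da2, dw3, db3 = _conv3d_backward(a2, self.w3, dy)
        dz2 = da2 * _dlrelu(z2)
        da1, dw2, db2 = _conv3d_backward(a1, self.w2, dz2)
        dz1 = da1 * _dlrelu(z1)
        dx, dw1, db1 = _conv3d_backward(x, self.w1, dz1)
        return [dw1, db1, dw2, db2, dw3, db3], dx

    def state_dict(self) -> dict:
        return {"channels": self.channels,
                "w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2,
                "w3": self.w3, "b3": self.b3}

    @classmethod
    def from_state(cls, state: dict) -> "ConvNet3D":
        net = cls(channels=int(state["channels"]))
        for k in ("w1", "b1", "w2", "b2", "w3", "b3"):
            setattr(net, k, np.array(state[k], dtype=float))
        return net


class PatchDiscriminator:
    """conv(1->c) LReLU, global average pool, linear -> logit per patch."""

    def __init__(self, channels: int = 4, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / _K**3)
        self.w1 = rng.normal(0.0, scale, size=(channels, 1, _K, _K, _K))
        self.b1 = np.zeros(channels)
        self.wl = rng.normal(0.0, 1.0 / np.sqrt(channels), size=(channels,))
        self.bl = 0.0

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w1, self.b1, self.wl]

    def forward(self, x: np.ndarray, want_cache: bool = False):
        z1 = _conv3d_same(x, self.w1, self.b1)
        a1 = _lrelu(z1)
        pooled = a1.mean(axis=(2, 3, 4))  # (B, C)
        logit = pooled @ self.wl + self.bl
        if want_cache:
            return logit, (x, z1, a1, pooled)
        return logit

    def backward(self, cache, dlogit: np.ndarray):
        x, z1, a1, pooled = cache
        B = x.shape[0]
        dwl = dlogit @ pooled
        dbl = float(dlogit.sum())
        n_spatial = np.prod(a1.shape[2:])
        da1 = (dlogit[:, None] * self.wl[None, :])[:, :, None, None, None] / n_spatial
        da1 = np.broadcast_to(da1, a1.shape)
        dz1 = da1 * _dlrelu(z1)
        dx, dw1, db1 = _conv3d_backward(x, self.w1, dz1)
        return [dw1, db1, dwl], dbl, dx
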