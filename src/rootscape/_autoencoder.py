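"""A small, deterministic convolutional autoencoder in pure numpy.

Trained to reconstruct binary root silhouettes; the 8-dimensional bottleneck
serves as the high-level shape feature vector for k-means clustering.

Architecture (64x64x1 input):

    conv 3x3/2 (8) - ReLU - conv 3x3/2 (16) - ReLU - conv 3x3/2 (32) - ReLU
    flatten - dense -> latent (8)
    dense - ReLU - reshape (32, 8, 8)
    [upsample x2 - conv 3x3 (16) - ReLU] x2 ... - conv to 1 channel - sigmoid

Loss is mean binary cross-entropy; optimization is full-batch Adam.  All
arithmetic is numpy, so a fixed seed gives bit-identical training histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConvAutoencoder", "train_autoencoder"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B, C, H, W) -> (B, C*k*k, oh*ow) patch matrix."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    cols = np.empty((B, C, k * k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[
                :, :, i : i + oh * stride : stride, j : j + ow * stride : stride
            ]
    return cols.reshape(B, C * k * k, oh * ow), (oh, ow)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patch gradients back to the input."""
    B, C, H, W = x_shape
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(B, C, k * k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[
                :, :, i : i + oh * stride : stride, j : j + ow * stride : stride
            ] += dcols[:, :, i * k + j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class _Conv:
    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=1):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        self.x_shape = x.shape
        self.cols, (oh, ow) = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,bcl->bol", self.W, self.cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        B, c_out, oh, ow = dout.shape
        d2 = dout.reshape(B, c_out, oh * ow)
        self.dW = np.einsum("bol,bcl->oc", d2, self.cols)
        self.db = d2.sum(axis=(0, 2))
        dcols = np.einsum("oc,bol->bcl", self.W, d2)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self), ("b", self)]


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self.x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _downgrad2(d):
    B, C, H, W = d.shape
    return d.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


@dataclass
class ConvAutoencoder:
    """Frozen-architecture convolutional autoencoder with an 8-d latent."""

    latent_dim: int = 8
    side: int = 64
    seed: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if self.side % 8 != 0:
            raise ValueError("side must be divisible by 8")
        s8 = self.side // 8
        self.enc_convs = [
            _Conv(rng, 1, 8, stride=2),
            _Conv(rng, 8, 16, stride=2),
            _Conv(rng, 16, 32, stride=2),
        ]
        self.enc_relus = [_ReLU(), _ReLU(), _ReLU()]
        self.flat_dim = 32 * s8 * s8
        self.enc_fc = _Dense(rng, self.flat_dim, self.latent_dim)
        self.dec_fc = _Dense(rng, self.latent_dim, self.flat_dim)
        self.dec_relu0 = _ReLU()
        self.dec_convs = [
            _Conv(rng, 32, 16, stride=1),
            _Conv(rng, 16, 8, stride=1),
            _Conv(rng, 8, 1, stride=1),
        ]
        self.dec_relus = [_ReLU(), _ReLU()]
        self._s8 = s8
        self._adam_state: dict = {}
        self._step = 0

    # -- forward / backward -------------------------------------------------

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Images (B, side, side) in [0, 1] -> latent vectors (B, latent_dim)."""
        x = np.asarray(images, dtype=float)[:, None, :, :]
        for conv, relu in zip(self.enc_convs, self.enc_relus):
            x = relu.forward(conv.forward(x))
        return self.enc_fc.forward(x.reshape(x.shape[0], -1))

    def _decode(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_relu0.forward(self.dec_fc.forward(z))
        x = h.reshape(-1, 32, self._s8, self._s8)
        for i, conv in enumerate(self.dec_convs):
            x = conv.forward(_upsample2(x))
            if i < 2:
                x = self.dec_relus[i].forward(x)
        return 1.0 / (1.0 + np.exp(-x))

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self._decode(self.encode(images))[:, 0]

    def _layers(self):
        return self.enc_convs + [self.enc_fc, self.dec_fc] + self.dec_convs

    def _train_step(self, x: np.ndarray, lr: float) -> float:
        B = x.shape[0]
        target = x[:, None, :, :]
        z = self.encode(x)
        out = self._decode(z)
        eps = 1e-7
        p = np.clip(out, eps, 1 - eps)
        loss = float(
            -np.mean(target * np.log(p) + (1 - target) * np.log(1 - p))
        )
        # d(BCE)/d(logit) = (p - target) / n
        dlogit = (out - target) / target.size

        d = dlogit
        for i in range(2, -1, -1):
            if i < 2:
                d = self.dec_relus[i].backward(d)
            d = self.dec_convs[i].backward(d)
            d = _downgrad2(d)
        d = self.dec_relu0.backward(d.reshape(B, -1))
        d = self.dec_fc.backward(d)
        d = self.enc_fc.backward(d)
        d = d.reshape(B, 32, self._s8, self._s8)
        for i in range(2, -1, -1):
            d = self.enc_relus[i].backward(d)
            d = self.enc_convs[i].backward(d)

        self._step += 1
        b1, b2, eps_a = 0.9, 0.999, 1e-8
        for li, layer in enumerate(self._layers()):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                key = (li, name)
                m, v = self._adam_state.get(
                    key, (np.zeros_like(g), np.zeros_like(g))
                )
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - b1**self._step)
                vhat = v / (1 - b2**self._step)
                p_ = getattr(layer, name)
                setattr(layer, name, p_ - lr * mhat / (np.sqrt(vhat) + eps_a))
        return loss

    def fit(self, images: np.ndarray, epochs: int = 60, lr: float = 2e-3):
        """Full-batch training; appends per-epoch losses to ``history``."""
        x = np.asarray(images, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.side or x.shape[2] != self.side:
            raise ValueError(
                f"images must be (B, {self.side}, {self.side}); got {x.shape}"
            )
        for _ in range(epochs):
            self.history.append(self._train_step(x, lr))
        return self

    def fingerprint(self) -> dict:
        """Architecture/seed identity for provenance manifests."""
        return {
            "architecture": f"conv8-16-32/dense{self.latent_dim}/side{self.side}",
            "latent_dim": self.latent_dim,
            "seed": self.seed,
            "epochs_trained": len(self.history),
        }


def train_autoencoder(
    images: np.ndarray,
    latent_dim: int = 8,
    epochs: int = 60,
    seed: int = 0,
    lr: float = 2e-3,
) -> tuple[ConvAutoencoder, list[float]]:
    """Train a convolutional autoencoder on uniform square silhouettes.

    Returns the trained (frozen) model and its loss history.  Requires at
    least 16 images of identical size.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim != 3:
        raise ValueError("images must be a (B, H, W) stack of equal-size images")
    if x.shape[0] < 16:
        raise ValueError("need at least 16 images to train")
    if x.shape[1] != x.shape[2]:
        raise ValueError("images must be square")
    model = ConvAutoencoder(latent_dim=latent_dim, side=x.shape[1], seed=seed)
    model.fit(x, epochs=epochs, lr=lr)
    return model, list(model.history)
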