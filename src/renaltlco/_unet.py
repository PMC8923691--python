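"""Minimal NumPy U-net: stride-1 same-padding convs, max-pool encoder,
nearest-upsample decoder with skip concatenation, softmax head, Adam.

Written for small 3-class segmentation problems on CPU; all layers carry
explicit backward passes, and all randomness flows through one Generator so
training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "adam_step"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*9) patches of the 1-padded input."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(x.shape[0], x.shape[2], x.shape[3], -1)


class Conv3x3:
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * 9))
        self.w = rng.normal(0.0, scale, (out_ch, in_ch, 3, 3))
        self.b = np.zeros(out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x)  # (B, H, W, C*9)
        out = self._cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, o, h, w = dout.shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, o)
        self.dw = (d.T @ self._cols.reshape(-1, self._cols.shape[-1])).reshape(self.w.shape)
        self.db = d.sum(axis=0)
        # dx = conv(dout, kernels rotated 180 and channel-transposed)
        wt = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, 3, 3)
        cols = _im2col(dout)
        dx = cols @ wt.reshape(wt.shape[0], -1).T
        return dx.transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


class ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class MaxPool2:
    def forward(self, x):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        self._shape = x.shape
        return out

    def backward(self, dout):
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(self._shape)


class Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """Two 3x3 conv + ReLU pairs."""

    def __init__(self, in_ch, out_ch, rng):
        self.c1, self.r1 = Conv3x3(in_ch, out_ch, rng), ReLU()
        self.c2, self.r2 = Conv3x3(out_ch, out_ch, rng), ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, d):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(d))))

    def convs(self):
        return [self.c1, self.c2]


class UNet:
    """Encoder-decoder with ``depth`` pooling stages and skip connections."""

    def __init__(self, depth: int = 3, in_ch: int = 1, classes: int = 3,
                 base_channels: int = 8, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        self.depth = depth
        ch = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        prev = in_ch
        for i in range(depth):
            self.enc.append(_Block(prev, ch[i], rng))
            prev = ch[i]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(prev, ch[depth], rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.up_convs = []   # channel-halving conv after upsampling
        self.dec = []
        prev = ch[depth]
        for i in range(depth - 1, -1, -1):
            self.up_convs.append(Conv3x3(prev, ch[i], rng))
            self.dec.append(_Block(ch[i] * 2, ch[i], rng))
            prev = ch[i]
        self.head = Conv3x3(prev, classes, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) -> per-class logits (B, classes, H, W)."""
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._concat_split = []
        for up, uc, blk, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = uc.forward(up.forward(x))
            self._concat_split.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []  # gradient into each skip, shallowest level first
        for up, uc, blk, nskip in zip(
            reversed(self.ups), reversed(self.up_convs), reversed(self.dec),
            reversed(self._concat_split),
        ):
            d = blk.backward(d)
            dskips.append(d[:, :nskip])
            d = up.backward(uc.backward(d[:, nskip:]))
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = blk.backward(pool.backward(d) + dskip)

    def conv_layers(self):
        layers = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            layers += blk.convs()
        layers += self.up_convs
        layers.append(self.head)
        return layers

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def softmax_weighted_ce(logits: np.ndarray, labels: np.ndarray, weights: np.ndarray):
    """Weighted cross-entropy over pixels.

    ``labels`` is (B, H, W) int, ``weights`` per-class.  Returns
    (loss, dlogits); the gradient is (p - onehot) * w[label] / n_pixels.
    """
    b, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    p = np.exp(logp)
    wmap = weights[labels]  # (B, H, W)
    n = labels.size
    picked = logp.transpose(0, 2, 3, 1)[
        np.arange(b)[:, None, None], np.arange(h)[None, :, None], np.arange(w)[None, None, :], labels
    ]
    loss = float(-(wmap * picked).sum() / n)
    onehot = np.zeros_like(p)
    onehot.transpose(0, 2, 3, 1)[np.arange(b)[:, None, None], np.arange(h)[None, :, None], np.arange(w)[None, None, :], labels] = 1.0
    dlogits = (p - onehot) * wmap[:, None] / n
    return loss, dlogits


class adam_step:
    """Adam optimizer over a UNet's conv parameters."""

    def __init__(self, net: UNet, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.state = {}
        for i, layer in enumerate(net.conv_layers()):
            self.state[i] = [
                (np.zeros_like(layer.w), np.zeros_like(layer.w)),
                (np.zeros_like(layer.b), np.zeros_like(layer.b)),
            ]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.net.conv_layers()):
            for j, (param, grad) in enumerate([(layer.w, layer.dw), (layer.b, layer.db)]):
                m, v = self.state[i][j]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
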