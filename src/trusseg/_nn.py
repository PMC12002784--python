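"""Minimal numpy CNN machinery for the 2D segmentation networks.

Self-contained convolutional encoder–decoder building blocks with explicit
forward/backward passes and an Adam optimizer, written for CPU-scale
training of small plane-segmentation networks.  All arithmetic is float32;
convolutions are 3x3 'same' (zero padding) implemented with an im2col
matmul, downsampling is 2x2 max pooling, upsampling is nearest-neighbour.

Everything is deterministic given the numpy Generator used for weight
initialisation and data ordering.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet2D", "Adam", "dice_bce_loss", "unet_parameter_count"]

_F32 = np.float32


class Conv2d:
    """3x3 (or 1x1) same-padding convolution with bias.

    The spatial kernel is unrolled into ``k*k`` channel-mixing matmuls over
    shifted views of the zero-padded input, which keeps the inner loop in
    BLAS without an im2col gather.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        # stored flat as (c_out, c_in * k * k) with (c_in, ky, kx) minor order
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def _w4(self) -> np.ndarray:
        return self.W.reshape(self.c_out, self.c_in, self.k, self.k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, _, h, w = x.shape
        k, pad = self.k, self.k // 2
        x = x.astype(_F32, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        w4 = self._w4()
        # accumulate in (c_out, N, H, W) then move channels into place once
        acc = np.zeros((self.c_out, n, h, w), dtype=_F32)
        for dy in range(k):
            for dx in range(k):
                v = xp[:, :, dy : dy + h, dx : dx + w]
                acc += np.tensordot(w4[:, :, dy, dx], v, axes=([1], [1]))
        out = acc.transpose(1, 0, 2, 3) + self.b[None, :, None, None]
        if train:
            self._xp = xp
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = dout.shape
        k, pad = self.k, self.k // 2
        dout = np.ascontiguousarray(dout, dtype=_F32)
        xp = self._xp
        w4 = self._w4()
        dW4 = self.dW.reshape(self.c_out, self.c_in, k, k)
        dxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                v = xp[:, :, dy : dy + h, dx : dx + w]
                dW4[:, :, dy, dx] += np.tensordot(dout, v, axes=([0, 2, 3], [0, 2, 3]))
                g = np.tensordot(w4[:, :, dy, dx], dout, axes=([0], [1]))  # (c_in, N, H, W)
                dxp[:, :, dy : dy + h, dx : dx + w] += g.transpose(1, 0, 2, 3)
        self.db += dout.sum(axis=(0, 2, 3))
        self._xp = None
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling; gradients split evenly across ties."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            m = (xr == out[:, :, :, None, :, None]).astype(_F32)
            self._mask = m / m.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self._mask * dout[:, :, :, None, :, None]
        return dx.reshape(self._shape)

    def params(self):
        return []


class UpNearest2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


class _Block:
    """Two (conv 3x3 + ReLU) stages."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [Conv2d(c_in, c_out, rng), ReLU(), Conv2d(c_out, c_out, rng), ReLU()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class UNet2D:
    """Encoder–decoder with skip connections and a 1x1 output head.

    ``depth`` encoder levels with channel widths ``base * 2**i``, a
    bottleneck at ``base * 2**depth``, nearest-upsampling decoder levels with
    skip concatenation, and a linear 1x1 head producing ``c_out`` logit
    channels (apply a sigmoid for probabilities).  Input spatial dimensions
    must be multiples of ``2**depth``.
    """

    def __init__(self, c_in: int, c_out: int, depth: int, base: int,
                 rng: np.random.Generator):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base < 4:
            raise ValueError("base_width must be >= 4")
        self.c_in, self.c_out, self.depth, self.base = c_in, c_out, depth, base
        widths = [base * 2**i for i in range(depth)]
        self.enc = [_Block(c_in if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(widths[-1], base * 2**depth, rng)
        self.ups = [UpNearest2() for _ in range(depth)]
        self.dec = []
        up_ch = base * 2**depth
        for i in reversed(range(depth)):
            self.dec.append(_Block(up_ch + widths[i], widths[i], rng))
            up_ch = widths[i]
        self.head = Conv2d(base, c_out, rng, k=1)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def params(self):
        out = []
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        step = 2**self.depth
        if h < step or w < step:
            raise ValueError(
                f"input {h}x{w} smaller than 2^depth = {step} per side")
        if h % step or w % step:
            raise ValueError(
                f"input {h}x{w} must be a multiple of 2^depth = {step}")
        x = x.astype(_F32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_ch.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, blk, (up_ch, _) in zip(reversed(self.ups), reversed(self.dec),
                                       reversed(self._skip_ch)):
            d = blk.backward(d)
            dskips.append(d[:, up_ch:])
            d = up.backward(d[:, :up_ch])
        # dskips were collected shallowest-first; the encoder loop below runs
        # deepest-first, so reverse
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state) -> None:
        for (p, _), s in zip(self.params(), state):
            p[...] = s


def unet_parameter_count(c_in: int, c_out: int, depth: int, base: int) -> int:
    """Closed-form trainable-parameter count of :class:`UNet2D`.

    Each conv contributes ``k^2 * c_in * c_out + c_out``.
    """

    def conv(ci, co, k=3):
        return k * k * ci * co + co

    def block(ci, co):
        return conv(ci, co) + conv(co, co)

    widths = [base * 2**i for i in range(depth)]
    total = block(c_in, widths[0])
    for i in range(1, depth):
        total += block(widths[i - 1], widths[i])
    total += block(widths[-1], base * 2**depth)
    up_ch = base * 2**depth
    for i in reversed(range(depth)):
        total += block(up_ch + widths[i], widths[i])
        up_ch = widths[i]
    total += conv(base, c_out, k=1)
    return total


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray,
                  eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Per-channel soft-Dice + binary cross-entropy on logits.

    Returns ``(loss, dL/dlogits)``.  The Dice term is computed over the whole
    batch per output channel; BCE is the element mean.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    n_el = z[:, 0].size  # elements per channel
    loss = 0.0
    dz = np.zeros_like(z)
    for c in range(z.shape[1]):
        zc, yc, pc = z[:, c], y[:, c], p[:, c]
        # stable BCE: softplus(z) - y*z
        bce = float(np.mean(np.logaddexp(0.0, zc) - yc * zc))
        dz[:, c] += (pc - yc) / n_el
        num = 2.0 * np.sum(pc * yc) + eps
        den = np.sum(pc) + np.sum(yc) + eps
        dice_l = 1.0 - num / den
        dp = (num - 2.0 * yc * den) / (den * den)
        dz[:, c] += dp * pc * (1.0 - pc)
        loss += bce + dice_l
    return loss, dz.astype(_F32)


class Adam:
    """Adam optimizer over a UNet2D's (param, grad) pairs."""

    def __init__(self, params, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
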