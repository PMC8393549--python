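"""A lightweight 2D U-Net in pure NumPy, with manual backpropagation.

The network is the canonical symmetric encoder-decoder with skip
connections: per level two 3x3 convolution + (optional) batch
normalisation + ReLU blocks, 2x2 max pooling down, nearest-neighbour
upsampling up, channel concatenation of the skip, and a final 1x1
convolution producing per-class logits (softmax is applied inside the
loss).  Shapes are preserved, so the output spatial shape equals the
input and the channel count equals the class count.

Sizing is configurable; the defaults (base width 8, depth 2) are a
desk-scale profile intended for CPU experiments on small phantoms.  All
initialisation is seeded, forward/backward are deterministic, and an
Adam optimizer with the conventional moment constants is included.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet2D", "Adam"]


class _Conv2D:
    """Same-padded 2D convolution (odd kernel)."""

    def __init__(self, cin, cout, ksize, rng):
        fan_in = cin * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (cout, cin, ksize, ksize))
        self.b = np.zeros(cout)
        self.k = ksize
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def _windows(self, x):
        p = self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return np.lib.stride_tricks.sliding_window_view(x, (self.k, self.k),
                                                        axis=(2, 3))

    def forward(self, x):
        self._x = x
        win = self._windows(x)  # (B, Cin, H, W, k, k)
        return np.einsum("bchwij,ocij->bohw", win, self.w,
                         optimize=True) + self.b[None, :, None, None]

    def backward(self, dy):
        win = self._windows(self._x)
        self.dw += np.einsum("bchwij,bohw->ocij", win, dy, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3))
        wflip = self.w[:, :, ::-1, ::-1]
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        dyw = np.lib.stride_tricks.sliding_window_view(dyp, (self.k, self.k),
                                                       axis=(2, 3))
        return np.einsum("bohwij,ocij->bchw", dyw, wflip, optimize=True)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def buffers(self):
        return []


class _BatchNorm2D:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)[None, :, None, None]
        xhat = (x - mu[None, :, None, None]) * inv
        self._cache = (xhat, inv, train)
        return self.gamma[None, :, None, None] * xhat \
            + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train = self._cache
        axes = (0, 2, 3)
        self.dgamma += (dy * xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        dxhat = dy * self.gamma[None, :, None, None]
        if not train:
            return dxhat * inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        sum_dxhat = dxhat.sum(axis=axes)[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes)[None, :, None, None]
        return inv / m * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def buffers(self):
        return [self.running_mean, self.running_var]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._onehot = np.eye(4, dtype=bool)[idx]  # (b,c,h2,w2,4)
        self._shape = (b, c, h, w)
        return xr.max(axis=-1)

    def backward(self, dy):
        b, c, h, w = self._shape
        d = dy[..., None] * self._onehot
        d = d.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(b, c, h, w)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _downgrad2(dy):
    b, c, h, w = dy.shape
    return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv 3x3 -> (batch norm) -> ReLU"""

    def __init__(self, cin, cout, rng, norm):
        self.conv = _Conv2D(cin, cout, 3, rng)
        self.bn = _BatchNorm2D(cout) if norm else None
        self.relu = _ReLU()

    def forward(self, x, train):
        x = self.conv.forward(x)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        return self.relu.forward(x)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def layers(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class UNet2D:
    """Symmetric encoder-decoder segmentation network.

    Parameters
    ----------
    in_channels, n_classes : int
    base : int
        Feature width of the first level; level ``l`` uses ``base * 2**l``.
    depth : int
        Number of pooling steps; input H and W must be divisible by
        ``2**depth``.
    norm : bool
        Batch normalisation after every 3x3 convolution.
    seed : int
        Initialisation seed; identical seeds give identical parameters.
    """

    def __init__(self, in_channels: int, n_classes: int, base: int = 8,
                 depth: int = 2, norm: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.enc = []
        cin = in_channels
        for lvl in range(depth):
            cout = base * 2 ** lvl
            self.enc.append((_Block(cin, cout, rng, norm),
                             _Block(cout, cout, rng, norm)))
            cin = cout
        cbot = base * 2 ** depth
        self.bottleneck = (_Block(cin, cbot, rng, norm),
                           _Block(cbot, cbot, rng, norm))
        self.dec = []
        cup = cbot
        for lvl in reversed(range(depth)):
            cskip = base * 2 ** lvl
            self.dec.append((_Block(cup + cskip, cskip, rng, norm),
                             _Block(cskip, cskip, rng, norm)))
            cup = cskip
        self.head = _Conv2D(cup, n_classes, 1, rng)
        self._pools = None

    # -- plumbing -----------------------------------------------------
    def _all_layers(self):
        layers = []
        for b1, b2 in self.enc + [self.bottleneck] + self.dec:
            layers += b1.layers() + b2.layers()
        layers.append(self.head)
        return layers

    def params(self):
        """Flat list of (parameter, gradient) array pairs (shared storage)."""
        return [pg for layer in self._all_layers() for pg in layer.params()]

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def get_state(self):
        """Copies of all parameters and normalisation buffers."""
        arrays = [p for p, _ in self.params()]
        for layer in self._all_layers():
            arrays += layer.buffers()
        return [a.copy() for a in arrays]

    def set_state(self, state):
        arrays = [p for p, _ in self.params()]
        for layer in self._all_layers():
            arrays += layer.buffers()
        if len(arrays) != len(state):
            raise ValueError("state does not match the architecture")
        for dst, src in zip(arrays, state):
            dst[...] = src

    def n_parameters(self):
        return int(sum(p.size for p, _ in self.params()))

    # -- forward / backward -------------------------------------------
    def forward(self, x, train: bool = True):
        """Logits of shape ``(B, n_classes, H, W)`` for input
        ``(B, in_channels, H, W)``."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (B, {self.in_channels}, H, W) input, "
                             f"got {x.shape}")
        h, w = x.shape[2:]
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError(f"spatial size {h}x{w} not divisible by "
                             f"2**depth={2 ** self.depth}")
        skips, self._pools = [], []
        for b1, b2 in self.enc:
            x = b2.forward(b1.forward(x, train), train)
            skips.append(x)
            pool = _MaxPool2()
            x = pool.forward(x)
            self._pools.append(pool)
        b1, b2 = self.bottleneck
        x = b2.forward(b1.forward(x, train), train)
        self._skip_channels = []
        for (b1, b2), skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = b2.forward(b1.forward(x, train), train)
        return self.head.forward(x)

    def backward(self, dlogits):
        """Backpropagate loss gradients; accumulates parameter gradients
        and returns the gradient w.r.t. the input."""
        dy = self.head.backward(dlogits)
        dskips = []
        for (b1, b2), cskip in zip(reversed(self.dec),
                                   reversed(self._skip_channels)):
            dy = b1.backward(b2.backward(dy))
            dskips.append(dy[:, :cskip])
            dy = _downgrad2(dy[:, cskip:])
        b1, b2 = self.bottleneck
        dy = b1.backward(b2.backward(dy))
        for (b1, b2), pool, dskip in zip(reversed(self.enc),
                                         reversed(self._pools),
                                         reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = b1.backward(b2.backward(dy))
        return dy


class Adam:
    """Adam optimizer over a network's (parameter, gradient) pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
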