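"""Layers and model blocks built on the autograd engine.

Initialisation follows the conventions used for the angiography models:
Xavier-uniform kernels everywhere, orthogonal recurrent weight matrices in the
LSTM, zero biases (forget-gate bias 1).
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, concatenate, conv2d, global_avg_pool,
                       global_max_pool, maxpool2d, stack)

__all__ = ["Module", "Dense", "Conv2d", "InceptionBlock", "InceptionBackbone",
           "BiLSTM", "MLP", "xavier_uniform", "orthogonal"]


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(xavier_uniform(rng, (n_in, n_out), n_in, n_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.w = Tensor(xavier_uniform(rng, (c_out, c_in, k, k), fan_in, fan_out),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class InceptionBlock(Module):
    """Parallel 1x1 / 3x3 / 5x5 convolution branches, concatenated
    channel-wise; the 5x5 branch is factorised into two stacked 3x3
    convolutions (same receptive field, fewer operations)."""

    def __init__(self, c_in: int, ch: int, rng: np.random.Generator):
        self.b1 = Conv2d(c_in, ch, 1, rng)
        self.b3 = Conv2d(c_in, ch, 3, rng)
        self.b5a = Conv2d(c_in, ch, 3, rng)
        self.b5b = Conv2d(ch, ch, 3, rng)
        self.c_out = 3 * ch

    def forward(self, x: Tensor) -> Tensor:
        return concatenate([self.b1(x).relu(), self.b3(x).relu(),
                            self.b5b(self.b5a(x).relu()).relu()], axis=1)


class InceptionBackbone(Module):
    """Inception-style classifier with taps before each pooling stage.

    Structure: stem conv -> [inception block -> 2x2 max pool] x depth ->
    global average pool -> dense logits. ``forward_features`` exposes the
    concatenated maps *before* each pool (used to build the detection pyramid)
    and the pooled embedding (fed to the recurrent frame selector).

    Parameters
    ----------
    width : channel multiplier; each inception block emits ``3 * width`` maps.
    depth : number of inception/pool stages (input size must be divisible by
        ``2 ** depth``).
    pool : global pooling of the last map — "avg", or "max" (suited to
        detecting a localized feature anywhere in the frame).
    """

    def __init__(self, n_out: int, rng: np.random.Generator, in_ch: int = 1,
                 width: int = 6, depth: int = 3, stem_stride: int = 1,
                 pool: str = "avg"):
        self.stem = Conv2d(in_ch, width, 3, rng, stride=stem_stride)
        self.blocks = []
        c = width
        for _ in range(depth):
            blk = InceptionBlock(c, width, rng)
            self.blocks.append(blk)
            c = blk.c_out
        self.feat_dim = c
        self.head = Dense(c, n_out, rng)
        self.depth = depth
        if pool not in ("avg", "max"):
            raise ValueError("pool must be 'avg' or 'max'")
        self.pool = pool

    def forward_features(self, x: Tensor):
        """Return (taps, embedding): per-stage pre-pool maps and pooled vector."""
        h = self.stem(x).relu()
        taps = []
        for blk in self.blocks:
            h = blk(h)
            taps.append(h)
            h = maxpool2d(h, 2)
        pooled = global_max_pool(h) if self.pool == "max" else global_avg_pool(h)
        return taps, pooled

    def forward(self, x: Tensor) -> Tensor:
        _, emb = self.forward_features(x)
        return self.head(emb)


class _LSTM(Module):
    """Single-direction LSTM over (B, T, D) inputs."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.wx = Tensor(xavier_uniform(rng, (n_in, 4 * hidden), n_in, 4 * hidden),
                         requires_grad=True)
        self.wh = Tensor(np.concatenate([orthogonal(rng, hidden) for _ in range(4)],
                                        axis=1), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0          # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def forward(self, x: Tensor, reverse: bool = False) -> list[Tensor]:
        n, t, _ = x.shape
        hd = self.hidden
        h = Tensor(np.zeros((n, hd)))
        c = Tensor(np.zeros((n, hd)))
        order = range(t - 1, -1, -1) if reverse else range(t)
        outs: list[Tensor | None] = [None] * t
        for step in order:
            gates = x[:, step, :] @ self.wx + h @ self.wh + self.b
            i = gates[:, 0 * hd:1 * hd].sigmoid()
            f = gates[:, 1 * hd:2 * hd].sigmoid()
            g = gates[:, 2 * hd:3 * hd].tanh()
            o = gates[:, 3 * hd:4 * hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[step] = h
        return outs


class BiLSTM(Module):
    """Bi-directional LSTM; per-step forward/backward states concatenated."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = _LSTM(n_in, hidden, rng)
        self.bwd = _LSTM(n_in, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        """(B, T, D) -> (B, T, 2 * hidden)."""
        hf = self.fwd(x, reverse=False)
        hb = self.bwd(x, reverse=True)
        steps = [concatenate([f, b], axis=1) for f, b in zip(hf, hb)]
        return stack(steps, axis=1)


class MLP(Module):
    """Dense -> relu -> Dense (one hidden layer)."""

    def __init__(self, n_in: int, hidden: int, n_out: int, rng: np.random.Generator):
        self.l1 = Dense(n_in, hidden, rng)
        self.l2 = Dense(hidden, n_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())
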