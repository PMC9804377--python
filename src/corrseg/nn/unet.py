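"""Residual group-normalized U-Net variant for corrective-annotation training.

The network is fully convolutional: five resolution levels on the way down
(2x2 max pooling between them), nearest-neighbour upsampling and skip
concatenation on the way up.  Down-blocks are residual and, from the second
block on, open with a 1x1 convolution that halves the incoming feature maps
before the 3x3 convolutions widen them again; up-blocks are residual with a
1x1 reduction after concatenation.  All 3x3 convolutions carry 1-px padding,
and the two-channel (background, foreground) logit map is finally cropped to
its central valid core, 36 px in from every side — so the output is always
``input - 72`` px per dimension, 572x572 in / 500x500 out in the canonical
configuration, with ~1.3 million trainable parameters.

Odd sizes are legal everywhere: pooling floors them and each up-block resizes
to its skip connection's exact shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import Conv2d, GroupNorm, MaxPool2, NearestResize, Param, ReLU

CONTEXT = 72  # total px lost to the valid-core crop (36 per side)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults are the canonical configuration: they satisfy the
    572 -> 500 geometry and land the trainable-parameter count at
    1.3 M (one decimal place).
    """

    in_channels: int = 3
    out_channels: int = 2
    down_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    up_widths: tuple[int, ...] = (96, 64, 48, 32)
    groupnorm_max_groups: int = 32
    input_size: int = 572   # canonical training/inference window
    output_size: int = 500  # = input_size - CONTEXT

    def __post_init__(self):
        if len(self.up_widths) != len(self.down_widths) - 1:
            raise ValueError("need one up-block per skip connection")
        if self.output_size != self.input_size - CONTEXT:
            raise ValueError("output_size must equal input_size - 72")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["down_widths"] = tuple(d["down_widths"])
        d["up_widths"] = tuple(d["up_widths"])
        return cls(**d)


class _DownBlock:
    """Residual block: optional pool, optional 1x1 channel halving, two 3x3 convs."""

    def __init__(self, c_in, c_out, rng, max_groups, pool, halve):
        self.pool = MaxPool2() if pool else None
        self.halve = halve
        mid_in = c_in
        self.layers = []
        if halve:
            mid_in = max(c_in // 2, 1)
            self.c1 = Conv2d(c_in, mid_in, 1, rng)
            self.n1 = GroupNorm(mid_in, max_groups)
            self.r1 = ReLU()
            self.layers += [self.c1, self.n1, self.r1]
        self.c2 = Conv2d(mid_in, c_out, 3, rng)
        self.n2 = GroupNorm(c_out, max_groups)
        self.r2 = ReLU()
        self.c3 = Conv2d(c_out, c_out, 3, rng)
        self.n3 = GroupNorm(c_out, max_groups)
        self.layers += [self.c2, self.n2, self.r2, self.c3, self.n3]
        self.proj = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None
        self.rout = ReLU()

    def params(self):
        ps = []
        for l in self.layers:
            ps += l.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=True):
        if self.pool is not None:
            x = self.pool.forward(x, train)
        y = x
        for l in self.layers:
            y = l.forward(y, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return self.rout.forward(y + s, train)

    def backward(self, dy):
        dy = self.rout.backward(dy)
        ds = dy if self.proj is None else self.proj.backward(dy)
        d = dy
        for l in reversed(self.layers):
            d = l.backward(d)
        d = d + ds
        if self.pool is not None:
            d = self.pool.backward(d)
        return d


class _UpBlock:
    """Residual block: upsample to the skip's size, concat, 1x1 reduce, 3x3 conv."""

    def __init__(self, c_below, c_skip, c_out, rng, max_groups):
        c_cat = c_below + c_skip
        self.resize = NearestResize()
        self.c1 = Conv2d(c_cat, c_out, 1, rng)
        self.n1 = GroupNorm(c_out, max_groups)
        self.r1 = ReLU()
        self.c2 = Conv2d(c_out, c_out, 3, rng)
        self.n2 = GroupNorm(c_out, max_groups)
        self.proj = Conv2d(c_cat, c_out, 1, rng)
        self.rout = ReLU()
        self.c_below = c_below

    def params(self):
        ps = []
        for l in (self.c1, self.n1, self.c2, self.n2, self.proj):
            ps += l.params()
        return ps

    def forward(self, below, skip, train=True):
        up = self.resize.forward(below, skip.shape[2], skip.shape[3], train)
        x = np.concatenate([up, skip], axis=1)
        y = self.r1.forward(self.n1.forward(self.c1.forward(x, train), train), train)
        y = self.n2.forward(self.c2.forward(y, train), train)
        s = self.proj.forward(x, train)
        return self.rout.forward(y + s, train)

    def backward(self, dy):
        dy = self.rout.backward(dy)
        dx = self.proj.backward(dy)
        d = self.n2.backward(dy)
        d = self.c2.backward(d)
        d = self.r1.backward(d)
        d = self.n1.backward(d)
        dx = dx + self.c1.backward(d)
        c = self.c_below
        d_below = self.resize.backward(dx[:, :c])
        d_skip = dx[:, c:]
        return d_below, d_skip


class UNet:
    """The full network; build with :func:`build_network` for seeded init."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        dw = config.down_widths
        mg = config.groupnorm_max_groups
        self.downs = []
        c_prev = config.in_channels
        for i, c in enumerate(dw):
            self.downs.append(
                _DownBlock(c_prev, c, rng, mg, pool=i > 0, halve=i > 0)
            )
            c_prev = c
        self.ups = []
        c_below = dw[-1]
        for skip_c, c_out in zip(reversed(dw[:-1]), config.up_widths):
            self.ups.append(_UpBlock(c_below, skip_c, c_out, rng, mg))
            c_below = c_out
        self.final = Conv2d(c_below, config.out_channels, 1, rng)
        self._in_shape = None

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        ps = []
        for b in self.downs + self.ups:
            ps += b.params()
        ps += self.final.params()
        return ps

    def num_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N,3,H,W) float32 in [0,1] -> (N,2,H-72,W-72) logits."""
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        x = np.ascontiguousarray(x)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N,{self.config.in_channels},H,W) input")
        h, w = x.shape[2], x.shape[3]
        if h <= CONTEXT or w <= CONTEXT:
            raise ValueError(f"input must exceed {CONTEXT} px in both dimensions")
        self._in_shape = x.shape
        skips = []
        y = x
        for b in self.downs:
            y = b.forward(y, train)
            skips.append(y)
        skips.pop()  # deepest level is not a skip
        for b in self.ups:
            y = b.forward(y, skips.pop(), train)
        y = self.final.forward(y, train)
        m = CONTEXT // 2
        return y[:, :, m : h - m, m : w - m]

    def backward(self, dlogits: np.ndarray) -> None:
        n, c, h, w = self._in_shape
        m = CONTEXT // 2
        full = np.zeros((n, self.config.out_channels, h, w), dtype=dlogits.dtype)
        full[:, :, m : h - m, m : w - m] = dlogits
        d = self.final.backward(full)
        nd = len(self.downs)
        skip_grad = [None] * (nd - 1)
        # ups[k] consumed the skip from downs[nd-2-k]
        for k in range(len(self.ups) - 1, -1, -1):
            d, ds = self.ups[k].backward(d)
            skip_grad[nd - 2 - k] = ds
        # d is now the gradient at the deepest down-block's output
        for i in range(nd - 1, 0, -1):
            g = self.downs[i].backward(d)
            d = g + skip_grad[i - 1]
        self.downs[0].backward(d)

    def forward_prob(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map, (N, H-72, W-72)."""
        z = self.forward(x, train=False)
        return softmax_fg(z)

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as z:
            cfg = NetworkConfig.from_json(bytes(z["__config__"]).decode())
            net = cls(cfg, np.random.default_rng(0))
            ps = net.params()
            keys = [k for k in z.files if k != "__config__"]
            if len(keys) != len(ps):
                raise ValueError("checkpoint incompatible with its stored config")
            for i, p in enumerate(ps):
                a = z[f"p{i}"]
                if a.shape != p.value.shape:
                    raise ValueError("checkpoint incompatible with its stored config")
                p.value[...] = a
        return net


def softmax_fg(logits: np.ndarray) -> np.ndarray:
    """Two-way softmax foreground probability; channel 1 is foreground."""
    from scipy.special import expit

    return expit(logits[:, 1] - logits[:, 0])


def build_network(
    config: NetworkConfig | None = None,
    init: str | object = "he",
    seed: int = 0,
) -> UNet:
    """Construct the network with He-initialized weights or from a checkpoint.

    ``init`` is either the string ``"he"`` (seeded random init) or a path to a
    saved checkpoint file.
    """
    config = config or NetworkConfig()
    if isinstance(init, str) and init == "he":
        return UNet(config, np.random.default_rng(seed))
    net = UNet.load(init)
    if net.config != config:
        raise ValueError("checkpoint config does not match the requested config")
    return net
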