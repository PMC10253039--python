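"""Network building blocks for the detector and grader architectures.

Alongside the stock YOLOv5-style blocks (Conv-BN-SiLU, bottleneck C3, SPPF)
this module implements the three architectural ideas the package is built
around:

* :class:`ODConv2d` — omni-dimensional dynamic convolution.  The effective
  kernel is an attention-weighted sum of ``n`` candidate kernels, with
  per-sample attention factors along four axes of kernel space: spatial
  (``alpha_s``, k x k), input channel (``alpha_c``), output channel
  (``alpha_f``) and kernel index (``alpha_w``).  All four factors are
  sigmoid-normalized outputs of a shared GAP -> FC -> ReLU trunk.
* :class:`GSConv` / :class:`VoVGSCSP` — the slim-neck pair: a dense
  convolution to half the output channels plus a depthwise complement,
  concatenated and channel-shuffled; and a cross-stage-partial block whose
  main path stacks two GSConv units.
* :class:`SwinBlockPair` — a window-attention / shifted-window-attention
  Swin Transformer block pair operating on a CNN feature map, with relative
  position bias and the standard cyclic-shift attention mask.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "LayerNorm",
    "ConvBNAct",
    "Bottleneck",
    "C3",
    "SPPF",
    "ODConv2d",
    "GSConv",
    "GSBottleneck",
    "VoVGSCSP",
    "SwinBlockPair",
    "Detect",
]


class Module:
    """Base class: parameter discovery, train/eval mode, counting."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        """Total number of trainable scalar parameters."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        w_shape = (c_out, c_in // groups, k, k)
        self.weight = Tensor(_kaiming(rng, w_shape, (c_in // groups) * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class ConvBNAct(Module):
    """Conv (no bias) -> BatchNorm -> SiLU, the standard YOLOv5 unit."""

    def __init__(self, c_in, c_out, k=1, stride=1, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class Bottleneck(Module):
    def __init__(self, c_in, c_out, shortcut=True, e=0.5, rng=None):
        super().__init__()
        c_ = int(c_out * e)
        self.cv1 = ConvBNAct(c_in, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(c_, c_out, 3, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage-partial block with ``n`` bottlenecks on the main path."""

    def __init__(self, c_in, c_out, n=1, shortcut=True, e=0.5, rng=None):
        super().__init__()
        c_ = int(c_out * e)
        self.cv1 = ConvBNAct(c_in, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(c_in, c_, 1, rng=rng)
        self.cv3 = ConvBNAct(2 * c_, c_out, 1, rng=rng)
        self.m = [Bottleneck(c_, c_, shortcut, e=1.0, rng=rng) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c_in, c_out, k=5, rng=None, conv_factory=None):
        super().__init__()
        make = conv_factory or (lambda a, b, kk: ConvBNAct(a, b, kk, rng=rng))
        c_ = c_in // 2
        self.cv1 = make(c_in, c_, 1)
        self.cv2 = make(c_ * 4, c_out, 1)
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = y.maxpool2d(self.k, 1, self.k // 2)
        p2 = p1.maxpool2d(self.k, 1, self.k // 2)
        p3 = p2.maxpool2d(self.k, 1, self.k // 2)
        return self.cv2(concat([y, p1, p2, p3], axis=1))


class ODConvAttention(Module):
    """GAP -> FC -> ReLU trunk with four sigmoid heads.

    Produces the four attention factors of omni-dimensional dynamic
    convolution, with shapes (k, k), (C_in,), (C_out,) and (n,) per sample.
    """

    def __init__(self, c_in, c_out, k, n, hidden, rng=None):
        super().__init__()
        self.k, self.n, self.c_in, self.c_out = k, n, c_in, c_out
        self.fc = Linear(c_in, hidden, rng=rng)
        self.head_s = Linear(hidden, k * k, rng=rng)
        self.head_c = Linear(hidden, c_in, rng=rng)
        self.head_f = Linear(hidden, c_out, rng=rng)
        self.head_w = Linear(hidden, n, rng=rng)

    def forward(self, x: Tensor):
        if x.shape[1] != self.c_in:
            raise ValueError(f"channel mismatch: got {x.shape[1]}, layer expects {self.c_in}")
        pooled = x.mean(axis=(2, 3))  # (N, C_in)
        z = self.fc(pooled).relu()
        alpha_s = self.head_s(z).sigmoid().reshape(x.shape[0], self.k, self.k)
        alpha_c = self.head_c(z).sigmoid()
        alpha_f = self.head_f(z).sigmoid()
        alpha_w = self.head_w(z).sigmoid()
        return alpha_s, alpha_c, alpha_f, alpha_w


class ODConv2d(Module):
    """Omni-dimensional dynamic convolution followed by BN + SiLU.

    The aggregated kernel for one sample is
    ``sum_i alpha_w[i] * (alpha_f ⊙ alpha_c ⊙ alpha_s ⊙ W_i)`` where each
    attention factor broadcasts along the axis it modulates; the sample is
    then convolved with that kernel.  Attention is computed per sample, so
    the batch is processed sample-by-sample.
    """

    def __init__(self, c_in, c_out, k, stride=1, n=4, hidden=None, reduction=4, act=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2
        self.k, self.n = k, n
        hidden = hidden if hidden is not None else max(c_in // reduction, 4)
        self.attention = ODConvAttention(c_in, c_out, k, n, hidden, rng=rng)
        bank = _kaiming(rng, (n, c_out, c_in, k, k), c_in * k * k)
        self.bank = Tensor(bank, requires_grad=True)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def aggregate_kernel(self, alpha_s, alpha_c, alpha_f, alpha_w) -> Tensor:
        """Materialize the attention-weighted kernel for one sample."""
        mod = (
            self.bank
            * alpha_f.reshape(1, -1, 1, 1, 1)
            * alpha_c.reshape(1, 1, -1, 1, 1)
            * alpha_s.reshape(1, 1, 1, self.k, self.k)
        )
        return (mod * alpha_w.reshape(self.n, 1, 1, 1, 1)).sum(axis=0)

    def forward(self, x: Tensor) -> Tensor:
        a_s, a_c, a_f, a_w = self.attention(x)
        outs = []
        for i in range(x.shape[0]):
            kernel = self.aggregate_kernel(a_s[i], a_c[i], a_f[i], a_w[i])
            outs.append(x[i : i + 1].conv2d(kernel, stride=self.stride, padding=self.padding))
        y = outs[0] if len(outs) == 1 else concat(outs, axis=0)
        y = self.bn(y)
        return y.silu() if self.act else y


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups: (N, g*c, H, W) -> permuted channels."""
    n, c, h, w = x.shape
    return x.reshape(n, groups, c // groups, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)


class GSConv(Module):
    """Half dense, half depthwise convolution with channel shuffle."""

    def __init__(self, c_in, c_out, k=1, stride=1, rng=None):
        super().__init__()
        if c_out % 2 != 0:
            raise ValueError(f"GSConv output channels must be even, got {c_out}")
        c_ = c_out // 2
        self.cv1 = ConvBNAct(c_in, c_, k, stride=stride, rng=rng)
        self.cv2 = ConvBNAct(c_, c_, 3, stride=1, groups=c_, rng=rng)  # depthwise complement

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        y2 = self.cv2(y1)
        return channel_shuffle(concat([y1, y2], axis=1), groups=2)


class GSBottleneck(Module):
    """Two stacked GSConv units (pointwise then 3x3)."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.gs1 = GSConv(c_in, c_in, 1, rng=rng)
        self.gs2 = GSConv(c_in, c_out, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.gs2(self.gs1(x))


class VoVGSCSP(Module):
    """Cross-stage-partial block whose main path is a GS bottleneck."""

    def __init__(self, c_in, c_out, e=0.5, rng=None):
        super().__init__()
        c_ = max(2, int(round(c_out * e / 2)) * 2)
        self.cv1 = ConvBNAct(c_in, c_, 1, rng=rng)
        self.cv2 = ConvBNAct(c_in, c_, 1, rng=rng)  # shortcut path
        self.gsb = GSBottleneck(c_, c_, rng=rng)
        self.cv3 = ConvBNAct(2 * c_, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cv3(concat([self.gsb(self.cv1(x)), self.cv2(x)], axis=1))


def _window_partition(x: Tensor, ws: int) -> Tensor:
    """(N, H, W, C) -> (N * nH * nW, ws*ws, C)."""
    n, h, w, c = x.shape
    x = x.reshape(n, h // ws, ws, w // ws, ws, c)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(n * (h // ws) * (w // ws), ws * ws, c)


def _window_merge(x: Tensor, ws: int, n: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(n, h // ws, w // ws, ws, ws, c)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


def swin_attention_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted windows.

    After a cyclic shift, tokens that originate from non-adjacent image
    regions share a window; pairs from different regions get -1e9 so softmax
    sends their attention weight to zero.  Shape: (num_windows, ws*ws, ws*ws).
    """
    img = np.zeros((h, w), dtype=np.int64)
    region = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for wsl in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, wsl] = region
            region += 1
    img = np.roll(img, (-shift, -shift), axis=(0, 1))
    wins = img.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3).reshape(-1, ws * ws)
    diff = wins[:, :, None] != wins[:, None, :]
    return np.where(diff, -1e9, 0.0).astype(np.float32)


class WindowAttention(Module):
    """Multi-head self-attention within windows, with relative position bias."""

    def __init__(self, dim, num_heads, window_size, rng=None):
        super().__init__()
        if dim % num_heads != 0:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.dim, self.num_heads, self.ws = dim, num_heads, window_size
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        n_rel = (2 * window_size - 1) ** 2
        self.rel_bias = Tensor(np.zeros((n_rel, num_heads), dtype=np.float32), requires_grad=True)
        coords = np.stack(np.meshgrid(np.arange(window_size), np.arange(window_size), indexing="ij"))
        flat = coords.reshape(2, -1)
        rel = flat[:, :, None] - flat[:, None, :] + window_size - 1
        self.rel_index = (rel[0] * (2 * window_size - 1) + rel[1]).astype(np.int64)

    def forward(self, x: Tensor, mask: np.ndarray | None = None, return_attn: bool = False):
        b, t, c = x.shape
        nh, hd = self.num_heads, c // self.num_heads
        qkv = self.qkv(x).reshape(b, t, 3, nh, hd).transpose(2, 0, 3, 1, 4)  # (3, B, nh, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale  # (B, nh, T, T)
        bias = self.rel_bias.take(self.rel_index.ravel()).reshape(t, t, nh).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, nh, t, t)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(b // nw, nw, nh, t, t) + Tensor(mask[None, :, None])
            attn = attn.reshape(b, nh, t, t)
        attn = attn.softmax(axis=-1)
        y = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        y = self.proj(y)
        if return_attn:
            return y, attn
        return y


class SwinSubBlock(Module):
    """One Swin sub-block: ``z + MSA(LN(z))`` then ``+ MLP(LN(.))``.

    ``shift = 0`` gives W-MSA; ``shift > 0`` gives SW-MSA with cyclic shift
    and region masking.
    """

    def __init__(self, dim, num_heads, window_size, shift, mlp_ratio=4.0, rng=None):
        super().__init__()
        if not (window_size > shift >= 0):
            raise ValueError(f"need window_size > shift >= 0, got ({window_size}, {shift})")
        self.ws, self.shift = window_size, shift
        self.ln1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window_size, rng=rng)
        self.ln2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)
        self._last_attn = None  # (B*, nh, T, T) of the most recent forward

    def forward(self, x: Tensor) -> Tensor:
        """``x``: token grid (N, H, W, C); H, W padded to the window size."""
        n, h, w, c = x.shape
        pad_h = (-h) % self.ws
        pad_w = (-w) % self.ws
        z = x
        if pad_h or pad_w:
            z = z.transpose(0, 3, 1, 2).pad2d((0, pad_h), (0, pad_w)).transpose(0, 2, 3, 1)
        hp, wp = h + pad_h, w + pad_w

        shortcut = z
        z = self.ln1(z)
        mask = None
        if self.shift:
            z = z.roll((-self.shift, -self.shift), axes=(1, 2))
            mask = swin_attention_mask(hp, wp, self.ws, self.shift)
        windows = _window_partition(z, self.ws)
        attended, attn = self.attn(windows, mask=mask, return_attn=True)
        self._last_attn = attn
        z = _window_merge(attended, self.ws, n, hp, wp)
        if self.shift:
            z = z.roll((self.shift, self.shift), axes=(1, 2))
        z = shortcut + z
        z = z + self.fc2(self.fc1(self.ln2(z)).silu())
        if pad_h or pad_w:
            z = z[:, :h, :w, :]
        return z


class SwinBlockPair(Module):
    """The canonical Swin unit: a W-MSA sub-block followed by SW-MSA."""

    def __init__(self, dim, num_heads, window_size=7, shift=3, mlp_ratio=4.0, rng=None):
        super().__init__()
        self.wmsa = SwinSubBlock(dim, num_heads, window_size, 0, mlp_ratio, rng=rng)
        self.swmsa = SwinSubBlock(dim, num_heads, window_size, shift, mlp_ratio, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """``x``: feature map (N, C, H, W); returns the same layout."""
        tokens = x.transpose(0, 2, 3, 1)
        tokens = self.swmsa(self.wmsa(tokens))
        return tokens.transpose(0, 3, 1, 2)


class Detect(Module):
    """YOLO-style heads: one 1x1 conv per scale -> (na * (5 + nc)) maps."""

    def __init__(self, num_classes: int, channels: tuple[int, ...], num_anchors: int = 3, rng=None):
        super().__init__()
        self.num_classes = num_classes
        self.num_anchors = num_anchors
        self.no = num_anchors * (5 + num_classes)
        self.heads = [Conv2d(c, self.no, 1, padding=0, rng=rng) for c in channels]

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        return [head(x) for head, x in zip(self.heads, xs)]
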