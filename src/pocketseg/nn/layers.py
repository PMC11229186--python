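"""Neural-network layers and the Adam optimizer built on the autodiff engine.

All activation tensors are channels-last: (N, D, H, W, C) for volumetric
blocks and (N, T, E) for token sequences inside the attention layer.
Weights use fan-in-scaled (He) initialisation from a caller-supplied
``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import engine as E
from .engine import Tensor


class Module:
    """Minimal parameter container; submodules are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class PReLU(Module):
    """Per-channel parametric ReLU, slope initialised at 0.25."""

    def __init__(self, channels: int):
        self.alpha = Tensor(np.full(channels, 0.25, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return E.prelu(x, self.alpha)


class Conv3dSame(Module):
    """Odd-kernel, stride-1, same-padded 3-D convolution."""

    def __init__(self, rng, cin: int, cout: int, kernel: int = 5):
        if kernel % 2 != 1:
            raise ValueError("same-padded conv needs an odd kernel")
        self.w = _he_init(rng, (kernel, kernel, kernel, cin, cout), kernel**3 * cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return E.conv3d_same(x, self.w, self.b)


class DownConv(Module):
    """Strided downsampling convolution, kernel == stride (default 2x2x2)."""

    def __init__(self, rng, cin: int, cout: int, factors=(2, 2, 2)):
        self.factors = tuple(factors)
        fz, fy, fx = self.factors
        self.w = _he_init(rng, (fz, fy, fx, cin, cout), fz * fy * fx * cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return E.conv3d_down(x, self.w, self.b, self.factors)


class UpConv(Module):
    """Transpose convolution, kernel == stride (block upsampling)."""

    def __init__(self, rng, cin: int, cout: int, factors=(2, 2, 2)):
        self.factors = tuple(factors)
        fz, fy, fx = self.factors
        self.w = _he_init(rng, (fz, fy, fx, cin, cout), cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return E.conv3d_up(x, self.w, self.b, self.factors)


class Linear(Module):
    def __init__(self, rng, nin: int, nout: int, bias: bool = True):
        self.w = _he_init(rng, (nin, nout), nin)
        self.b = Tensor(np.zeros(nout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = E.matmul(x, self.w)
        return y if self.b is None else y + self.b


class MultiHeadAttention(Module):
    """Scaled dot-product multi-head self-attention.

    Per head i with head width d_k = E/h:
        head_i = softmax(Q_i K_i^T / sqrt(d_k)) V_i,  Q_i = X Wq_i, ...
    Heads are concatenated and passed through a final linear map.  The
    projections are bias-free linear maps, matching the plain formulation.
    """

    def __init__(self, rng, embed: int, heads: int):
        if embed % heads != 0:
            raise ValueError(f"embedding width {embed} not divisible by {heads} heads")
        self.embed = embed
        self.heads = heads
        self.d_k = embed // heads
        self.wq = Linear(rng, embed, embed, bias=False)
        self.wk = Linear(rng, embed, embed, bias=False)
        self.wv = Linear(rng, embed, embed, bias=False)
        self.wo = Linear(rng, embed, embed, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.embed:
            raise ValueError(
                f"token width {x.shape[-1]} does not match attention width {self.embed}"
            )
        lead = x.shape[:-2]
        t = x.shape[-2]
        q = self._split(self.wq(x), lead, t)
        k = self._split(self.wk(x), lead, t)
        v = self._split(self.wv(x), lead, t)
        scores = E.matmul(q, transpose_last(k)) * (1.0 / np.sqrt(self.d_k))
        attn = E.softmax(scores, axis=-1)
        ctx = E.matmul(attn, v)  # (..., h, T, d_k)
        merged = self._merge(ctx, lead, t)
        return self.wo(merged)

    def _split(self, x: Tensor, lead, t) -> Tensor:
        x = E.reshape(x, (*lead, t, self.heads, self.d_k))
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return E.transpose(x, axes)

    def _merge(self, x: Tensor, lead, t) -> Tensor:
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        x = E.transpose(x, axes)
        return E.reshape(x, (*lead, t, self.embed))


def transpose_last(x: Tensor) -> Tensor:
    axes = list(range(x.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return E.transpose(x, tuple(axes))


class FormerLayer3D(Module):
    """Hybrid global-context layer: 1x1x1 convolution + multi-head self-attention.

    The volumetric block is first mixed channel-wise by a 1x1x1 convolution,
    then flattened so every voxel becomes one token (channels as the
    embedding), passed through self-attention over all positions, reshaped
    back, and added residually to the layer input.
    """

    def __init__(self, rng, channels: int, heads: int):
        self.conv = Conv3dSame(rng, channels, channels, kernel=1)
        self.attn = MultiHeadAttention(rng, channels, heads)

    def __call__(self, x: Tensor) -> Tensor:
        n, d, h, w, c = x.shape
        y = self.conv(x)
        tokens = E.reshape(y, (n, d * h * w, c))
        tokens = self.attn(tokens)
        y = E.reshape(tokens, (n, d, h, w, c))
        return x + y


class Adam:
    """Adam with bias correction; state is exposed for exact checkpoint/resume."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "lr": self.lr,
        }

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float32) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float32) for v in state["v"]]
        self.lr = float(state["lr"])
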