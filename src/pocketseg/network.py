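"""Dual-path volumetric segmentation network for binding-pocket prediction.

The architecture couples two encoder pathways over the same voxel grid:

* a deep **V path** (V-Net style): per-stage stacks of 5x5x5 convolutions with
  PReLU and stage-internal residual additions, downsampled between stages by
  strided convolutions that double the channel width;
* a shallow **L path**: a single convolution per stage, intended to carry
  global information through far fewer nonlinear local mixings.

At a configurable middle stage each path runs a hybrid global-context layer
(1x1x1 convolution + multi-head self-attention over all voxel positions,
:class:`~pocketseg.nn.layers.FormerLayer3D`), after which the V-path tensor is
concatenated into the L path (one-way information exchange).  The two encoder
outputs are concatenated at the lowest resolution and decoded by transpose
convolutions with concatenated V-path skip tensors, ending in a 1x1x1
convolution + sigmoid that yields a per-voxel pocket probability.

Odd grid sides are supported: strided downsampling floors odd extents and the
decoder zero-pads each upsampled block back to its skip tensor's size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .nn import engine as E
from .nn.engine import Tensor
from .nn.layers import (
    Adam,  # noqa: F401  (re-exported for training)
    Conv3dSame,
    DownConv,
    FormerLayer3D,
    Module,
    PReLU,
    UpConv,
)


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``former_stage`` indexes the encoder stage (0-based, by number of
    downsamplings before it) after whose convolutions the attention layers
    sit; ``None`` places them at the middle stage.  ``down_factors`` is the
    per-axis kernel-and-stride of the downsampling convolutions; (2, 2, 2)
    preserves cubic symmetry, (2, 2, 1) is available as a variant.
    """

    grid_side: int = 36
    in_channels: int = 18
    base_width: int = 16
    n_stages: int = 4
    attention_heads: int = 4
    former_stage: int | None = None
    down_factors: tuple[int, int, int] = (2, 2, 2)
    stage_convs: tuple[int, ...] | None = None
    seed: int = 0

    def resolved_former_stage(self) -> int:
        return self.n_stages // 2 if self.former_stage is None else self.former_stage

    def resolved_stage_convs(self) -> tuple[int, ...]:
        if self.stage_convs is not None:
            if len(self.stage_convs) != self.n_stages + 1:
                raise ConfigError(
                    f"stage_convs needs {self.n_stages + 1} entries, got {len(self.stage_convs)}"
                )
            return tuple(self.stage_convs)
        return tuple(min(s + 1, 3) for s in range(self.n_stages + 1))

    def widths(self) -> list[int]:
        return [self.base_width * 2**s for s in range(self.n_stages + 1)]

    def validate(self):
        if self.grid_side < 2:
            raise ConfigError("grid_side must be >= 2")
        if self.n_stages < 1:
            raise ConfigError("n_stages must be >= 1")
        fs = self.resolved_former_stage()
        if not 0 <= fs <= self.n_stages:
            raise ConfigError(f"former_stage {fs} outside stages 0..{self.n_stages}")
        spatial = [self.grid_side] * 3
        for s in range(self.n_stages):
            spatial = [dim // f for dim, f in zip(spatial, self.down_factors)]
            if min(spatial) < 1:
                raise ConfigError(
                    f"stage {s + 1}: grid side {self.grid_side} collapses below one "
                    f"voxel after {s + 1} downsamplings"
                )
        w_fs = self.widths()[fs]
        if w_fs % self.attention_heads != 0:
            raise ConfigError(
                f"embedding width {w_fs} at former stage {fs} not divisible by "
                f"{self.attention_heads} attention heads"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["down_factors"] = list(self.down_factors)
        if d["stage_convs"] is not None:
            d["stage_convs"] = list(d["stage_convs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["down_factors"] = tuple(d.get("down_factors", (2, 2, 2)))
        if d.get("stage_convs") is not None:
            d["stage_convs"] = tuple(d["stage_convs"])
        return cls(**d)


class ResStage(Module):
    """Stack of same-padded 5x5x5 conv+PReLU with a residual addition.

    When the input width differs from the stage width the residual branch is
    a 1x1x1 projection convolution.
    """

    def __init__(self, rng, cin: int, width: int, depth: int, kernel: int = 5):
        self.convs = [Conv3dSame(rng, cin if i == 0 else width, width, kernel) for i in range(depth)]
        self.acts = [PReLU(width) for _ in range(depth)]
        self.proj = Conv3dSame(rng, cin, width, kernel=1) if cin != width else None

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act(conv(h))
        res = x if self.proj is None else self.proj(x)
        return h + res


class DualPathVNet(Module):
    """The full encoder(-exchange)-decoder graph. Use :func:`build_model`."""

    def __init__(self, config: NetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.widths()
        depths = config.resolved_stage_convs()
        ns = config.n_stages
        fs = config.resolved_former_stage()
        f = config.down_factors

        # V path
        self.v_stages = [
            ResStage(rng, config.in_channels if s == 0 else w[s], w[s], depths[s])
            for s in range(ns + 1)
        ]
        self.v_downs = [DownConv(rng, w[s], w[s + 1], f) for s in range(ns)]
        self.v_down_acts = [PReLU(w[s + 1]) for s in range(ns)]
        self.former_v = FormerLayer3D(rng, w[fs], config.attention_heads)

        # L path: one conv per stage + shared-geometry downsampling
        self.l_convs = [
            Conv3dSame(rng, config.in_channels if s == 0 else w[s], w[s], 5)
            for s in range(ns + 1)
        ]
        self.l_acts = [PReLU(w[s]) for s in range(ns + 1)]
        self.l_downs = [DownConv(rng, w[s], w[s + 1], f) for s in range(ns)]
        self.l_down_acts = [PReLU(w[s + 1]) for s in range(ns)]
        self.former_l = FormerLayer3D(rng, w[fs], config.attention_heads)
        # mixes the exchanged (concatenated) tensor back to the stage width
        self.l_mix = Conv3dSame(rng, 2 * w[fs], w[fs], kernel=1)

        # decoder
        self.ups = []
        self.up_acts = []
        self.d_stages = []
        cur = 2 * w[ns]  # fused encoder output
        for s in reversed(range(ns)):
            self.ups.append(UpConv(rng, cur, w[s], f))
            self.up_acts.append(PReLU(w[s]))
            self.d_stages.append(ResStage(rng, 2 * w[s], w[s], depths[s]))
            cur = w[s]
        self.head = Conv3dSame(rng, w[0], 1, kernel=1)

    # ------------------------------------------------------------------ forward
    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        cfg = self.config
        if x.ndim != 5 or x.shape[1:4] != (cfg.grid_side,) * 3 or x.shape[4] != cfg.in_channels:
            raise ConfigError(
                f"input shape {x.shape} does not match (N, {cfg.grid_side}^3, {cfg.in_channels})"
            )
        ns = cfg.n_stages
        fs = cfg.resolved_former_stage()

        # V path
        v = x
        skips: list[Tensor] = []
        v_exchange = None
        for s in range(ns + 1):
            v = self.v_stages[s](v)
            if s == fs:
                v = self.former_v(v)
                v_exchange = v
            if s < ns:
                skips.append(v)
                v = self.v_down_acts[s](self.v_downs[s](v))

        # L path (receives the V-path tensor after both attention layers)
        l = x
        for s in range(ns + 1):
            l = self.l_acts[s](self.l_convs[s](l))
            if s == fs:
                l = self.former_l(l)
                l = E.concat([l, v_exchange], axis=-1)
                l = self.l_mix(l)
            if s < ns:
                l = self.l_down_acts[s](self.l_downs[s](l))

        # fusion + decoder
        u = E.concat([v, l], axis=-1)
        for i, s in enumerate(reversed(range(ns))):
            u = self.up_acts[i](self.ups[i](u))
            u = E.pad_spatial(u, skips[s].shape[1:4])
            u = E.concat([u, skips[s]], axis=-1)
            u = self.d_stages[i](u)
        logits = self.head(u)
        return E.sigmoid(logits)

    # ------------------------------------------------------------- persistence
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ConfigError(
                f"checkpoint has {len(arrays)} parameter arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float32)
            if a.shape != p.data.shape:
                raise ConfigError(f"parameter shape mismatch: {a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(config: NetConfig | None = None) -> DualPathVNet:
    """Construct the network from a validated config (seeded, reproducible)."""
    return DualPathVNet(config or NetConfig())


def predict(model: DualPathVNet, grid) -> "ProbGrid":
    """Deterministic forward pass on one feature grid -> probability grid."""
    from .grids import ProbGrid  # local import to avoid a cycle

    x = grid.values[None].astype(np.float32)
    out = model(x)
    probs = np.asarray(out.data[0, ..., 0], dtype=np.float32)
    # sigmoid output is in (0,1); clip guards exact float32 saturation
    probs = np.clip(probs, np.float32(1e-7), np.float32(1.0 - 1e-7))
    return ProbGrid(values=probs, origin=grid.origin.copy(), spacing=grid.spacing)
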