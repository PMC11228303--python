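"""The fusion network's architectural blocks.

``SeqResBlock`` is a residual unit that 1x1-reduces the input to 15
channels, splits them into five 3-channel subspaces F0..F4 processed by a
*hierarchically increasing* number of factorized (3x1 then 1x3)
convolution stages — F0 passes through untouched, F1 gets one plain
factorized stage, F2..F4 get 2..4 stages whose stages beyond the first
are depthwise-separable (per-channel 3x1/1x3 followed by a 1x1 pointwise
mix) — then concatenates the subspaces, 1x1-restores the original channel
count, and adds the identity shortcut.  With all conv weights zero the
block is exactly the identity.

``UpsampleModule`` / ``DownsampleModule`` are back-projection style
resamplers built from transpose convolutions (kernel 2, stride 2): the
first projection produces the resampled map, a reverse projection
reconstructs the input scale, and the reconstruction residual is
projected again and merged (concat + 1x1) with the first projection.
Spatial dims are exactly doubled / halved, channels preserved.

``FusionNet`` stacks Seq-ResNet stages with downsampling between them,
one upsampling stage before global pooling, and an FC head that exposes
the penultimate ``fc_dim``-dimensional deep feature vector used for
fusion with radiomics features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .layers import (BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module,
                     ReLU, Sequential)

__all__ = ["SeqResBlock", "UpsampleModule", "DownsampleModule",
           "FusionNetConfig", "FusionNet", "count_parameters",
           "PlainResidualBlock"]


def count_parameters(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())


class _FactorizedStage(Module):
    """One 3x3-equivalent stage factorized as 3x1 then 1x3, each followed
    by BN + ReLU; ``depthwise=True`` makes the spatial convs per-channel
    with a trailing 1x1 pointwise mix."""

    def __init__(self, channels: int, depthwise: bool = False):
        super().__init__()
        groups = channels if depthwise else 1
        layers = [
            Conv2d(channels, channels, (3, 1), padding=(1, 0), groups=groups, bias=False),
            Conv2d(channels, channels, (1, 3), padding=(0, 1), groups=groups, bias=False),
        ]
        if depthwise:
            layers.append(Conv2d(channels, channels, 1, bias=False))
        layers += [BatchNorm2d(channels), ReLU()]
        self.body = Sequential(*layers)

    def forward(self, x):
        return self.body(x)


class SeqResBlock(Module):
    """Sequential residual block; output channels equal input channels."""

    def __init__(self, in_channels: int, reduced_channels: int = 15,
                 n_subspaces: int = 5):
        super().__init__()
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if reduced_channels % n_subspaces:
            raise ValueError("reduced_channels must be divisible by n_subspaces")
        self.in_channels = in_channels
        self.n_subspaces = n_subspaces
        self.sub_channels = reduced_channels // n_subspaces
        self.reduce = Sequential(
            Conv2d(in_channels, reduced_channels, 1, bias=False),
            BatchNorm2d(reduced_channels), ReLU())
        # subspace j undergoes j factorized stages; stages beyond the first
        # are depthwise-separable
        self.branches = Sequential(*[
            Sequential(*[_FactorizedStage(self.sub_channels, depthwise=(s > 0))
                         for s in range(j)])
            for j in range(n_subspaces)
        ])
        self.restore = Conv2d(reduced_channels, in_channels, 1, bias=False)
        self.restore_bn = BatchNorm2d(in_channels)

    def forward(self, x):
        r = self.reduce(x)
        parts = []
        for j, branch in enumerate(self.branches.layers):
            sub = ag.narrow(r, 1, j * self.sub_channels, self.sub_channels)
            parts.append(branch(sub))
        merged = self.restore_bn(self.restore(ag.concat(parts, axis=1)))
        return ag.add(x, merged)


class PlainResidualBlock(Module):
    """Reference residual block (two 3x3 convs) for parameter-count
    comparisons against :class:`SeqResBlock`."""

    def __init__(self, channels: int):
        super().__init__()
        self.body = Sequential(
            Conv2d(channels, channels, 3, padding=1, bias=False),
            BatchNorm2d(channels), ReLU(),
            Conv2d(channels, channels, 3, padding=1, bias=False),
            BatchNorm2d(channels))

    def forward(self, x):
        return ag.add(x, self.body(x))


class UpsampleModule(Module):
    """Back-projection upsampler: doubles H and W, preserves channels."""

    def __init__(self, channels: int, bias: bool = False):
        super().__init__()
        self.project_up = ConvTranspose2d(channels, channels, 2, stride=2, bias=bias)
        self.project_back = Conv2d(channels, channels, 2, stride=2, bias=bias)
        self.residual_up = ConvTranspose2d(channels, channels, 2, stride=2, bias=bias)
        self.merge = Conv2d(2 * channels, channels, 1, bias=bias)

    def forward(self, x):
        hi1 = self.project_up(x)          # LowRes1 -> HiRes1
        lo2 = self.project_back(hi1)      # HiRes1 -> LowRes2
        res = ag.sub(lo2, x)              # back-projection residual
        hi_res = self.residual_up(res)
        return self.merge(ag.concat([hi1, hi_res], axis=1))


class DownsampleModule(Module):
    """Mirror of :class:`UpsampleModule`: halves H and W (must be even)."""

    def __init__(self, channels: int, bias: bool = False):
        super().__init__()
        self.project_down = Conv2d(channels, channels, 2, stride=2, bias=bias)
        self.project_back = ConvTranspose2d(channels, channels, 2, stride=2, bias=bias)
        self.residual_down = Conv2d(channels, channels, 2, stride=2, bias=bias)
        self.merge = Conv2d(2 * channels, channels, 1, bias=bias)

    def forward(self, x):
        h, w = x.data.shape[2:]
        if h % 2 or w % 2:
            raise ValueError(f"downsampling requires even spatial dims, got {(h, w)}")
        lo1 = self.project_down(x)
        hi2 = self.project_back(lo1)
        res = ag.sub(hi2, x)
        lo_res = self.residual_down(res)
        return self.merge(ag.concat([lo1, lo_res], axis=1))


@dataclass(frozen=True)
class FusionNetConfig:
    """Architecture plan.

    ``stage_blocks`` Seq-ResNet blocks per resolution stage (default sums
    to the canonical 37); ``stage_channels`` the width per stage;
    ``depth_scale`` < 1 shrinks every stage's block count (floor 1) for
    desk-scale runs with identical topology.
    """

    in_channels: int = 5
    n_classes: int = 2
    stage_blocks: tuple[int, ...] = (6, 8, 12, 8, 3)
    stage_channels: tuple[int, ...] = (32, 64, 96, 96, 64)
    fc_dim: int = 256
    depth_scale: float = 1.0

    def __post_init__(self):
        if len(self.stage_blocks) != len(self.stage_channels):
            raise ValueError("stage_blocks and stage_channels length mismatch")
        if not 0.0 < self.depth_scale <= 1.0:
            raise ValueError("depth_scale must be in (0, 1]")
        if any(b < 1 for b in self.stage_blocks):
            raise ValueError("every stage needs >= 1 block")

    def scaled_blocks(self) -> tuple[int, ...]:
        return tuple(max(1, round(b * self.depth_scale)) for b in self.stage_blocks)


class FusionNet(Module):
    """Seq-ResNet encoder with back-projection resampling and an FC head.

    forward(x) -> (logits, deep_features); ``n_seqres_blocks`` reports the
    instantiated block count.
    """

    def __init__(self, config: FusionNetConfig | None = None, **overrides):
        super().__init__()
        if config is None:
            config = FusionNetConfig(**overrides)
        elif overrides:
            raise ValueError("pass either a config or keyword overrides, not both")
        self.config = config
        blocks = config.scaled_blocks()
        widths = config.stage_channels
        self.stem = Sequential(
            Conv2d(config.in_channels, widths[0], 3, padding=1, bias=False),
            BatchNorm2d(widths[0]), ReLU())
        stages = []
        for i, (n, w) in enumerate(zip(blocks, widths)):
            stage = [SeqResBlock(w) for _ in range(n)]
            if i + 1 < len(blocks):
                stage.append(DownsampleModule(w))
                if widths[i + 1] != w:
                    stage += [Conv2d(w, widths[i + 1], 1, bias=False),
                              BatchNorm2d(widths[i + 1]), ReLU()]
            stages.append(Sequential(*stage))
        self.stages = Sequential(*stages)
        self.upsample = UpsampleModule(widths[-1])
        self.fc = Linear(widths[-1], config.fc_dim)
        self.head = Linear(config.fc_dim, config.n_classes)
        self.n_seqres_blocks = sum(blocks)

    def forward(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(x)
        h = self.stem(x)
        h = self.stages(h)
        h = self.upsample(h)
        pooled = ag.global_avg_pool(h)
        features = ag.relu(self.fc(pooled))
        logits = self.head(features)
        return logits, features
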