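"""Segmentation network architectures: U-Net, U-Net++, attention-gated U-Net++.

All models map an (N, C, S, S) input to an (N, 1, S, S) logit map.  The
encoder uses ``depth`` consecutive 2x2 max-pool down-samplings; decoders
up-sample bilinearly and merge skip features by channel concatenation.  The
attention variant inserts one :class:`~pterymeter.nn.layers.AttentionGate`
before each up-sampling step of every nested decoder node, gating the
concatenated skip features with the coarser feature map that is about to be
up-sampled.  Deep supervision is not used: the top-level node of the last
nested column is the prediction head's input.
"""

from __future__ import annotations

import numpy as np

from .layers import AttentionGate, Conv2d, ConvBlock, Module
from .tensor import Tensor, concat, max_pool2, upsample2

__all__ = ["UNet", "UNetPP"]


class UNet(Module):
    def __init__(self, in_channels: int = 3, base_channels: int = 16,
                 depth: int = 4, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        ch = [base_channels * 2**i for i in range(depth + 1)]
        self.depth = depth
        self.encoders = [ConvBlock(in_channels if i == 0 else ch[i - 1], ch[i],
                                   rng, dtype) for i in range(depth + 1)]
        self.decoders = [ConvBlock(ch[i + 1] + ch[i], ch[i], rng, dtype)
                         for i in reversed(range(depth))]
        self.head = Conv2d(ch[0], 1, 1, rng, dtype)

    def __call__(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        feats = []
        for i, enc in enumerate(self.encoders):
            if i > 0:
                x = max_pool2(x)
            x = enc(x)
            feats.append(x)
        y = feats[-1]
        for k, dec in enumerate(self.decoders):
            skip = feats[self.depth - 1 - k]
            y = dec(concat([skip, upsample2(y, "bilinear")], axis=1))
        return self.head(y)


class UNetPP(Module):
    """Nested U-Net with dense skip pathways, optionally attention-gated.

    Node ``X[i][j]`` (level ``i``, column ``j``) receives the concatenation
    of all same-level predecessors ``X[i][0..j-1]`` and the up-sampled
    ``X[i+1][j-1]``.  With ``attention=True`` the same-level concatenation is
    first reweighted by an attention gate whose gating signal is
    ``X[i+1][j-1]`` (half the spatial size, per the gate contract).
    """

    def __init__(self, in_channels: int = 3, base_channels: int = 16,
                 depth: int = 4, attention: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        ch = [base_channels * 2**i for i in range(depth + 1)]
        self.depth = depth
        self.attention = attention
        self.encoders = [ConvBlock(in_channels if i == 0 else ch[i - 1], ch[i],
                                   rng, dtype) for i in range(depth + 1)]
        # blocks[i][j-1] computes X[i][j]; gates[i][j-1] gates its skip concat
        self.blocks: list[list[ConvBlock]] = []
        self.gates: list[list[AttentionGate]] = []
        for i in range(depth):
            row_b, row_g = [], []
            for j in range(1, depth - i + 1):
                row_b.append(ConvBlock(j * ch[i] + ch[i + 1], ch[i], rng, dtype))
                if attention:
                    f_l = j * ch[i]
                    row_g.append(AttentionGate(ch[i + 1], f_l, max(f_l // 2, 1),
                                               rng, dtype))
            self.blocks.append(row_b)
            self.gates.append(row_g)
        self.head = Conv2d(ch[0], 1, 1, rng, dtype)

    def set_force_alpha(self, value: float | None):
        for row in self.gates:
            for gate in row:
                gate.force_alpha = value

    def __call__(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        grid: dict[tuple[int, int], Tensor] = {}
        h = x
        for i, enc in enumerate(self.encoders):
            if i > 0:
                h = max_pool2(h)
            h = enc(h)
            grid[(i, 0)] = h
        for j in range(1, self.depth + 1):
            for i in range(self.depth + 1 - j):
                below = grid[(i + 1, j - 1)]
                skips = concat([grid[(i, jj)] for jj in range(j)], axis=1)
                if self.attention:
                    skips = self.gates[i][j - 1](skips, below)
                merged = concat([skips, upsample2(below, "bilinear")], axis=1)
                grid[(i, j)] = self.blocks[i][j - 1](merged)
        return self.head(grid[(0, self.depth)])
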