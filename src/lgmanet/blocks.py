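"""The network's building blocks.

Three stage types appear in the encoder-decoder:

* :class:`Lgipb` — the local-global information processing block, a densely
  connected four-convolution unit whose inner channel trace is
  12 -> 12 -> 24 -> 48 regardless of its input width.
* :class:`Emra` — efficient multi-scale reconstruction attention: ECA-style
  channel attention with an adaptively sized 1-D kernel, followed by
  parallel 1/3/5/7 convolutions, concatenation to 4*C_in channels and a
  1x1 fusion convolution.
* :class:`ShiftedMlpBlock` — a tokenized MLP with axial channel-group
  shifting and a depthwise 3x3 convolution between the two projections.

All blocks preserve the spatial size of their input exactly.
"""

from __future__ import annotations

import math

from . import nn
from .config import EmraConfig, LgipbConfig, ShiftedMlpConfig
from .nn import Tensor


def eca_kernel_size(c: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size for channel attention.

    ``t = floor(|log2(c) + b| / gamma)``; the kernel is ``t`` when odd and
    ``t + 1`` when even, clamped to a minimum of 1 so the convolution is
    always defined.
    """
    if c < 1:
        raise ValueError(f"channel count must be positive, got {c}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    t = math.floor(abs(math.log2(c) + b) / gamma)
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


class _ConvBnPrelu(nn.Module):
    """3x3 convolution -> batch norm -> channelwise PReLU (same padding)."""

    def __init__(self, cin: int, cout: int, prelu_init: float):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.PReLU(cout, prelu_init)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class Lgipb(nn.Module):
    """Densely connected local-global information processing block.

    The first convolution is bare (no normalisation or activation); each of
    the following convolutions consumes the concatenation of every earlier
    dense feature and is wrapped in batch norm + PReLU. With the default
    inner widths the intermediates carry 12, 12, 24 and 48 channels.
    """

    def __init__(self, cfg: LgipbConfig):
        super().__init__()
        self.cfg = cfg
        w1, w2, w3 = cfg.inner_widths
        self.conv1 = nn.Conv2d(cfg.in_channels, w1, 3, bias=True)
        self.stage2 = _ConvBnPrelu(w1, w2, cfg.prelu_init)
        self.stage3 = _ConvBnPrelu(w1 + w2, w3, cfg.prelu_init)
        self.stage4 = _ConvBnPrelu(w1 + w2 + w3, cfg.dense_width, cfg.prelu_init)
        self.stage_out = _ConvBnPrelu(cfg.dense_width, cfg.out_channels, cfg.prelu_init)

    def forward(self, x: Tensor) -> Tensor:
        out, _ = self.forward_trace(x)
        return out

    def forward_trace(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Forward pass that also returns the dense intermediates x1..x4."""
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"LGIPB expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        x1 = self.conv1(x)
        x2 = self.stage2(x1)
        x3 = self.stage3(nn.concat([x1, x2], axis=1))
        x4 = self.stage4(nn.concat([x1, x2, x3], axis=1))
        out = self.stage_out(x4)
        return out, [x1, x2, x3, x4]


class Emra(nn.Module):
    """Efficient multi-scale reconstruction attention.

    Channel attention (global average pool -> adaptive-kernel 1-D
    convolution -> sigmoid) reweights the input; four parallel square
    convolutions then extract features at receptive fields 1/3/5/7, are
    concatenated to ``len(kernel_sizes) * C_in`` channels and fused back to
    ``C_out`` by a 1x1 convolution.
    """

    def __init__(self, cfg: EmraConfig):
        super().__init__()
        self.cfg = cfg
        self.k1d = eca_kernel_size(cfg.in_channels, cfg.gamma, cfg.b)
        # bias-free 1-D kernel over the pooled channel descriptor
        from .nn.modules import _kaiming
        self.attn_weight = Tensor(_kaiming((self.k1d,), self.k1d), requires_grad=True)
        self.branches = nn.Sequential(*[
            nn.Conv2d(cfg.in_channels, cfg.in_channels, k, bias=True)
            for k in cfg.kernel_sizes
        ])
        self.fuse = nn.Conv2d(len(cfg.kernel_sizes) * cfg.in_channels, cfg.out_channels, 1)

    def attention(self, x: Tensor) -> Tensor:
        """Channel-attention weights with shape (B, C, 1, 1), each in (0, 1)."""
        desc = nn.global_avg_pool(x)                       # (B, C)
        desc = nn.conv1d_channel(desc, self.attn_weight)   # (B, C)
        w = nn.sigmoid(desc)
        b, c = w.shape
        return w.reshape(b, c, 1, 1)

    def multi_scale(self, x: Tensor) -> Tensor:
        """The attention-free path: parallel convolutions, concat, 1x1 fuse."""
        feats = [branch(x) for branch in self.branches.layers]
        return self.fuse(nn.concat(feats, axis=1))

    def forward(self, x: Tensor, apply_attention: bool = True) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"EMRA expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if apply_attention:
            x = nn.mul(x, self.attention(x))
        return self.multi_scale(x)


class ShiftedMlpBlock(nn.Module):
    """Tokenized shifted-MLP block with a residual connection.

    Tokens are the spatial positions; the block is
    ``x + fc2(shift_H(drop(gelu(dwconv(fc1(shift_W(LN(x))))))))`` with the
    channel groups shifted by -2..2 pixels along one spatial axis before
    each projection. Token dimensionality (and hence the feature-map shape)
    is preserved end to end.
    """

    def __init__(self, cfg: ShiftedMlpConfig, drop_seed: int = 0):
        super().__init__()
        self.cfg = cfg
        hidden = max(int(cfg.channels * cfg.expansion), 1)
        self.hidden = hidden
        self.norm = nn.LayerNorm(cfg.channels)
        self.fc1 = nn.Linear(cfg.channels, hidden)
        self.dwconv = nn.DepthwiseConv3x3(hidden)
        self.fc2 = nn.Linear(hidden, cfg.channels)
        self.drop1 = nn.Dropout(cfg.drop_rate, seed=drop_seed)
        self.drop2 = nn.Dropout(cfg.drop_rate, seed=drop_seed + 1)

    @staticmethod
    def _to_tokens(x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        return x.reshape(b, c, h * w).transpose(0, 2, 1)

    @staticmethod
    def _to_spatial(t: Tensor, h: int, w: int) -> Tensor:
        b, n, c = t.shape
        return t.transpose(0, 2, 1).reshape(b, c, h, w)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"shifted-MLP expected {self.cfg.channels} channels, got {x.shape[1]}")
        b, c, h, w = x.shape
        tokens = self._to_tokens(x)
        z = self.norm(tokens)
        z = nn.axial_shift(self._to_spatial(z, h, w), self.cfg.shift_size, axis=3)
        z = self.fc1(self._to_tokens(z))
        z = self.dwconv(self._to_spatial(z, h, w))
        z = nn.gelu(z)
        z = self.drop1(z)
        z = nn.axial_shift(z, self.cfg.shift_size, axis=2)
        z = self.fc2(self._to_tokens(z))
        z = self.drop2(z)
        return self._to_spatial(nn.add(tokens, z), h, w)
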