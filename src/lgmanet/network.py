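"""Five-stage encoder-decoder assembly with skip connections.

Encoder: three convolutional stages of two dense local-global blocks each
(2x2 max-pool between stages), then two tokenized-MLP stages entered
through stride-2 patch-merging convolutions. Decoder mirrors the encoder:
bilinear 2x upsampling + convolution, skip fusion with the mirrored
encoder feature, then a shifted-MLP block (deep stages), shifted-MLP +
multi-scale attention (middle stage) or attention + convolution (shallow
stages). The head is a 1x1 convolution emitting logits; a sigmoid is
applied only at prediction/metric time.

Ablation variants replace each dense block with a single plain
convolutional layer (``baseline``, ``baseline_emra``) and/or drop every
attention module (``baseline``, ``baseline_lgipb``).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .blocks import Emra, Lgipb, ShiftedMlpBlock
from .config import EmraConfig, LgipbConfig, ModelConfig, ShiftedMlpConfig
from .nn import Tensor


class _PlainConv(nn.Module):
    """Standard convolutional layer (3x3 + BN + ReLU): the dense-block
    substitute used by the ablation variants."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class _UpConv(nn.Module):
    """Bilinear 2x upsampling followed by a 3x3 convolution."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.up = nn.Upsample2x()
        self.conv = nn.Conv2d(cin, cout, 3, bias=False)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(self.up(x))))


class _SkipFuse(nn.Module):
    """Skip fusion: channel concatenation followed by a 1x1 convolution
    (or plain addition when skip_mode='add')."""

    def __init__(self, width: int, mode: str):
        super().__init__()
        self.mode = mode
        if mode == "concat":
            self.conv = nn.Conv2d(2 * width, width, 1, bias=False)
            self.bn = nn.BatchNorm2d(width)
            self.act = nn.ReLU()

    def forward(self, x, skip):
        if x.shape[2:] != skip.shape[2:]:
            raise ValueError(f"skip fusion spatial mismatch: {x.shape} vs {skip.shape}")
        if self.mode == "add":
            return nn.add(x, skip)
        return self.act(self.bn(self.conv(nn.concat([x, skip], axis=1))))


def _lgipb_cfg(cfg: ModelConfig, cin: int, cout: int) -> LgipbConfig:
    return LgipbConfig(cin, cout, cfg.lgipb_inner_widths, cfg.prelu_init)


def _emra_cfg(cfg: ModelConfig, cin: int, cout: int) -> EmraConfig:
    return EmraConfig(cin, cout, cfg.emra_gamma, cfg.emra_b, cfg.emra_kernel_sizes)


def _mlp_cfg(cfg: ModelConfig, channels: int) -> ShiftedMlpConfig:
    return ShiftedMlpConfig(channels, cfg.mlp_expansion, cfg.mlp_shift_size,
                            cfg.mlp_drop_rate)


class LgmaNet(nn.Module):
    """The assembled segmentation network. Input spatial dims must be
    divisible by 32 (five 2x halvings)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w1, w2, w3, w4, w5 = cfg.stage_widths
        use_lgipb = cfg.variant in ("full", "baseline_lgipb")
        use_emra = cfg.variant in ("full", "baseline_emra")
        self.uses_lgipb = use_lgipb
        self.uses_emra = use_emra

        def enc_block(cin, cout):
            if use_lgipb:
                return Lgipb(_lgipb_cfg(cfg, cin, cout))
            return _PlainConv(cin, cout)

        # encoder: three dense/conv stages, each followed by 2x2 max-pool
        self.enc1a = enc_block(cfg.in_channels, w1)
        self.enc1b = enc_block(w1, w1)
        self.enc2a = enc_block(w1, w2)
        self.enc2b = enc_block(w2, w2)
        self.enc3a = enc_block(w2, w3)
        self.enc3b = enc_block(w3, w3)
        self.pool = nn.MaxPool2x2()
        # two tokenized-MLP stages behind stride-2 patch-merging convolutions
        self.embed4 = nn.Conv2d(w3, w4, 3, stride=2, padding=1)
        self.mlp4 = ShiftedMlpBlock(_mlp_cfg(cfg, w4))
        self.embed5 = nn.Conv2d(w4, w5, 3, stride=2, padding=1)
        self.mlp5 = ShiftedMlpBlock(_mlp_cfg(cfg, w5))

        # decoder
        self.up1 = _UpConv(w5, w4)
        self.fuse1 = _SkipFuse(w4, cfg.skip_mode)
        self.dec1_mlp = ShiftedMlpBlock(_mlp_cfg(cfg, w4))
        self.up2 = _UpConv(w4, w3)
        self.fuse2 = _SkipFuse(w3, cfg.skip_mode)
        self.dec2_mlp = ShiftedMlpBlock(_mlp_cfg(cfg, w3))
        if use_emra:
            self.dec2_emra = Emra(_emra_cfg(cfg, w3, w3))
        self.up3 = _UpConv(w3, w2)
        self.fuse3 = _SkipFuse(w2, cfg.skip_mode)
        if use_emra:
            self.dec3_emra = Emra(_emra_cfg(cfg, w2, w2))
        self.dec3_conv = _PlainConv(w2, w2)
        self.up4 = _UpConv(w2, w1)
        self.fuse4 = _SkipFuse(w1, cfg.skip_mode)
        if use_emra:
            self.dec4_emra = Emra(_emra_cfg(cfg, w1, w1))
        self.dec4_conv = _PlainConv(w1, w1)
        self.up5 = _UpConv(w1, w1)
        if use_emra:
            self.dec5_emra = Emra(_emra_cfg(cfg, w1, w1))
        self.dec5_conv = _PlainConv(w1, w1)
        self.head = nn.Conv2d(w1, cfg.num_classes, 1, bias=True)

    # -- forward -------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial dims must be divisible by 32 (five 2x "
                f"downsamplings); got {h}x{w}")
        # encoder
        t1 = self.pool(self.enc1b(self.enc1a(x)))          # w1, H/2
        t2 = self.pool(self.enc2b(self.enc2a(t1)))         # w2, H/4
        t3 = self.pool(self.enc3b(self.enc3a(t2)))         # w3, H/8
        t4 = self.mlp4(self.embed4(t3))                    # w4, H/16
        z = self.mlp5(self.embed5(t4))                     # w5, H/32
        # decoder
        z = self.dec1_mlp(self.fuse1(self.up1(z), t4))     # w4, H/16
        z = self.dec2_mlp(self.fuse2(self.up2(z), t3))     # w3, H/8
        if self.uses_emra:
            z = self.dec2_emra(z)
        z = self.fuse3(self.up3(z), t2)                    # w2, H/4
        if self.uses_emra:
            z = self.dec3_emra(z)
        z = self.dec3_conv(z)
        z = self.fuse4(self.up4(z), t1)                    # w1, H/2
        if self.uses_emra:
            z = self.dec4_emra(z)
        z = self.dec4_conv(z)
        z = self.up5(z)                                    # w1, H
        if self.uses_emra:
            z = self.dec5_emra(z)
        z = self.dec5_conv(z)
        return self.head(z)                                # logits

    def encoder_features(self, x: Tensor) -> list[Tensor]:
        """The five encoder outputs, shallow to deep (for shape checks)."""
        t1 = self.pool(self.enc1b(self.enc1a(x)))
        t2 = self.pool(self.enc2b(self.enc2a(t1)))
        t3 = self.pool(self.enc3b(self.enc3a(t2)))
        t4 = self.mlp4(self.embed4(t3))
        t5 = self.mlp5(self.embed5(t4))
        return [t1, t2, t3, t4, t5]


@dataclass(frozen=True)
class ParamReport:
    total_params: int
    total_params_millions: float
    per_module: dict[str, int]


def build_model(cfg: ModelConfig, seed: int | None = None) -> LgmaNet:
    """Construct the network; `seed` resets the weight-init stream."""
    if seed is not None:
        nn.seed_all(seed)
    return LgmaNet(cfg)


def make_variant(cfg: ModelConfig, variant: str) -> ModelConfig:
    """Return a config for one of the four ablation wirings."""
    return cfg.with_variant(variant)


def count_parameters(model: nn.Module) -> ParamReport:
    """Count every trainable scalar exactly once, grouped by top-level
    submodule."""
    per: dict[str, int] = {}
    total = 0
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        per[top] = per.get(top, 0) + p.size
        total += p.size
    return ParamReport(total_params=total,
                       total_params_millions=round(total / 1e6, 2),
                       per_module=per)
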