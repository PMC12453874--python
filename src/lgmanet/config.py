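"""Typed configuration objects for the network, training, data and fixtures.

Each dataclass validates its invariants on construction so that an invalid
configuration fails loudly before any compute is spent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

VARIANTS = ("full", "baseline", "baseline_lgipb", "baseline_emra")

#: Encoder output widths, shallow to deep. The three shallow widths follow
#: the tokenized-MLP family convention for the convolutional stem; the two
#: deep (MLP-stage) widths were fixed by calibrating the trainable-parameter
#: count of the assembled full model to 5.51 M.
DEFAULT_STAGE_WIDTHS = (16, 32, 128, 220, 304)


@dataclass(frozen=True)
class LgipbConfig:
    """Local-global information processing block.

    ``inner_widths`` are the widths of the first three dense convolutions;
    with the default (12, 12, 24) the dense concatenations trace
    12 -> 24 -> 48 channels and the fourth convolution emits 48.
    """
    in_channels: int
    out_channels: int
    inner_widths: tuple[int, int, int] = (12, 12, 24)
    prelu_init: float = 0.25

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if len(self.inner_widths) != 3 or any(w < 1 for w in self.inner_widths):
            raise ValueError("inner_widths must be three positive integers")
        if not (0.0 < self.prelu_init < 1.0):
            raise ValueError("prelu_init must lie in (0, 1)")

    @property
    def dense_width(self) -> int:
        """Width after the final dense concatenation (48 by default)."""
        return sum(self.inner_widths)


@dataclass(frozen=True)
class EmraConfig:
    """Efficient multi-scale reconstruction attention module."""
    in_channels: int
    out_channels: int
    gamma: float = 2.0
    b: float = 1.0
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if len(self.kernel_sizes) < 1 or any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel_sizes must be odd positive integers")


@dataclass(frozen=True)
class ShiftedMlpConfig:
    """Tokenized shifted-MLP stage (axial shift + depthwise 3x3 between
    two linear projections, with a residual connection)."""
    channels: int
    expansion: float = 4.0
    shift_size: int = 5
    drop_rate: float = 0.0

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.expansion <= 0:
            raise ValueError("expansion must be positive")
        if self.shift_size < 1:
            raise ValueError("shift_size must be positive")
        if not (0.0 <= self.drop_rate < 1.0):
            raise ValueError("drop_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural free parameter of the segmentation network."""
    in_channels: int = 3
    num_classes: int = 1
    stage_widths: tuple[int, int, int, int, int] = DEFAULT_STAGE_WIDTHS
    variant: str = "full"
    skip_mode: str = "concat"          # "concat" (fuse conv) or "add"
    lgipb_inner_widths: tuple[int, int, int] = (12, 12, 24)
    prelu_init: float = 0.25
    emra_gamma: float = 2.0
    emra_b: float = 1.0
    emra_kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    mlp_expansion: float = 4.0
    mlp_shift_size: int = 5
    mlp_drop_rate: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")
        if self.skip_mode not in ("concat", "add"):
            raise ValueError("skip_mode must be 'concat' or 'add'")
        if len(self.stage_widths) != 5 or any(w < 1 for w in self.stage_widths):
            raise ValueError("stage_widths must be five positive integers")
        if self.in_channels < 1 or self.num_classes < 1:
            raise ValueError("in_channels and num_classes must be positive")

    def with_variant(self, variant: str) -> "ModelConfig":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
        return replace(self, variant=variant)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation regime: Adam with cosine-annealed learning rate."""
    epochs: int = 400
    batch_size: int = 8
    lr0: float = 1e-4
    lr_min: float = 0.0
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str = "checkpoints"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0.0 <= self.lr_min <= self.lr0):
            raise ValueError("need 0 <= lr_min <= lr0")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass(frozen=True)
class DatasetSpec:
    """A folder-based image/mask dataset with the 80/20 split convention."""
    images_dir: str
    masks_dir: str
    resolution: int = 384
    split_ratio: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.resolution < 1:
            raise ValueError("resolution must be positive")


NOISE_KINDS = ("hair_streaks", "patch_artifacts", "speckle", "blur_boundary")


@dataclass(frozen=True)
class SynthSpec:
    """Synthetic lesion-like fixture: smooth irregular bright-or-dark blobs
    on a textured background, with optional acquisition artifacts."""
    n_images: int
    size: int = 96
    n_blobs: tuple[int, int] = (1, 3)
    noise_profile: tuple[str, ...] = ()
    seed: int = 0
    fg_fraction: tuple[float, float] = (0.05, 0.45)
    contrast: float = 0.45

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        if self.size < 16:
            raise ValueError("size must be >= 16")
        lo, hi = self.n_blobs
        if not (1 <= lo <= hi):
            raise ValueError("n_blobs must be a range (lo, hi) with 1 <= lo <= hi")
        bad = [k for k in self.noise_profile if k not in NOISE_KINDS]
        if bad:
            raise ValueError(f"unknown noise kinds {bad}; valid: {NOISE_KINDS}")


def config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    return d
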