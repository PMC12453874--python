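"""Layer containers over the autodiff primitives.

Initialisation draws from a module-level generator set by :func:`seed_all`,
so a whole model is reproducible from one integer seed.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

_INIT_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the parameter-initialisation stream."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def _kaiming(shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (_INIT_RNG.standard_normal(shape) * std).astype(np.float32)


class Module:
    """Minimal module: tracks child modules and parameters by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, child in self._children.items():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- serialisation -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self.named_buffers():
            out[name] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key in own:
                if own[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{own[key].data.shape} vs {arr.shape}")
                own[key].data[...] = arr
            elif key in bufs:
                bufs[key][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (f"{prefix}{name}", getattr(self, name))
        for name, child in self._children.items():
            yield from child.named_buffers(f"{prefix}{name}.")


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(_kaiming((out_channels, in_channels, kernel_size, kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"Conv2d expected {self.in_channels} input channels, got {x.shape[1]}")
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv3x3(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.weight = Tensor(_kaiming((channels, 1, 3, 3), 9), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.depthwise_conv3x3(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_kaiming((in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, features: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Tensor(np.ones(features, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(features, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.layer_norm(x, self.weight, self.bias, self.eps)


class PReLU(Module):
    """Channelwise parametric ReLU, one learnable negative slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.weight = Tensor(np.full(channels, init, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.prelu(x, self.weight)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.gelu(x)


class Dropout(Module):
    def __init__(self, rate: float = 0.0, seed: int = 0):
        super().__init__()
        self.rate = rate
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        return T.dropout(x, self.rate, self._rng)


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.maxpool2x2(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.upsample2x_bilinear(x)


class Adam:
    """Adam with the conventional (0.9, 0.999, 1e-8) moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
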