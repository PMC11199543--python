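"""Layers for the 3-D segmentation network, built on :mod:`oclnet.nn.tensor`.

Each layer owns its parameter tensors and implements ``__call__`` taking the
input tensor plus a :class:`Context` carrying the train/eval flag and the
dropout random stream.  Weight initialization is He-uniform for convolutions
(fan-in based), matching common practice for ReLU networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import Tensor

__all__ = [
    "Context",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "Dropout",
    "ConvBlock",
]

DTYPE = np.float32


@dataclass
class Context:
    """Per-forward state: training mode and the dropout random stream."""

    training: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All learnable and buffer arrays keyed by attribute path."""
        out: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.array(state[key], dtype=v.data.dtype)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_arrays(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv3d(Module):
    """``bias=False`` for convolutions feeding a normalization layer, whose
    mean subtraction would cancel the bias exactly (leaving it gradient-free)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        k = kernel_size
        fan_in = in_channels * k**3
        self.weight = Tensor(
            _he_uniform(rng, (out_channels, in_channels, k, k, k), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=bias)
        self.padding = (k - 1) // 2

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return x.conv3d(self.weight, self.bias, self.padding)


class ConvTranspose3d(Module):
    """Kernel-2 / stride-2 transposed convolution (doubles each spatial axis).

    Bias-free: its output only ever enters convolution + normalization
    blocks, where a constant channel shift cancels out.
    """

    def __init__(
        self, in_channels: int, out_channels: int, rng: np.random.Generator
    ) -> None:
        fan_in = in_channels * 8
        self.weight = Tensor(
            _he_uniform(rng, (in_channels, out_channels, 2, 2, 2), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=False)

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias)


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes.

    With one volume per batch the batch statistics are the instance
    statistics.  ``instance_mode`` keeps using the current input's
    statistics at evaluation time too (instance-normalization behaviour),
    which avoids the train/eval mismatch that running statistics develop
    when every batch is a single, fairly different volume.
    """

    def __init__(
        self,
        channels: int,
        momentum: float = 0.1,
        eps: float = 1e-5,
        instance_mode: bool = False,
    ) -> None:
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.instance_mode = instance_mode

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return x.batchnorm(
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=ctx.training or self.instance_mode,
            momentum=self.momentum if ctx.training else 0.0,
            eps=self.eps,
        )


class Dropout(Module):
    def __init__(self, p: float) -> None:
        self.p = p

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return x.dropout(self.p, ctx.rng, ctx.training)


class ConvBlock(Module):
    """Two (conv 3x3x3 -> norm -> ReLU) stages at a fixed resolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        instance_norm: bool = False,
    ) -> None:
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng, bias=False)
        self.norm1 = BatchNorm3d(out_channels, instance_mode=instance_norm)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng, bias=False)
        self.norm2 = BatchNorm3d(out_channels, instance_mode=instance_norm)

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        x = self.norm1(self.conv1(x, ctx), ctx).relu()
        x = self.norm2(self.conv2(x, ctx), ctx).relu()
        return x
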