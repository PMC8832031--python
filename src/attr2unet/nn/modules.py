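"""Layer abstractions over the autograd core: parameter registration,
train/eval mode, state dicts, and the concrete layers used by the network."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
    "kaiming_normal",
]


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    """Fan-in scaled normal initialization (He et al. convention)."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Module:
    """Base class with recursive parameter/submodule discovery via attributes."""

    def __init__(self):
        self.training = True

    # -- mode -------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- traversal --------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ----------------------------------------------------
    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in getattr(self, "_buffers", {}).items():
            if val is not None:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers: dict[str, tuple[Module, str]] = {}

        def collect(mod: Module, prefix: str) -> None:
            for name in getattr(mod, "_buffers", {}):
                buffers[prefix + name] = (mod, name)
            for cname, child in mod._children():
                collect(child, prefix + cname + ".")

        collect(self, "")
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.copy()
            elif key in buffers:
                mod, name = buffers[key]
                mod._buffers[name] = value.copy()
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class ModuleList(list):
    """A plain list of modules that participates in attribute discovery."""


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: Optional[int] = None,
        bias: bool = True,
        dtype=np.float32,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Running statistics start undefined; using eval mode before any training
    batch (or an explicit assignment) raises, since there is nothing to
    normalize against.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self._buffers: dict[str, Optional[np.ndarray]] = {
            "running_mean": None,
            "running_var": None,
        }

    def set_running_stats(self, mean, var) -> None:
        self._buffers["running_mean"] = np.asarray(mean, dtype=self.gamma.dtype).reshape(self.num_features)
        self._buffers["running_var"] = np.asarray(var, dtype=self.gamma.dtype).reshape(self.num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (m / max(m - 1, 1))
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            if rm is None:
                self._buffers["running_mean"] = mean.copy()
                self._buffers["running_var"] = unbiased.copy()
            else:
                self._buffers["running_mean"] = (1 - self.momentum) * rm + self.momentum * mean
                self._buffers["running_var"] = (1 - self.momentum) * rv + self.momentum * unbiased
            return ag.batch_norm2d(x, self.gamma, self.beta, mean, var, self.eps, training=True)
        rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
        if rm is None or rv is None:
            raise RuntimeError(
                "BatchNorm2d used in eval mode without running statistics; "
                "train first or call set_running_stats()"
            )
        return ag.batch_norm2d(x, self.gamma, self.beta, rm, rv, self.eps, training=False)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.p, self.rng, self.training)
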