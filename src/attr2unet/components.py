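"""Architectural building blocks of the segmentation network.

Three mechanisms are implemented:

* :class:`AttentionGate` — additive soft spatial attention on a skip
  connection. Encoder features ``x_e`` and same-resolution decoder guidance
  ``x_d`` are each passed through 1x1 convolutions, summed, rectified, reduced
  to a single channel and squashed with a sigmoid; the resulting coefficient
  map (values strictly in (0, 1)) multiplicatively re-weights ``x_e``.
* :class:`RecurrentConvLayer` — a convolution applied over ``t`` discrete time
  steps. At each step the layer sees the (constant) feedforward drive plus a
  recurrent transform of the previous step's output; every step is followed by
  batch normalization and ReLU. Feedforward and recurrent weights are shared
  across steps, as is the batch-norm state (a per-step-BN option is exposed).
* :class:`RRCB` — recurrent residual convolutional block: a 1x1
  channel-matching convolution followed by two recurrent conv layers, with the
  block input added back to the body output (scaled by a modulating scalar).

:func:`unrolled_residual_input` evaluates the closed-form expansion of stacked
residual layers and exists to cross-check the iterated residual recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "AttentionOutput",
    "AttentionGate",
    "RecurrentConvLayer",
    "RRCB",
    "iterate_residual",
    "unrolled_residual_input",
]


@dataclass
class AttentionOutput:
    """Gated encoder features plus the single-channel coefficient map."""

    gated: Tensor
    coefficients: Tensor


class AttentionGate(nn.Module):
    """Additive attention gate for a skip connection.

    Parameters
    ----------
    channels_e, channels_d : int
        Channel counts of the encoder features and the decoder guidance.
    inter_channels : int, optional
        Width of the intermediate (pre-sigmoid) representation; defaults to
        half the encoder width, floored at 1.
    """

    def __init__(
        self,
        channels_e: int,
        channels_d: int,
        rng: np.random.Generator,
        inter_channels: int | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(1, channels_e // 2)
        self.inter_channels = inter_channels
        # lambda = W_e * x_e + W_d * x_d + b_lambda  (single shared bias)
        self.conv_e = nn.Conv2d(channels_e, inter_channels, 1, rng, bias=True, dtype=dtype)
        self.conv_d = nn.Conv2d(channels_d, inter_channels, 1, rng, bias=False, dtype=dtype)
        # mu = psi * relu(lambda) + b_mu
        self.psi = nn.Conv2d(inter_channels, 1, 1, rng, bias=True, dtype=dtype)

    def forward(self, x_e: Tensor, x_d: Tensor) -> AttentionOutput:
        if x_e.data.shape[2:] != x_d.data.shape[2:]:
            raise ValueError(
                f"spatial mismatch: encoder {x_e.data.shape[2:]} vs guidance "
                f"{x_d.data.shape[2:]}; resample the guidance first"
            )
        if x_e.data.shape[0] != x_d.data.shape[0]:
            raise ValueError(
                f"batch mismatch: {x_e.data.shape[0]} vs {x_d.data.shape[0]}"
            )
        lam = ag.add(self.conv_e(x_e), self.conv_d(x_d))
        mu = self.psi(ag.relu(lam))
        alpha = ag.sigmoid(mu)  # (N, 1, H, W), broadcast over encoder channels
        return AttentionOutput(gated=ag.mul(x_e, alpha), coefficients=alpha)


class RecurrentConvLayer(nn.Module):
    """Convolutional layer unrolled over discrete time steps.

    The input drive is constant across steps; step 0 uses the feedforward
    term only (the recurrent state starts at zero), and each step applies
    conv -> batch norm -> ReLU. ``t`` counts total conv passes, so ``t=1`` is
    a plain conv+BN+ReLU.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        t: int,
        rng: np.random.Generator,
        kernel_size: int = 3,
        with_recurrent_weights: bool = True,
        per_step_bn: bool = False,
        bn_eps: float = 1e-5,
        dtype=np.float32,
    ):
        super().__init__()
        if t < 1:
            raise ValueError(f"t must be >= 1, got {t}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.t = t
        self.per_step_bn = per_step_bn
        self.conv_f = nn.Conv2d(in_channels, out_channels, kernel_size, rng, bias=True, dtype=dtype)
        self.conv_r = (
            nn.Conv2d(out_channels, out_channels, kernel_size, rng, bias=False, dtype=dtype)
            if with_recurrent_weights
            else None
        )
        if per_step_bn:
            self.bns = nn.ModuleList(
                nn.BatchNorm2d(out_channels, eps=bn_eps, dtype=dtype) for _ in range(t)
            )
        else:
            self.bn = nn.BatchNorm2d(out_channels, eps=bn_eps, dtype=dtype)

    def _bn(self, step: int) -> nn.BatchNorm2d:
        return self.bns[step] if self.per_step_bn else self.bn

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.data.shape[1]} channels, "
                f"layer expects {self.in_channels}"
            )
        drive = self.conv_f(x)
        out = ag.relu(self._bn(0)(drive))
        for step in range(1, self.t):
            if self.conv_r is None:
                raise RuntimeError("t > 1 requires recurrent weights")
            out = ag.relu(self._bn(step)(ag.add(drive, self.conv_r(out))))
        return out


class RRCB(nn.Module):
    """Recurrent residual convolutional block.

    ``shortcut = conv1x1(x)``; ``body = RCL(RCL(shortcut))``;
    ``output = modulating_scalar * shortcut + body`` when ``residual`` is on.
    With ``recurrent`` off the two layers collapse to plain conv+BN+ReLU
    pairs (``t`` is forced to 1 and no recurrent weights are allocated); with
    ``residual`` off the shortcut addition is dropped and the first layer maps
    channels directly.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        t: int,
        rng: np.random.Generator,
        residual: bool = True,
        recurrent: bool = True,
        modulating_scalar: float = 1.0,
        per_step_bn: bool = False,
        dtype=np.float32,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.residual = residual
        self.modulating_scalar = float(modulating_scalar)
        t_eff = t if recurrent else 1
        kw = dict(
            rng=rng,
            with_recurrent_weights=recurrent,
            per_step_bn=per_step_bn,
            dtype=dtype,
        )
        if residual:
            self.shortcut = nn.Conv2d(in_channels, out_channels, 1, rng, bias=True, dtype=dtype)
            self.layer1 = RecurrentConvLayer(out_channels, out_channels, t_eff, **kw)
        else:
            self.shortcut = None
            self.layer1 = RecurrentConvLayer(in_channels, out_channels, t_eff, **kw)
        self.layer2 = RecurrentConvLayer(out_channels, out_channels, t_eff, **kw)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.data.shape[1]} channels, "
                f"block expects {self.in_channels}"
            )
        if self.shortcut is None:
            return self.layer2(self.layer1(x))
        pre = self.shortcut(x)
        body = self.layer2(self.layer1(pre))
        return ag.add(ag.scale(pre, self.modulating_scalar), body)


# ---------------------------------------------------------------------------
# Closed-form residual expansion (verification utility)
# ---------------------------------------------------------------------------

ResidualLayer = tuple[float, Callable[[np.ndarray], np.ndarray]]


def iterate_residual(x: np.ndarray, layers: Sequence[ResidualLayer]) -> np.ndarray:
    """Apply ``x <- alpha_k * x + f_k(x)`` sequentially (combine op = identity)."""
    x = np.asarray(x, dtype=float)
    for alpha, f in layers:
        x = alpha * x + f(x)
    return x


def unrolled_residual_input(
    layer_I: int,
    layer_i: int,
    x: np.ndarray,
    layers: Sequence[ResidualLayer],
) -> np.ndarray:
    """Evaluate the telescoped expansion of stacked residual layers.

    The input of layer ``I`` expressed relative to layer ``i`` is the product
    of the modulating scalars applied to ``x_i`` plus, for each intermediate
    layer ``k``, its body output propagated through the remaining scalars:

    ``x_I = (prod_k alpha_k) x_i + sum_k (prod_{h>k} alpha_h) f_k(x_k)``

    ``layers[k - layer_i]`` holds ``(alpha_k, f_k)`` for
    ``k = layer_i .. layer_I - 1``. The intermediate inputs ``x_k`` are the
    residual iterates themselves.
    """
    if layer_I <= layer_i:
        raise ValueError(f"layer_I ({layer_I}) must exceed layer_i ({layer_i})")
    span = layer_I - layer_i
    if len(layers) != span:
        raise ValueError(f"expected {span} layer definitions, got {len(layers)}")
    x = np.asarray(x, dtype=float)
    # Intermediate inputs x_k, built by the recursion itself.
    xs = [x]
    for alpha, f in layers[:-1]:
        xs.append(alpha * xs[-1] + f(xs[-1]))
    alphas = np.array([a for a, _ in layers], dtype=float)
    total = np.prod(alphas) * x
    for k in range(span):
        tail = np.prod(alphas[k + 1 :]) if k + 1 < span else 1.0
        total = total + tail * layers[k][1](xs[k])
    return total
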