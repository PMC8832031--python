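"""Full encoder–decoder assembly and the ablation variant factory.

The network is a five-level U-shaped model. The encoder applies five blocks
with 2x2 max pooling between levels; the decoder mirrors it with four blocks,
each preceded by an up-conv (2x nearest upsample + 3x3 conv + BN + ReLU) and a
skip fusion with the same-scale encoder features — attention-gated
concatenation when the attention mechanism is enabled, plain concatenation
otherwise. A 1x1 convolution plus sigmoid produces the per-pixel lesion
probability map. Blocks are recurrent residual convolutional blocks (RRCB) or
degrade per the ablation flags.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .components import RRCB, AttentionGate
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "NetworkConfig",
    "VariantSpec",
    "VARIANT_NAMES",
    "AttR2UNet",
    "build_model",
    "make_variant",
    "extract_attention_maps",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

DEPTH = 5  # encoder levels; fixed by the architecture


@dataclass
class NetworkConfig:
    """Structural hyperparameters defining a model (or ablation variant).

    ``use_normalization`` is consumed by the data pipeline, not the network
    itself; it travels with the config so a variant fully describes a run.
    """

    base_channels: int = 64
    t: int = 3
    use_attention: bool = True
    use_recurrent: bool = True
    use_residual: bool = True
    use_normalization: bool = True
    dropout_rate: float = 0.5
    modulating_scalar: float = 1.0
    per_step_bn: bool = False
    dtype: str = "float32"

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class VariantSpec:
    name: str
    config: NetworkConfig


# Ablation flag tables: name -> (attention, recurrent, residual, normalization)
_VARIANT_FLAGS: dict[str, tuple[bool, bool, bool, bool]] = {
    "Att+Rec+Res": (True, True, True, True),
    "Att+Rec": (True, True, False, True),
    "Att+Res": (True, False, True, True),
    "Rec+Res": (False, True, True, True),
    "Only Att": (True, False, False, True),
    "Only Rec": (False, True, False, True),
    "Only Res": (False, False, True, True),
    "Skeleton": (False, False, False, True),
    "Without Norm": (True, True, True, False),
}

VARIANT_NAMES = tuple(_VARIANT_FLAGS)


def make_variant(name: str, base: NetworkConfig | None = None) -> VariantSpec:
    """Resolve an ablation-variant name to a fully specified config."""
    if name not in _VARIANT_FLAGS:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(_VARIANT_FLAGS)}"
        )
    att, rec, res, norm = _VARIANT_FLAGS[name]
    base = base or NetworkConfig()
    cfg = replace(
        base,
        use_attention=att,
        use_recurrent=rec,
        use_residual=res,
        use_normalization=norm,
    )
    return VariantSpec(name=name, config=cfg)


class _UpConv(nn.Module):
    """2x nearest-neighbour upsample followed by conv + BN + ReLU."""

    def __init__(self, in_channels: int, out_channels: int, rng, dtype):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(ag.upsample_nearest2d(x))))


class AttR2UNet(nn.Module):
    """Five-level attention-gated recurrent residual U-Net (1-channel input,
    1-channel probability output)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(seed)
        self._dropout_rng_seed = int(np.random.default_rng(seed + 1).integers(2**31))
        self._dropout_rng = np.random.default_rng(self._dropout_rng_seed)

        b = config.base_channels
        chans = [b * (2**i) for i in range(DEPTH)]
        self.channels = chans

        def block(cin, cout):
            return RRCB(
                cin,
                cout,
                t=config.t,
                rng=rng,
                residual=config.use_residual,
                recurrent=config.use_recurrent,
                modulating_scalar=config.modulating_scalar,
                per_step_bn=config.per_step_bn,
                dtype=dtype,
            )

        self.encoder = nn.ModuleList(
            block(1 if i == 0 else chans[i - 1], chans[i]) for i in range(DEPTH)
        )
        # Dropout at the two deepest encoder blocks.
        self.enc_dropout = nn.ModuleList(
            nn.Dropout(config.dropout_rate, self._dropout_rng) for _ in range(2)
        )
        self.upconvs = nn.ModuleList(
            _UpConv(chans[i + 1], chans[i], rng, dtype) for i in reversed(range(DEPTH - 1))
        )
        self.decoder = nn.ModuleList(
            block(2 * chans[i], chans[i]) for i in reversed(range(DEPTH - 1))
        )
        if config.use_attention:
            self.gates = nn.ModuleList(
                AttentionGate(chans[i], chans[i], rng, dtype=dtype)
                for i in reversed(range(DEPTH - 1))
            )
        else:
            self.gates = nn.ModuleList()
        self.head = nn.Conv2d(chans[0], 1, 1, rng, dtype=dtype)

    def reset_dropout_rng(self) -> None:
        """Restore the dropout stream to its construction-time state."""
        self._dropout_rng = np.random.default_rng(self._dropout_rng_seed)
        for d in self.enc_dropout:
            d.rng = self._dropout_rng

    def forward(self, x, collect_attention: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.config.dtype))
        n, c, h, w = x.data.shape
        if c != 1:
            raise ValueError(f"expected 1 input channel, got {c}")
        if h % 16 or w % 16:
            raise ValueError(
                f"input spatial dims must be divisible by 16 (four 2x poolings); got {h}x{w}"
            )
        skips = []
        cur = x
        for i, blk in enumerate(self.encoder):
            cur = blk(cur)
            if i >= DEPTH - 2:  # two deepest blocks
                cur = self.enc_dropout[i - (DEPTH - 2)](cur)
            if i < DEPTH - 1:
                skips.append(cur)
                cur = ag.max_pool2d(cur)
        attention_maps: list[np.ndarray] = []
        # Decoder runs coarse -> fine; skips are stored fine -> coarse.
        for j in range(DEPTH - 1):
            level = DEPTH - 2 - j  # encoder level being fused
            g = self.upconvs[j](cur)
            x_e = skips[level]
            if self.config.use_attention:
                gate_out = self.gates[j](x_e, g)
                fused = ag.concat_channels([gate_out.gated, g])
                if collect_attention:
                    attention_maps.append(gate_out.coefficients.data.copy())
            else:
                fused = ag.concat_channels([x_e, g])
            cur = self.decoder[j](fused)
        # Clamp keeps probabilities strictly inside (0, 1) even where the
        # sigmoid saturates at working precision.
        out = ag.clamp(ag.sigmoid(self.head(cur)), 1e-6, 1.0 - 1e-6)
        if collect_attention:
            return out, attention_maps
        return out


def build_model(config: NetworkConfig, seed: int = 0) -> AttR2UNet:
    """Construct a network with seeded, deterministic initialization."""
    return AttR2UNet(config, seed=seed)


def extract_attention_maps(model: AttR2UNet, batch) -> list[np.ndarray]:
    """Return one single-channel coefficient map per decoder level, ordered
    finest (encoder level 1 resolution) to coarsest."""
    if not model.config.use_attention:
        raise ValueError("model was built without attention gates")
    _, maps = model.forward(batch, collect_attention=True)
    return list(reversed(maps))  # decoder emits coarse->fine; report fine->coarse


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: AttR2UNet, path: str | Path) -> None:
    """Write a flat named-tensor archive plus a JSON manifest and config."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    manifest = {
        "config": asdict(model.config),
        "seed": model.seed,
        "tensors": {k: {"shape": list(v.shape), "dtype": str(v.dtype)} for k, v in state.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> AttR2UNet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    config = NetworkConfig(**manifest["config"])
    model = AttR2UNet(config, seed=manifest["seed"])
    with np.load(path.with_suffix(".npz")) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
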