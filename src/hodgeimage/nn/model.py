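"""The decomposed-image classifier network.

Architecture: an initialization block (3-kernel convolution to the
hidden width C, batch norm, ReLU), a stack of Transformer-encoder-shaped
convolution layers, global average pooling, and an MLP head.  Each
encoder layer applies two post-norm residual sublayers and then halves
every spatial extent:

    x'   = Norm(x + MultiHeadConv(x))
    x''  = Norm(x' + FeedForwardConv(x'))
    x''' = MaxPool(x'')

MultiHeadConv mimics multi-head attention with a grouped 3-kernel
convolution C -> C*h (h groups), ReLU, and a 1-kernel fusion convolution
C*h -> C.  FeedForwardConv mimics the feed-forward block with two
grouped 1-kernel convolutions C -> 2C -> C.  Both preserve spatial
extents.  Reference configurations: 2D C=72, h=4, g=3 (g=1 for
grayscale), 5 layers; 3D C=64, h=4, g=1, 5 layers — about 0.39M and
0.74M parameters respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    BatchNormNd,
    ConvNd,
    GlobalAvgPool,
    Linear,
    MaxPoolHalf,
    Module,
    ReLU,
    ResidualNorm,
    Sequential,
)

__all__ = [
    "ModelConfig", "MultiHeadConv", "FeedForwardConv", "TransConvLayer",
    "build_model", "count_params", "save_model", "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    ndim: int = 2
    in_channels: int = 6
    hidden_channels: int = 72
    heads: int = 4
    groups: int = 3
    n_layers: int = 5
    n_classes: int = 9
    loss: str = "cross_entropy"  # or "bce_with_logits" for multi-label

    def __post_init__(self):
        c, h, g = self.hidden_channels, self.heads, self.groups
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if c % h:
            raise ValueError(f"hidden channels C={c} must be divisible by heads h={h}")
        if c % g or (2 * c) % g:
            raise ValueError(f"C={c} and 2C must be divisible by groups g={g}")
        if self.n_layers < 1 or self.n_classes < 1:
            raise ValueError("n_layers and n_classes must be positive")
        if self.loss not in ("cross_entropy", "bce_with_logits"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def pool_factor(self) -> int:
        return 2**self.n_layers


def MultiHeadConv(ndim: int, c: int, h: int, rng) -> Sequential:
    """Grouped 3-kernel conv C -> C*h (h groups), ReLU, 1-kernel fusion."""
    return Sequential(
        ConvNd(ndim, c, c * h, kernel_size=3, groups=h, rng=rng),
        ReLU(),
        ConvNd(ndim, c * h, c, kernel_size=1, groups=1, rng=rng),
    )


def FeedForwardConv(ndim: int, c: int, g: int, rng) -> Sequential:
    """Two grouped 1-kernel convolutions C -> 2C -> C with ReLU between."""
    return Sequential(
        ConvNd(ndim, c, 2 * c, kernel_size=1, groups=g, rng=rng),
        ReLU(),
        ConvNd(ndim, 2 * c, c, kernel_size=1, groups=g, rng=rng),
    )


def TransConvLayer(ndim: int, c: int, h: int, g: int, rng) -> Sequential:
    """Post-norm residual encoder layer followed by stride-2 max pooling."""
    return Sequential(
        ResidualNorm(MultiHeadConv(ndim, c, h, rng), BatchNormNd(c, ndim)),
        ResidualNorm(FeedForwardConv(ndim, c, g, rng), BatchNormNd(c, ndim)),
        MaxPoolHalf(ndim),
    )


class Network(Module):
    """Full classifier; forward returns class logits (N, n_classes)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        nd, c = config.ndim, config.hidden_channels
        self.body = Sequential(
            ConvNd(nd, config.in_channels, c, kernel_size=3, groups=1, rng=rng),
            BatchNormNd(c, nd),
            ReLU(),
            *[
                TransConvLayer(nd, c, config.heads, config.groups, rng)
                for _ in range(config.n_layers)
            ],
            GlobalAvgPool(),
            Linear(c, c, rng),
            ReLU(),
            Linear(c, config.n_classes, rng),
        )

    def parameters(self):
        return self.body.parameters()

    def forward(self, x, training=False):
        x = self._pad_to_multiple(np.asarray(x, dtype=np.float32))
        return self.body.forward(x, training)

    def backward(self, dlogits):
        return self.body.backward(dlogits)

    def _pad_to_multiple(self, x):
        """Center-pad spatial extents with zeros to a multiple of 2^layers."""
        f = self.config.pool_factor
        spatial = x.shape[2:]
        target = tuple(-(-s // f) * f for s in spatial)
        if target == spatial:
            return x
        pads = [(0, 0), (0, 0)]
        for s, t in zip(spatial, target):
            before = (t - s) // 2
            pads.append((before, t - s - before))
        return np.pad(x, pads)


def build_model(config: ModelConfig, seed: int = 0) -> Network:
    rng = np.random.default_rng(seed)
    return Network(config, rng)


def count_params(model: Network) -> int:
    return int(sum(p.value.size for p in model.parameters()))


def save_model(model: Network, path) -> None:
    """NPZ checkpoint: ordered parameter arrays, running stats, config JSON."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    i = 0
    for mod in _walk(model.body):
        if isinstance(mod, BatchNormNd):
            arrays[f"bn_{i}_mean"] = mod.running_mean
            arrays[f"bn_{i}_var"] = mod.running_var
            i += 1
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> Network:
    data = np.load(path)
    config = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
    model = build_model(config, seed=0)
    for i, p in enumerate(model.parameters()):
        p.value = data[f"param_{i}"].astype(np.float32)
    i = 0
    for mod in _walk(model.body):
        if isinstance(mod, BatchNormNd):
            mod.running_mean = data[f"bn_{i}_mean"].astype(np.float32)
            mod.running_var = data[f"bn_{i}_var"].astype(np.float32)
            i += 1
    return model


def _walk(module: Module):
    yield module
    if isinstance(module, Sequential):
        for m in module.modules:
            yield from _walk(m)
    elif isinstance(module, ResidualNorm):
        yield from _walk(module.block)
        yield from _walk(module.norm)
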