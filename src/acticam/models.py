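"""The two CNN architectures: DixonNet and a one-dimensional ResNet-18.

Both networks map a ``(batch, 3, L)`` triaxial window to one raw logit per
window.  Both end in global average pooling followed by a single linear
layer, which is the structural prerequisite for class activation mapping:
the CAM machinery needs access to the last convolutional feature maps
``S_k(x)`` and the classifier weights ``w_k``, and both are exposed here via
:meth:`Model.forward_with_features`.

DixonNet is a compact four-convolution network (100 filters of kernel 16,
one max-pool of 4, no normalization layers).  The ResNet follows the
standard 18-layer residual design with every 2D convolution replaced by its
1D equivalent: a stride-2 stem (kernel 7, 64 filters), max-pool (kernel 3,
stride 2), then four stages of two basic residual units each with 64, 128,
256 and 512 filters, stride-2 transitions and projection shortcuts.  An
abbreviated one-unit-per-stage variant (``resnet10_1d``) is available for
comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.layers import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    GlobalAvgPool1d,
    Identity,
    Layer,
    Linear,
    MaxPool1d,
    Param,
    ReLU,
    Sequential,
)

ARCHITECTURES = ("dixonnet", "resnet18_1d", "resnet10_1d")


@dataclass
class ModelConfig:
    """Architecture and initialization settings.

    ``width`` rescales DixonNet's filter count (default 100) for cheap test
    variants; ``activation="identity"`` together with ``use_bias=False``
    yields the fully linear DixonNet variant used to verify homogeneity.
    """

    architecture: str = "dixonnet"
    in_channels: int = 3
    out_size: int = 1
    window_length: int = 4096
    dropout_p: float = 0.5
    width: int = 100
    activation: str = "relu"
    use_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        if self.in_channels < 1 or self.out_size < 1:
            raise ValueError("in_channels and out_size must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")


@dataclass
class FeatureMap:
    """Last-convolution activations S (K x T) and their pooled means f (K,)."""

    S: np.ndarray
    f: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.S.ndim != 2 or self.S.shape[1] < 1:
            raise ValueError("feature map must be a K x T array with T >= 1")
        self.f = self.S.mean(axis=1)


class Model:
    """Common forward/backward surface over a feature extractor + GAP + linear head."""

    config: ModelConfig
    features: Sequential  # everything up to and including the last conv activation
    head_pool: GlobalAvgPool1d
    head_dropout: Dropout | None
    head_linear: Linear

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Raw (pre-sigmoid) logits for a (B, 3, L) batch; (B,) when out_size is 1."""
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, L) input, got {x.shape}")
        h = self.features.forward(x, train=train)
        h = self.head_pool.forward(h, train=train)
        if self.head_dropout is not None:
            h = self.head_dropout.forward(h, train=train)
        out = self.head_linear.forward(h, train=train)
        if self.config.out_size == 1:
            return out[:, 0]
        return out

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = grad_logits[:, None] if self.config.out_size == 1 else grad_logits
        g = self.head_linear.backward(g)
        if self.head_dropout is not None:
            g = self.head_dropout.backward(g)
        g = self.head_pool.backward(g)
        return self.features.backward(g)

    def forward_with_features(self, window: np.ndarray) -> tuple[float, FeatureMap, np.ndarray, float]:
        """Evaluate one (3, L) window, returning (logit, FeatureMap, w, bias).

        The returned feature map is exactly the last-conv activation that
        produced the logit, so ``w @ fmap.f + bias == logit``.
        """
        if window.ndim != 2:
            raise ValueError("forward_with_features expects a single (channels, L) window")
        s = self.features.forward(window[None], train=False)[0]
        fmap = FeatureMap(S=s)
        w, bias = self.classifier_weights()
        logit = float(w @ fmap.f + bias)
        return logit, fmap, w, bias

    def classifier_weights(self) -> tuple[np.ndarray, float]:
        """Weights (K,) and bias of the linear head for the positive class."""
        return self.head_linear.weight.data[0].astype(np.float64), float(self.head_linear.bias.data[0])

    # -- bookkeeping -------------------------------------------------------

    def params(self) -> list[Param]:
        return self.features.params() + self.head_linear.params()

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(_batchnorms(self.features)):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        return arrays

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self._state_arrays())

    def load_state(self, arrays) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = arrays[f"p{i}"]
        for i, bn in enumerate(_batchnorms(self.features)):
            bn.running_mean[...] = arrays[f"rm{i}"]
            bn.running_var[...] = arrays[f"rv{i}"]


def _batchnorms(layer: Layer) -> list[BatchNorm1d]:
    found: list[BatchNorm1d] = []
    if isinstance(layer, BatchNorm1d):
        found.append(layer)
    for child in getattr(layer, "layers", []):
        found.extend(_batchnorms(child))
    if isinstance(layer, BasicBlock1d):
        for part in (layer.main, layer.shortcut):
            if part is not None:
                found.extend(_batchnorms(part))
    return found


def load_model(path) -> Model:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig(**json.loads(str(data["__config__"])))
        model = build_model(config)
        model.load_state(data)
    return model


# ---------------------------------------------------------------------------
# DixonNet
# ---------------------------------------------------------------------------


class DixonNet(Model):
    """conv(3->W,k16) conv(W->W,k16) maxpool(4) conv conv, GAP, dropout, linear(W->1).

    Convolutions are length-preserving (same padding) so the last-conv map
    has length L/4 and CAM positions align with input samples by a constant
    factor of 4.  There are no normalization layers.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.width
        act = ReLU if config.activation == "relu" else Identity

        def conv(cin: int, cout: int) -> Conv1d:
            return Conv1d(cin, cout, 16, padding="same", bias=config.use_bias, rng=rng)

        self.features = Sequential(
            conv(config.in_channels, w), act(),
            conv(w, w), act(),
            MaxPool1d(4),
            conv(w, w), act(),
            conv(w, w), act(),
        )
        self.head_pool = GlobalAvgPool1d()
        self.head_dropout = Dropout(config.dropout_p, rng=np.random.default_rng(rng.integers(2**31)))
        self.head_linear = Linear(w, config.out_size, rng=rng)
        if not config.use_bias:
            self.head_linear.bias.data[...] = 0.0

    @property
    def last_conv_channels(self) -> int:
        return self.config.width

    def last_conv_length(self, input_length: int) -> int:
        return input_length // 4


# ---------------------------------------------------------------------------
# 1D ResNet
# ---------------------------------------------------------------------------


class BasicBlock1d(Layer):
    """Two k3 conv+BN layers with an identity or 1x1-projection shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, rng: np.random.Generator) -> None:
        self.main = Sequential(
            Conv1d(in_channels, out_channels, 3, stride=stride, padding=1, bias=False, rng=rng),
            BatchNorm1d(out_channels),
            ReLU(),
            Conv1d(out_channels, out_channels, 3, stride=1, padding=1, bias=False, rng=rng),
            BatchNorm1d(out_channels),
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut: Sequential | None = Sequential(
                Conv1d(in_channels, out_channels, 1, stride=stride, padding=0, bias=False, rng=rng),
                BatchNorm1d(out_channels),
            )
        else:
            self.shortcut = None
        self.relu_out = ReLU()
        self.skip_residual = False  # test hook: drop the shortcut addition

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        main = self.main.forward(x, train=train)
        if not self.skip_residual:
            short = self.shortcut.forward(x, train=train) if self.shortcut is not None else x
            main = main + short
        return self.relu_out.forward(main, train=train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad_out)
        dx = self.main.backward(g)
        if not self.skip_residual:
            if self.shortcut is not None:
                dx = dx + self.shortcut.backward(g)
            else:
                dx = dx + g
        return dx

    def params(self) -> list[Param]:
        out = self.main.params()
        if self.shortcut is not None:
            out.extend(self.shortcut.params())
        return out


class ResNet1d(Model):
    STAGE_WIDTHS = (64, 128, 256, 512)

    def __init__(self, config: ModelConfig, units_per_stage: int = 2) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[Layer] = [
            Conv1d(config.in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng),
            BatchNorm1d(64),
            ReLU(),
            MaxPool1d(3, stride=2, padding=1),
        ]
        in_ch = 64
        for stage, width in enumerate(self.STAGE_WIDTHS):
            for unit in range(units_per_stage):
                stride = 2 if (stage > 0 and unit == 0) else 1
                layers.append(BasicBlock1d(in_ch, width, stride, rng))
                in_ch = width
        self.features = Sequential(*layers)
        self.head_pool = GlobalAvgPool1d()
        self.head_dropout = None
        self.head_linear = Linear(in_ch, config.out_size, rng=rng)

    @property
    def last_conv_channels(self) -> int:
        return self.STAGE_WIDTHS[-1]

    def last_conv_length(self, input_length: int) -> int:
        n = (input_length + 2 * 3 - 7) // 2 + 1  # stem conv
        n = (n + 2 * 1 - 3) // 2 + 1  # max-pool
        for stage in range(1, len(self.STAGE_WIDTHS)):
            n = (n + 2 * 1 - 3) // 2 + 1  # stride-2 stage transition
        return n

    def residual_blocks(self) -> list[BasicBlock1d]:
        return [l for l in self.features.layers if isinstance(l, BasicBlock1d)]


def build_dixonnet(config: ModelConfig) -> DixonNet:
    if config.architecture != "dixonnet":
        raise ValueError("config.architecture must be 'dixonnet'")
    return DixonNet(config)


def build_resnet18_1d(config: ModelConfig) -> ResNet1d:
    if config.architecture not in ("resnet18_1d", "resnet10_1d"):
        raise ValueError("config.architecture must be 'resnet18_1d' or 'resnet10_1d'")
    return ResNet1d(config, units_per_stage=2 if config.architecture == "resnet18_1d" else 1)


def build_model(config: ModelConfig) -> Model:
    if config.architecture == "dixonnet":
        return build_dixonnet(config)
    return build_resnet18_1d(config)
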