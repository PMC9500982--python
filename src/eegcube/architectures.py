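"""Declarative model specifications and exact shape accounting.

The three architectures — the channel-bottleneck 3D CNN (CNN-BN), a plain
3D CNN baseline (modified C3D), and a stacked-LSTM baseline — are described
as ordered layer lists (:class:`ModelSpec`).  Instantiation (numpy backend),
shape tables, parameter counts and FLOP counts all derive from the same
spec, so there is a single source of truth for every census and count.

A channel bottleneck block wraps the expensive d x k x k convolution between
two cheap 1x1x1 convolutions: the first shrinks the channel width (to 1/4 of
the block input for the early blocks), the last restores it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd
import yaml

Triple = tuple[int, int, int]


@dataclass(frozen=True)
class KernelSpec:
    """A d x k x k kernel with its stride and padding triples."""

    size: Triple
    stride: Triple = (1, 1, 1)
    padding: Triple = (0, 0, 0)

    def __post_init__(self):
        for name, triple in (("size", self.size), ("stride", self.stride)):
            if any(v < 1 for v in triple):
                raise ValueError(f"kernel {name} entries must be >= 1, got {triple}")
        if any(v < 0 for v in self.padding):
            raise ValueError(f"padding entries must be >= 0, got {self.padding}")

    @property
    def volume(self) -> int:
        d, h, w = self.size
        return d * h * w


@dataclass(frozen=True)
class LayerSpec:
    """One layer record; which fields apply depends on ``kind``."""

    kind: str  # conv3d | batchnorm | relu | tanh | maxpool3d | flatten | dense | dropout | lstm | take_last
    in_channels: int | None = None
    out_channels: int | None = None
    kernel: KernelSpec | None = None
    in_features: int | None = None
    out_features: int | None = None
    rate: float | None = None
    input_size: int | None = None
    hidden_size: int | None = None
    bias: bool = True


@dataclass
class ModelSpec:
    """An ordered layer sequence plus the input shape it expects."""

    name: str
    input_shape: tuple
    layers: list[LayerSpec] = field(default_factory=list)

    def to_yaml(self) -> str:
        def layer_dict(layer: LayerSpec) -> dict:
            d = {k: v for k, v in asdict(layer).items() if v is not None}
            if layer.kernel is not None:
                d["kernel"] = {
                    "size": list(layer.kernel.size),
                    "stride": list(layer.kernel.stride),
                    "padding": list(layer.kernel.padding),
                }
            return d

        return yaml.safe_dump(
            {
                "name": self.name,
                "input_shape": list(self.input_shape),
                "layers": [layer_dict(l) for l in self.layers],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        payload = yaml.safe_load(text)
        layers = []
        for d in payload["layers"]:
            d = dict(d)
            if "kernel" in d:
                k = d["kernel"]
                d["kernel"] = KernelSpec(
                    size=tuple(k["size"]),
                    stride=tuple(k["stride"]),
                    padding=tuple(k["padding"]),
                )
            layers.append(LayerSpec(**d))
        return cls(
            name=payload["name"],
            input_shape=tuple(payload["input_shape"]),
            layers=layers,
        )


@dataclass(frozen=True)
class ShapeRecord:
    index: int
    kind: str
    input_shape: tuple
    output_shape: tuple


def _conv_axis(n: int, kernel: int, stride: int, pad: int, where: str) -> int:
    out = (n + 2 * pad - kernel) // stride + 1
    if out <= 0:
        raise ValueError(f"{where}: axis of size {n} collapses to {out}")
    return out


# ---------------------------------------------------------------------------
# shape propagation
# ---------------------------------------------------------------------------

def forward_shapes(spec: ModelSpec, input_shape: tuple | None = None) -> list[ShapeRecord]:
    """Symbolically propagate an input shape through every layer.

    Conv/pool axes follow floor((n + 2 pad - kernel)/stride) + 1; max pooling
    additionally requires the axis to tile exactly (the architectures here
    halve dimensions, so a remainder means the input is incompatible with
    the pooling cascade).
    """
    shape = tuple(input_shape if input_shape is not None else spec.input_shape)
    records: list[ShapeRecord] = []
    for i, layer in enumerate(spec.layers):
        where = f"layer {i} ({layer.kind})"
        if layer.kind == "conv3d":
            c, d, h, w = shape
            if c != layer.in_channels:
                raise ValueError(f"{where}: expected {layer.in_channels} channels, got {c}")
            k, s, p = layer.kernel.size, layer.kernel.stride, layer.kernel.padding
            out = (
                layer.out_channels,
                _conv_axis(d, k[0], s[0], p[0], where),
                _conv_axis(h, k[1], s[1], p[1], where),
                _conv_axis(w, k[2], s[2], p[2], where),
            )
        elif layer.kind == "maxpool3d":
            c, d, h, w = shape
            k, s, p = layer.kernel.size, layer.kernel.stride, layer.kernel.padding
            for n, kk, ss, pp, ax in zip((d, h, w), k, s, p, "DHW"):
                if (n + 2 * pp - kk) % ss != 0:
                    raise ValueError(
                        f"{where}: axis {ax} of size {n} not divisible by the pooling cascade"
                    )
            out = (
                c,
                _conv_axis(d, k[0], s[0], p[0], where),
                _conv_axis(h, k[1], s[1], p[1], where),
                _conv_axis(w, k[2], s[2], p[2], where),
            )
        elif layer.kind in ("batchnorm", "relu", "tanh", "dropout"):
            out = shape
        elif layer.kind == "flatten":
            n = 1
            for v in shape:
                n *= v
            out = (n,)
        elif layer.kind == "dense":
            if len(shape) != 1 or shape[0] != layer.in_features:
                raise ValueError(
                    f"{where}: expected a flat ({layer.in_features},) input, got {shape}"
                )
            out = (layer.out_features,)
        elif layer.kind == "lstm":
            t, f = shape
            if f != layer.input_size:
                raise ValueError(f"{where}: expected {layer.input_size} features, got {f}")
            out = (t, layer.hidden_size)
        elif layer.kind == "take_last":
            t, f = shape
            out = (f,)
        else:
            raise ValueError(f"{where}: unknown layer kind")
        records.append(ShapeRecord(i, layer.kind, shape, out))
        shape = out
    return records


def shape_table(spec: ModelSpec, input_shape: tuple | None = None) -> pd.DataFrame:
    """The per-layer shape table as a DataFrame (CSV-friendly)."""
    recs = forward_shapes(spec, input_shape)
    return pd.DataFrame(
        {
            "layer": [r.index for r in recs],
            "kind": [r.kind for r in recs],
            "input_shape": ["x".join(map(str, r.input_shape)) for r in recs],
            "output_shape": ["x".join(map(str, r.output_shape)) for r in recs],
        }
    )


def layer_census(spec: ModelSpec) -> Counter:
    """Multiset of layer kinds in the spec."""
    return Counter(layer.kind for layer in spec.layers)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

CONV_KERNEL = KernelSpec(size=(7, 3, 3), stride=(1, 1, 1), padding=(3, 1, 1))
POINT_KERNEL = KernelSpec(size=(1, 1, 1), stride=(1, 1, 1), padding=(0, 0, 0))
POOL_D = KernelSpec(size=(2, 1, 1), stride=(2, 1, 1))
POOL_DHW = KernelSpec(size=(2, 2, 2), stride=(2, 2, 2))

DEFAULT_BOTTLENECKS: tuple[tuple[int, int], ...] = (
    (16, 128), (32, 256), (64, 256), (64, 256), (64, 256),
)


def _conv_bn_relu(c_in: int, c_out: int, kernel: KernelSpec, bias: bool) -> list[LayerSpec]:
    return [
        LayerSpec("conv3d", in_channels=c_in, out_channels=c_out, kernel=kernel, bias=bias),
        LayerSpec("batchnorm", in_channels=c_out, out_channels=c_out),
        LayerSpec("relu"),
    ]


def _dense_block(in_features: int, hidden: int, dropout: float, n_out: int) -> list[LayerSpec]:
    return [
        LayerSpec("flatten"),
        LayerSpec("dense", in_features=in_features, out_features=hidden),
        LayerSpec("relu"),
        LayerSpec("dropout", rate=dropout),
        LayerSpec("dense", in_features=hidden, out_features=n_out),
    ]


def _flat_features(layers: list[LayerSpec], input_shape: tuple) -> int:
    out = forward_shapes(ModelSpec("probe", input_shape, layers))[-1].output_shape
    n = 1
    for v in out:
        n *= v
    return int(n)


def build_cnn_bn(
    input_shape: tuple = (1, 128, 64, 64),
    conv_channels: int = 64,
    bottlenecks: Sequence[tuple[int, int]] = DEFAULT_BOTTLENECKS,
    dense_hidden: int = 128,
    dropout: float = 0.5,
    conv_bias: bool = True,
    n_classes: int = 2,
) -> ModelSpec:
    """The channel-bottleneck 3D CNN.

    One convolution block (7x3x3 conv, BN, ReLU, 2x1x1 pool), five bottleneck
    blocks (1x1x1 reduce -> 7x3x3 -> 1x1x1 expand, each conv followed by BN
    and ReLU, then a 2x2x2 pool), and a two-layer dense head.  ``dense_hidden``
    is 128 in the training profile and 64 in the complexity-report profile.
    """
    layers: list[LayerSpec] = []
    layers += _conv_bn_relu(input_shape[0], conv_channels, CONV_KERNEL, conv_bias)
    layers.append(LayerSpec("maxpool3d", kernel=POOL_D))
    c_in = conv_channels
    for c_bn, c_out in bottlenecks:
        layers += _conv_bn_relu(c_in, c_bn, POINT_KERNEL, conv_bias)
        layers += _conv_bn_relu(c_bn, c_bn, CONV_KERNEL, conv_bias)
        layers += _conv_bn_relu(c_bn, c_out, POINT_KERNEL, conv_bias)
        layers.append(LayerSpec("maxpool3d", kernel=POOL_DHW))
        c_in = c_out
    flat = _flat_features(layers, input_shape)
    layers += _dense_block(flat, dense_hidden, dropout, n_classes)
    spec = ModelSpec("cnn-bn", tuple(input_shape), layers)
    forward_shapes(spec)  # validates the pooling cascade against the input
    return spec


def build_c3d(
    input_shape: tuple = (1, 128, 64, 64),
    channels: Sequence[int] = (64, 128, 256, 256, 256, 256),
    dense_hidden: int = 512,
    dropout: float = 0.5,
    conv_bias: bool = True,
    n_classes: int = 2,
) -> ModelSpec:
    """The plain 3D CNN baseline: six conv blocks, no bottlenecks.

    Every convolution is 7x3x3; the first block pools only temporally
    (2x1x1), the remaining five pool 2x2x2.
    """
    layers: list[LayerSpec] = []
    c_in = input_shape[0]
    for i, c_out in enumerate(channels):
        layers += _conv_bn_relu(c_in, c_out, CONV_KERNEL, conv_bias)
        layers.append(LayerSpec("maxpool3d", kernel=POOL_D if i == 0 else POOL_DHW))
        c_in = c_out
    flat = _flat_features(layers, input_shape)
    layers += _dense_block(flat, dense_hidden, dropout, n_classes)
    spec = ModelSpec("c3d", tuple(input_shape), layers)
    forward_shapes(spec)
    return spec


def build_lstm(
    seq_len: int = 128,
    input_features: int = 32,
    hidden_size: int = 128,
    n_layers: int = 3,
    dense_hidden: int = 128,
    dropout: float = 0.5,
    n_classes: int = 2,
) -> ModelSpec:
    """The stacked-LSTM baseline on raw 1-s segments (time steps x channels).

    Three recurrent layers, each followed by tanh; the last time step feeds
    a two-layer dense head.
    """
    if hidden_size <= 0:
        raise ValueError(f"hidden size must be positive, got {hidden_size}")
    layers: list[LayerSpec] = []
    in_size = input_features
    for _ in range(n_layers):
        layers.append(LayerSpec("lstm", input_size=in_size, hidden_size=hidden_size))
        layers.append(LayerSpec("tanh"))
        in_size = hidden_size
    layers.append(LayerSpec("take_last"))
    layers += [
        LayerSpec("dense", in_features=hidden_size, out_features=dense_hidden),
        LayerSpec("relu"),
        LayerSpec("dropout", rate=dropout),
        LayerSpec("dense", in_features=dense_hidden, out_features=n_classes),
    ]
    spec = ModelSpec("lstm", (seq_len, input_features), layers)
    forward_shapes(spec)
    return spec
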