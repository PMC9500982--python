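"""Trainable-parameter and FLOP accounting over model specs.

Counting conventions
--------------------
* Parameters: conv3d ``C_out C_in d k k (+ C_out bias)``; batch norm ``2 C``
  (scale and shift); dense ``out x in + out``; LSTM layer
  ``4 (h (in + h) + 2 h)`` (four gates, both bias vectors); activation,
  pooling, dropout and flatten layers carry none.
* FLOPs: one forward pass, 2 FLOPs per multiply-accumulate for conv and
  dense layers (biases not counted separately).  Elementwise add-ons are
  selectable: batch norm 2 ops/element, ReLU/tanh 1 op/element, max pooling
  ``kernel volume - 1`` comparisons per output element.  LSTM layers count
  2 x MACs of their gate products per time step.

Reported "millions"/"giga" figures are rounded half-up to two decimals, and
reduction percentages are computed from those rounded figures.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .architectures import ModelSpec, forward_shapes


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _require(layer, *fields):
    for f in fields:
        if getattr(layer, f) is None:
            raise ValueError(f"layer kind {layer.kind!r} has unresolved field {f!r}")


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter total of a fully resolved spec."""
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv3d":
            _require(layer, "in_channels", "out_channels", "kernel")
            total += layer.out_channels * layer.in_channels * layer.kernel.volume
            if layer.bias:
                total += layer.out_channels
        elif layer.kind == "batchnorm":
            _require(layer, "in_channels")
            total += 2 * layer.in_channels
        elif layer.kind == "dense":
            _require(layer, "in_features", "out_features")
            total += layer.out_features * layer.in_features + layer.out_features
        elif layer.kind == "lstm":
            _require(layer, "input_size", "hidden_size")
            h, n_in = layer.hidden_size, layer.input_size
            total += 4 * (h * (n_in + h) + 2 * h)
    return total


@dataclass
class FlopCount:
    """FLOPs of one forward pass, with a per-layer breakdown."""

    conv_dense: int
    elementwise: int
    include_elementwise: bool
    per_layer: pd.DataFrame

    @property
    def total(self) -> int:
        return self.conv_dense + (self.elementwise if self.include_elementwise else 0)

    def __int__(self) -> int:
        return self.total


def count_flops(
    spec: ModelSpec,
    input_shape: tuple | None = None,
    include_elementwise: bool = True,
) -> FlopCount:
    """Count forward-pass FLOPs under the 2 x MAC convention."""
    records = forward_shapes(spec, input_shape)
    rows = []
    conv_dense = 0
    elementwise = 0
    for layer, rec in zip(spec.layers, records):
        out_elems = int(np.prod(rec.output_shape))
        flops = 0
        kind = "conv_dense"
        if layer.kind == "conv3d":
            flops = 2 * out_elems * layer.in_channels * layer.kernel.volume
            conv_dense += flops
        elif layer.kind == "dense":
            flops = 2 * layer.out_features * layer.in_features
            conv_dense += flops
        elif layer.kind == "lstm":
            t = rec.input_shape[0]
            h, n_in = layer.hidden_size, layer.input_size
            flops = 2 * t * 4 * h * (n_in + h)
            conv_dense += flops
        elif layer.kind == "batchnorm":
            flops = 2 * out_elems
            kind = "elementwise"
            elementwise += flops
        elif layer.kind in ("relu", "tanh"):
            flops = out_elems
            kind = "elementwise"
            elementwise += flops
        elif layer.kind == "maxpool3d":
            flops = (layer.kernel.volume - 1) * out_elems
            kind = "elementwise"
            elementwise += flops
        rows.append({"layer": rec.index, "kind": layer.kind, "class": kind, "flops": flops})
    return FlopCount(conv_dense, elementwise, include_elementwise, pd.DataFrame(rows))


@dataclass
class ModelComplexity:
    name: str
    parameter_count: int
    flops: int
    parameter_breakdown: pd.DataFrame = field(repr=False)
    flop_breakdown: pd.DataFrame = field(repr=False)

    @property
    def parameters_millions(self) -> float:
        return _round2(self.parameter_count / 1e6)

    @property
    def flops_giga(self) -> float:
        return _round2(self.flops / 1e9)


@dataclass
class ComplexityReport:
    """Per-model totals plus baseline-vs-proposed reduction percentages."""

    models: dict[str, ModelComplexity]
    baseline: str
    proposed: str

    @staticmethod
    def _reduction(small: float, big: float, raw_small: float, raw_big: float) -> float:
        # rounded figures match how such tables are printed; fall back to the
        # raw totals when the baseline is below the rounding scale
        if big == 0:
            small, big = raw_small, raw_big
        return _round2(100.0 * (1.0 - small / big))

    @property
    def parameter_reduction_percent(self) -> float:
        base, prop = self.models[self.baseline], self.models[self.proposed]
        return self._reduction(prop.parameters_millions, base.parameters_millions,
                               prop.parameter_count, base.parameter_count)

    @property
    def flops_reduction_percent(self) -> float:
        base, prop = self.models[self.baseline], self.models[self.proposed]
        return self._reduction(prop.flops_giga, base.flops_giga,
                               prop.flops, base.flops)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "models": {
                name: {
                    "parameter_count": m.parameter_count,
                    "parameters_millions": m.parameters_millions,
                    "flops": m.flops,
                    "flops_giga": m.flops_giga,
                }
                for name, m in self.models.items()
            },
            "baseline": self.baseline,
            "proposed": self.proposed,
            "parameter_reduction_percent": self.parameter_reduction_percent,
            "flops_reduction_percent": self.flops_reduction_percent,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _parameter_breakdown(spec: ModelSpec) -> pd.DataFrame:
    rows = []
    for i, layer in enumerate(spec.layers):
        one = ModelSpec("probe", spec.input_shape, [layer])
        rows.append({"layer": i, "kind": layer.kind, "parameters": count_parameters(one)})
    return pd.DataFrame(rows)


def complexity_report(
    specs: Sequence[ModelSpec],
    input_shape: tuple | None = None,
    baseline: str | None = None,
    proposed: str | None = None,
    include_elementwise: bool = True,
) -> ComplexityReport:
    """Profile several specs and compare a (baseline, proposed) pair.

    The pair defaults to the first and last spec.  Reductions are computed
    from the two-decimal rounded millions/giga figures, matching how such
    tables are typically printed.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError(f"need at least 2 specs to compare, got {len(specs)}")
    models = {}
    for spec in specs:
        fc = count_flops(spec, input_shape, include_elementwise)
        models[spec.name] = ModelComplexity(
            name=spec.name,
            parameter_count=count_parameters(spec),
            flops=fc.total,
            parameter_breakdown=_parameter_breakdown(spec),
            flop_breakdown=fc.per_layer,
        )
    baseline = baseline or specs[0].name
    proposed = proposed or specs[-1].name
    return ComplexityReport(models=models, baseline=baseline, proposed=proposed)


def measure_inference_time(
    spec_or_model,
    input_shape: tuple | None = None,
    repeats: int = 10,
    warmup: int = 2,
    batch_size: int = 1,
    seed: int = 0,
) -> dict:
    """Median wall-clock per forward pass, in milliseconds.

    Hardware- and load-dependent; provided for orientation only, never as a
    validated quantity.
    """
    from .backend import NumpyModel

    if repeats <= 0:
        raise ValueError(f"repeats must be positive, got {repeats}")
    model = (
        spec_or_model
        if isinstance(spec_or_model, NumpyModel)
        else NumpyModel.from_spec(spec_or_model, seed=seed)
    )
    shape = tuple(input_shape if input_shape is not None else model.spec.input_shape)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((batch_size,) + shape)
    for _ in range(warmup):
        model.forward(x)
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model.forward(x)
        times.append((time.perf_counter() - t0) * 1e3)
    return {
        "median_ms": float(np.median(times)),
        "mean_ms": float(np.mean(times)),
        "min_ms": float(np.min(times)),
        "repeats": repeats,
        "batch_size": batch_size,
    }
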