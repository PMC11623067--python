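"""Declarative computation graph of the HierbaNet architecture.

The network is described as a DAG of :class:`LayerSpec` records rather than
framework layer objects, so that shape inference, parameter accounting and the
model summary are exact, auditable integer arithmetic.  The default
configuration (224x224x3 input, 3 classes, 2 feature-integration blocks,
base width 32) is the published architecture; ``num_blocks`` in {1, 2, 3}
covers the ablation variants and ``base_width`` scales every channel width
proportionally for desk-scale experiments.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable

LAYER_KINDS = frozenset(
    {
        "input",
        "conv",
        "batchnorm",
        "activation",
        "pool",
        "concat",
        "global_pool",
        "dropout",
        "dense",
    }
)

#: dropout probability at the network head
DROPOUT_RATE = 0.2


@dataclass(frozen=True)
class TensorShape:
    """Spatial extent and channel width of an activation, channels-last."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"TensorShape.{name} must be a positive integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)


@dataclass(frozen=True)
class LayerSpec:
    """One node of the architecture graph."""

    name: str
    kind: str
    inputs: tuple[str, ...] = ()
    kernel_h: int | None = None
    kernel_w: int | None = None
    filters: int | None = None
    stride: int = 1
    padding_mode: str = "same"
    rate: float | None = None  # dropout only

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "pool"):
            if not (self.kernel_h and self.kernel_w and self.kernel_h >= 1 and self.kernel_w >= 1):
                raise ValueError(f"{self.kind} layer {self.name!r} needs positive kernel sizes")
        if self.kind in ("conv", "dense") and (self.filters is None or self.filters < 1):
            raise ValueError(f"{self.kind} layer {self.name!r} needs a positive filter count")
        if self.kind == "input":
            if self.inputs:
                raise ValueError("input layer takes no inputs")
        elif self.kind == "concat":
            if len(self.inputs) < 2:
                raise ValueError(f"concat layer {self.name!r} needs >= 2 inputs")
        elif len(self.inputs) != 1:
            raise ValueError(f"{self.kind} layer {self.name!r} needs exactly 1 input")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding_mode != "same":
            raise ValueError("only 'same' padding is supported")


@dataclass
class ArchitectureGraph:
    """Ordered, acyclic collection of layers; insertion order is topological."""

    input_shape: TensorShape
    num_classes: int
    num_blocks: int = 2
    base_width: int = 32
    layers: list[LayerSpec] = field(default_factory=list)
    _by_name: dict[str, LayerSpec] = field(default_factory=dict, repr=False)

    def add(self, spec: LayerSpec) -> str:
        if spec.name in self._by_name:
            raise ValueError(f"duplicate layer name {spec.name!r}")
        for ref in spec.inputs:
            if ref not in self._by_name:
                raise KeyError(f"layer {spec.name!r} references unknown input {ref!r}")
        self.layers.append(spec)
        self._by_name[spec.name] = spec
        return spec.name

    def layer(self, name: str) -> LayerSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no layer named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def conv_layers(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "conv"]

    def census(self) -> dict[str, int]:
        """Count of layers per kind (the layer-taxonomy breakdown)."""
        out = {k: 0 for k in LAYER_KINDS}
        for l in self.layers:
            out[l.kind] += 1
        return out

    @property
    def output_layer(self) -> LayerSpec:
        return self.layers[-1]


@dataclass(frozen=True)
class LayerSummary:
    """One row of the convolutional-layer model summary."""

    name: str
    output_shape: TensorShape
    param_count: int
    kernel: str
    filters: int
    growth_rate: int


@dataclass(frozen=True)
class ParamAccount:
    """Trainable / non-trainable parameter breakdown of a graph."""

    per_layer: dict[str, tuple[int, int]]
    total: int
    trainable: int
    non_trainable: int


def conv_bn_act(
    graph: ArchitectureGraph,
    input_name: str,
    prefix: str,
    filters: int,
    kh: int,
    kw: int,
) -> str:
    """Append a conv -> batchnorm -> LeakyReLU triple; return the activation name.

    The convolution carries a bias, uses stride 1 and 'same' padding; batch
    normalisation is per-channel.
    """
    if filters < 1 or kh < 1 or kw < 1:
        raise ValueError("filters and kernel sizes must be positive")
    graph.layer(input_name)  # raises KeyError if unresolvable
    conv = graph.add(
        LayerSpec(name=prefix, kind="conv", inputs=(input_name,), kernel_h=kh, kernel_w=kw, filters=filters)
    )
    bn = graph.add(LayerSpec(name=f"{prefix}_BN", kind="batchnorm", inputs=(conv,)))
    return graph.add(LayerSpec(name=f"{prefix}_Act", kind="activation", inputs=(bn,)))


def _max_pool(graph: ArchitectureGraph, input_name: str, name: str) -> str:
    return graph.add(
        LayerSpec(name=name, kind="pool", inputs=(input_name,), kernel_h=2, kernel_w=2, stride=2)
    )


def feature_extraction_high_level(graph: ArchitectureGraph, input_name: str, block_prefix: str) -> str:
    """High-level module: four diversified kernels (1,3,5,7) -> concat -> three
    3x3 stages -> 2x2 pool.  Widths scale with ``graph.base_width``."""
    b = graph.base_width
    branches = []
    for i, k in enumerate((1, 3, 5, 7), start=1):
        branches.append(conv_bn_act(graph, input_name, f"{block_prefix}_HL_Conv{i}", 2 * b, k, k))
    cat = graph.add(LayerSpec(name=f"{block_prefix}_HL_Concat", kind="concat", inputs=tuple(branches)))
    x = conv_bn_act(graph, cat, f"{block_prefix}_HL_Conv5", 8 * b, 3, 3)
    x = conv_bn_act(graph, x, f"{block_prefix}_HL_Conv6", 8 * b, 3, 3)
    x = conv_bn_act(graph, x, f"{block_prefix}_HL_Conv7", 16 * b, 3, 3)
    return _max_pool(graph, x, f"{block_prefix}_HL_MaxPool")


def feature_extraction_low_level(graph: ArchitectureGraph, input_name: str, block_prefix: str) -> str:
    """Low-level module: one 3x3 conv stage and a 2x2 pool."""
    x = conv_bn_act(graph, input_name, f"{block_prefix}_LL_Conv1", 2 * graph.base_width, 3, 3)
    return _max_pool(graph, x, f"{block_prefix}_LL_MaxPool")


def feature_integration(graph: ArchitectureGraph, input_name: str, block_prefix: str) -> str:
    """One feature-integration block: both modules on the same input, outputs
    concatenated channel-wise (16b + 2b = 18b channels; spatial dims halved)."""
    hl = feature_extraction_high_level(graph, input_name, block_prefix)
    ll = feature_extraction_low_level(graph, input_name, block_prefix)
    return graph.add(LayerSpec(name=f"{block_prefix}_Concat", kind="concat", inputs=(hl, ll)))


def build_hierbanet(
    input_shape: TensorShape | tuple[int, int, int] = TensorShape(224, 224, 3),
    num_classes: int = 3,
    num_blocks: int = 2,
    base_width: int = 32,
) -> ArchitectureGraph:
    """Build the full architecture graph.

    Stem conv (base_width, 3x3) + pool; per block a feature-integration block
    followed by a trunk conv (18*base_width, 3x3) + pool; head is global
    average pool, dropout(0.2) and a softmax dense layer.
    """
    if not isinstance(input_shape, TensorShape):
        input_shape = TensorShape(*input_shape)
    if num_blocks not in (1, 2, 3):
        raise ValueError(f"num_blocks must be in {{1, 2, 3}}, got {num_blocks}")
    if num_classes < 2:
        raise ValueError(f"num_classes must be >= 2, got {num_classes}")
    if base_width < 1:
        raise ValueError("base_width must be >= 1")
    div = 2 ** (num_blocks + 1)
    if input_shape.height % div or input_shape.width % div:
        raise ValueError(
            f"input spatial dims {input_shape.height}x{input_shape.width} must be "
            f"divisible by {div} for {num_blocks} blocks"
        )

    g = ArchitectureGraph(
        input_shape=input_shape,
        num_classes=num_classes,
        num_blocks=num_blocks,
        base_width=base_width,
    )
    x = g.add(LayerSpec(name="Input", kind="input"))
    x = conv_bn_act(g, x, "Base_Conv1", base_width, 3, 3)
    x = _max_pool(g, x, "Base_MaxPool1")
    for i in range(1, num_blocks + 1):
        x = feature_integration(g, x, f"B{i}")
        x = conv_bn_act(g, x, f"Base_Conv{i + 1}", 18 * base_width, 3, 3)
        x = _max_pool(g, x, f"Base_MaxPool{i + 1}")
    x = g.add(LayerSpec(name="GAP", kind="global_pool", inputs=(x,)))
    x = g.add(LayerSpec(name="Dropout", kind="dropout", inputs=(x,), rate=DROPOUT_RATE))
    g.add(LayerSpec(name="Dense", kind="dense", inputs=(x,), filters=num_classes))
    return g


def infer_shapes(graph: ArchitectureGraph) -> dict[str, TensorShape]:
    """Output shape of every layer.

    Stride-1 'same' convolution preserves spatial dims; 2x2/stride-2 pooling
    maps d -> ceil(d/2); concatenation sums channels and requires matching
    spatial dims.
    """
    shapes: dict[str, TensorShape] = {}
    for l in graph.layers:
        if l.kind == "input":
            shapes[l.name] = graph.input_shape
            continue
        ins = [shapes[i] for i in l.inputs]
        s = ins[0]
        if l.kind == "conv":
            out = TensorShape(
                math.ceil(s.height / l.stride), math.ceil(s.width / l.stride), l.filters
            )
        elif l.kind == "pool":
            out = TensorShape(
                math.ceil(s.height / l.stride), math.ceil(s.width / l.stride), s.channels
            )
        elif l.kind == "concat":
            for other in ins[1:]:
                if (other.height, other.width) != (s.height, s.width):
                    raise ValueError(
                        f"concat {l.name!r}: spatial dims differ between inputs "
                        f"({s.height}x{s.width} vs {other.height}x{other.width})"
                    )
            out = TensorShape(s.height, s.width, sum(i.channels for i in ins))
        elif l.kind == "global_pool":
            out = TensorShape(1, 1, s.channels)
        elif l.kind == "dense":
            out = TensorShape(1, 1, l.filters)
        else:  # batchnorm, activation, dropout: shape-preserving
            out = s
        shapes[l.name] = out
    return shapes


def count_parameters(graph: ArchitectureGraph) -> ParamAccount:
    """Exact per-layer parameter accounting.

    conv: filters*(kh*kw*in_channels + 1) trainable; batchnorm: 2C trainable
    (scale, shift) + 2C non-trainable (running mean, variance); dense:
    classes*(in+1) trainable; all other layers parameter-free.
    """
    shapes = infer_shapes(graph)
    per_layer: dict[str, tuple[int, int]] = {}
    for l in graph.layers:
        trainable = non_trainable = 0
        if l.kind == "conv":
            cin = shapes[l.inputs[0]].channels
            trainable = l.filters * (l.kernel_h * l.kernel_w * cin + 1)
        elif l.kind == "batchnorm":
            c = shapes[l.inputs[0]].channels
            trainable = 2 * c
            non_trainable = 2 * c
        elif l.kind == "dense":
            cin = shapes[l.inputs[0]].channels
            trainable = l.filters * (cin + 1)
        per_layer[l.name] = (trainable, non_trainable)
    trainable = sum(t for t, _ in per_layer.values())
    non_trainable = sum(n for _, n in per_layer.values())
    return ParamAccount(
        per_layer=per_layer,
        total=trainable + non_trainable,
        trainable=trainable,
        non_trainable=non_trainable,
    )


def summarize(graph: ArchitectureGraph) -> list[LayerSummary]:
    """Model summary: one row per conv layer in topological order, with the
    cumulative feature-map growth rate (running sum of conv output channels)."""
    shapes = infer_shapes(graph)
    account = count_parameters(graph)
    rows: list[LayerSummary] = []
    growth = 0
    for l in graph.layers:
        if l.kind != "conv":
            continue
        growth += l.filters
        rows.append(
            LayerSummary(
                name=l.name,
                output_shape=shapes[l.name],
                param_count=account.per_layer[l.name][0],
                kernel=f"{l.kernel_h}x{l.kernel_w}",
                filters=l.filters,
                growth_rate=growth,
            )
        )
    return rows


SUMMARY_CSV_COLUMNS = ("name", "out_h", "out_w", "out_c", "params", "kernel", "filters", "growth")


def summary_to_csv(rows: Iterable[LayerSummary], fh=None) -> str:
    """Serialize a model summary to CSV (columns mirroring the summary table)."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(SUMMARY_CSV_COLUMNS)
    for r in rows:
        w.writerow(
            [
                r.name,
                r.output_shape.height,
                r.output_shape.width,
                r.output_shape.channels,
                r.param_count,
                r.kernel,
                r.filters,
                r.growth_rate,
            ]
        )
    text = buf.getvalue()
    if fh is not None:
        fh.write(text)
    return text


def graph_to_text(graph: ArchitectureGraph) -> str:
    """Human-readable key-value serialization, one record per layer."""
    lines = [
        f"input_shape: {graph.input_shape.height} {graph.input_shape.width} {graph.input_shape.channels}",
        f"num_classes: {graph.num_classes}",
        f"num_blocks: {graph.num_blocks}",
        f"base_width: {graph.base_width}",
        "",
    ]
    for l in graph.layers:
        lines.append(f"layer: {l.name}")
        lines.append(f"  kind: {l.kind}")
        if l.inputs:
            lines.append(f"  inputs: {' '.join(l.inputs)}")
        if l.kind in ("conv", "pool"):
            lines.append(f"  kernel: {l.kernel_h} {l.kernel_w}")
            lines.append(f"  stride: {l.stride}")
        if l.filters is not None:
            lines.append(f"  filters: {l.filters}")
        if l.rate is not None:
            lines.append(f"  rate: {l.rate}")
        lines.append("")
    return "\n".join(lines)


def graph_from_text(text: str) -> ArchitectureGraph:
    """Inverse of :func:`graph_to_text`."""
    header: dict[str, str] = {}
    records: list[dict[str, str]] = []
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip():
            continue
        key, _, value = line.strip().partition(":")
        key, value = key.strip(), value.strip()
        if key == "layer":
            current = {"name": value}
            records.append(current)
        elif current is not None:
            current[key] = value
        else:
            header[key] = value
    h, w, c = (int(v) for v in header["input_shape"].split())
    g = ArchitectureGraph(
        input_shape=TensorShape(h, w, c),
        num_classes=int(header["num_classes"]),
        num_blocks=int(header.get("num_blocks", 2)),
        base_width=int(header.get("base_width", 32)),
    )
    for rec in records:
        kernel = rec.get("kernel")
        kh = kw = None
        if kernel:
            kh, kw = (int(v) for v in kernel.split())
        g.add(
            LayerSpec(
                name=rec["name"],
                kind=rec["kind"],
                inputs=tuple(rec.get("inputs", "").split()) if rec.get("inputs") else (),
                kernel_h=kh,
                kernel_w=kw,
                filters=int(rec["filters"]) if "filters" in rec else None,
                stride=int(rec.get("stride", 1)),
                rate=float(rec["rate"]) if "rate" in rec else None,
            )
        )
    return g
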