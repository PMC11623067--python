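"""Reference numerical semantics of every layer, in plain float64 NumPy.

These kernels define *what* each layer computes — cross-correlation with
'same' zero padding, per-channel batch normalisation with stabiliser
c = 0.001, LeakyReLU with slope 0.001, 2x2/stride-2 max pooling, global
average pooling, softmax head, inverted dropout — independent of any
accelerated framework.  They execute the whole architecture graph at
inference time via :func:`forward`; the batched training engine in
:mod:`hierbanet.nn` is tested against them.

Convolution follows the deep-learning convention (cross-correlation, no
kernel flip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ArchitectureGraph

#: batch-normalisation stabilising constant
BN_EPSILON = 1e-3
#: LeakyReLU negative slope
LEAKY_SLOPE = 1e-3


@dataclass
class ConvParams:
    """Convolution weights indexed (kh, kw, in_channel, out_channel) + bias."""

    f: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.f.ndim != 4:
            raise ValueError("kernel must be 4-d (kh, kw, cin, cout)")
        if self.bias.shape != (self.f.shape[3],):
            raise ValueError("bias length must equal the number of output channels")
        if not (np.all(np.isfinite(self.f)) and np.all(np.isfinite(self.bias))):
            raise ValueError("convolution parameters must be finite")


@dataclass
class BatchNormParams:
    """Per-channel batch-normalisation quantities.

    Output per channel is ``p1 * (x - b_m) / sqrt(b_v2 + c) + p2``.
    """

    b_m: np.ndarray
    b_v2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    c: float = BN_EPSILON

    def __post_init__(self) -> None:
        for name in ("b_m", "b_v2", "p1", "p2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.b_v2 < 0):
            raise ValueError("batch variance must be non-negative")
        if self.c <= 0:
            raise ValueError("stabilising constant must be positive")


def _same_pad_amounts(dim: int, k: int, stride: int) -> tuple[int, int]:
    """'Same' padding: output = ceil(dim/stride); extra padding goes after."""
    total = max((int(np.ceil(dim / stride)) - 1) * stride + k - dim, 0)
    before = total // 2
    return before, total - before


def conv2d_same(x: np.ndarray, params: ConvParams, stride: int = 1) -> np.ndarray:
    """Cross-correlate a (H, W, C) tensor with zero 'same' padding + bias."""
    x = np.asarray(x, dtype=np.float64)
    kh, kw, cin, cout = params.f.shape
    if x.ndim != 3 or x.shape[2] != cin:
        raise ValueError(
            f"input has {x.shape[2] if x.ndim == 3 else '?'} channels, kernel expects {cin}"
        )
    h, w = x.shape[:2]
    pt, pb = _same_pad_amounts(h, kh, stride)
    pl, pr = _same_pad_amounts(w, kw, stride)
    xp = np.pad(x, ((pt, pb), (pl, pr), (0, 0)))
    oh, ow = int(np.ceil(h / stride)), int(np.ceil(w / stride))
    out = np.broadcast_to(params.bias, (oh, ow, cout)).copy()
    for i in range(kh):
        for j in range(kw):
            patch = xp[i : i + (oh - 1) * stride + 1 : stride, j : j + (ow - 1) * stride + 1 : stride, :]
            out += patch @ params.f[i, j]
    return out


def batch_norm(x: np.ndarray, params: BatchNormParams) -> np.ndarray:
    """Normalise each channel with the given statistics, then scale and shift."""
    x = np.asarray(x, dtype=np.float64)
    if params.b_m.shape[-1] != x.shape[-1]:
        raise ValueError("per-channel parameter length must equal the channel count")
    return params.p1 * (x - params.b_m) / np.sqrt(params.b_v2 + params.c) + params.p2


def leaky_relu(x: np.ndarray, alpha: float = LEAKY_SLOPE) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, alpha * x)


def max_pool(x: np.ndarray, size: int = 2, stride: int = 2) -> np.ndarray:
    """Per-channel max over 'same'-padded windows; even dims map d -> d/2."""
    x = np.asarray(x, dtype=np.float64)
    h, w, c = x.shape
    pt, pb = _same_pad_amounts(h, size, stride)
    pl, pr = _same_pad_amounts(w, size, stride)
    xp = np.pad(x, ((pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
    oh, ow = int(np.ceil(h / stride)), int(np.ceil(w / stride))
    out = np.full((oh, ow, c), -np.inf)
    for i in range(size):
        for j in range(size):
            patch = xp[i : i + (oh - 1) * stride + 1 : stride, j : j + (ow - 1) * stride + 1 : stride, :]
            out = np.maximum(out, patch)
    return out


def global_average_pool(x: np.ndarray) -> np.ndarray:
    """Spatial mean of each feature map: (H, W, C) -> vector of length C."""
    x = np.asarray(x, dtype=np.float64)
    return x.mean(axis=(0, 1))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dense_softmax(features: np.ndarray, weights: np.ndarray, bias: np.ndarray, num_classes: int) -> np.ndarray:
    """Affine map followed by softmax; returns a probability vector."""
    features = np.asarray(features, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (features.shape[-1], num_classes):
        raise ValueError(
            f"weight matrix shape {weights.shape} incompatible with "
            f"({features.shape[-1]}, {num_classes})"
        )
    return softmax(features @ weights + bias)


def dropout(
    x: np.ndarray, rate: float = 0.2, training: bool = False, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Inverted dropout: identity at inference; kept units scaled by 1/(1-rate)."""
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    x = np.asarray(x, dtype=np.float64)
    if not training or rate == 0:
        return x.copy()
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = rng.random(x.shape) >= rate
    return x * mask / (1.0 - rate)


def forward(
    graph: ArchitectureGraph,
    params: dict[str, dict[str, np.ndarray]],
    image: np.ndarray,
    return_activations: bool = False,
):
    """Execute the graph in inference mode on one (H, W, C) image.

    ``params`` maps layer name -> arrays ({"W", "b"} for conv/dense;
    {"gamma", "beta", "running_mean", "running_var"} for batchnorm).
    Returns the class-probability vector, optionally with every intermediate
    activation.
    """
    image = np.asarray(image, dtype=np.float64)
    acts: dict[str, np.ndarray] = {}
    for layer in graph.layers:
        if layer.kind in ("conv", "batchnorm", "dense") and layer.name not in params:
            raise KeyError(f"missing parameters for layer {layer.name!r}")
        if layer.kind == "input":
            if image.shape != graph.input_shape.as_tuple():
                raise ValueError(
                    f"image shape {image.shape} != graph input {graph.input_shape.as_tuple()}"
                )
            acts[layer.name] = image
        elif layer.kind == "conv":
            p = params[layer.name]
            acts[layer.name] = conv2d_same(
                acts[layer.inputs[0]], ConvParams(p["W"], p["b"]), stride=layer.stride
            )
        elif layer.kind == "batchnorm":
            p = params[layer.name]
            acts[layer.name] = batch_norm(
                acts[layer.inputs[0]],
                BatchNormParams(p["running_mean"], p["running_var"], p["gamma"], p["beta"]),
            )
        elif layer.kind == "activation":
            acts[layer.name] = leaky_relu(acts[layer.inputs[0]])
        elif layer.kind == "pool":
            acts[layer.name] = max_pool(acts[layer.inputs[0]], layer.kernel_h, layer.stride)
        elif layer.kind == "concat":
            acts[layer.name] = np.concatenate([acts[i] for i in layer.inputs], axis=2)
        elif layer.kind == "global_pool":
            acts[layer.name] = global_average_pool(acts[layer.inputs[0]])
        elif layer.kind == "dropout":
            acts[layer.name] = dropout(acts[layer.inputs[0]], layer.rate, training=False)
        elif layer.kind == "dense":
            p = params[layer.name]
            acts[layer.name] = dense_softmax(acts[layer.inputs[0]], p["W"], p["b"], layer.filters)
    probs = acts[graph.output_layer.name]
    return (probs, acts) if return_activations else probs


def predict_class(probs: np.ndarray) -> int:
    """Argmax prediction; ties break toward the lowest class index."""
    return int(np.argmax(probs))
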