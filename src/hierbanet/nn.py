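"""Batched execution engine: vectorised forward/backward passes and Adam.

This is the performance path used for training.  Semantics are defined by the
single-image reference kernels in :mod:`hierbanet.ops` (the two are compared
in the test suite); here every operator works on (N, H, W, C) float64 batches
and carries an analytic backward pass.

Batch normalisation uses per-batch statistics during training and exponential
running averages (momentum 0.99) at inference; the running statistics are
updated in place on the parameter dictionary during training forward passes.
"""

from __future__ import annotations

import copy

import numpy as np

from .graph import ArchitectureGraph, infer_shapes
from .ops import BN_EPSILON, LEAKY_SLOPE

BN_MOMENTUM = 0.99

Params = dict[str, dict[str, np.ndarray]]


# ---------------------------------------------------------------- operators

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation on a batch (odd kernels)."""
    kh, kw, cin, cout = W.shape
    n, h, w, _ = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    out = np.empty((n, h, w, cout))
    out[:] = b
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + h, j : j + w, :] @ W[i, j]
    return out


def _conv_backward(dout, x, W):
    kh, kw, cin, cout = W.shape
    n, h, w, _ = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i : i + h, j : j + w, :]
            dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + h, j : j + w, :] += dout @ W[i, j].T
    db = dout.sum(axis=(0, 1, 2))
    dx = dxp[:, ph : ph + h, pw : pw + w, :]
    return dx, dW, db


def _bn_forward_train(x, gamma, beta):
    m = x.shape[0] * x.shape[1] * x.shape[2]
    mean = x.mean(axis=(0, 1, 2))
    var = x.var(axis=(0, 1, 2))  # biased
    ivar = 1.0 / np.sqrt(var + BN_EPSILON)
    xhat = (x - mean) * ivar
    out = gamma * xhat + beta
    return out, (xhat, ivar, gamma, m), mean, var


def _bn_backward(dout, cache):
    xhat, ivar, gamma, m = cache
    dgamma = (dout * xhat).sum(axis=(0, 1, 2))
    dbeta = dout.sum(axis=(0, 1, 2))
    dxhat = dout * gamma
    dx = (ivar / m) * (
        m * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
    )
    return dx, dgamma, dbeta


def _pool_forward(x):
    """2x2 stride-2 max pool with -inf 'same' padding to even dims."""
    n, h, w, c = x.shape
    oh, ow = -(-h // 2), -(-w // 2)
    xp = np.pad(x, ((0, 0), (0, 2 * oh - h), (0, 2 * ow - w), (0, 0)), constant_values=-np.inf)
    win = (
        xp.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout, cache):
    idx, (n, h, w, c) = cache
    oh, ow = -(-h // 2), -(-w // 2)
    dwin = np.zeros((n, oh, ow, c, 4))
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    dxp = dwin.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, 2 * oh, 2 * ow, c
    )
    return dxp[:, :h, :w, :]


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------- executor

def forward_batch(
    graph: ArchitectureGraph,
    params: Params,
    x: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    capture: set[str] | None = None,
):
    """Run the graph on a (N, H, W, C) batch.

    Returns ``(probs, caches)``; ``caches`` holds what backward needs (and any
    activations named in ``capture``).  In training mode batchnorm running
    statistics in ``params`` are updated in place.
    """
    acts: dict[str, np.ndarray] = {}
    caches: dict[str, object] = {"__captured__": {}}
    for layer in graph.layers:
        if layer.kind == "input":
            out = np.asarray(x, dtype=np.float64)
        elif layer.kind == "conv":
            p = params[layer.name]
            xin = acts[layer.inputs[0]]
            out = _conv_forward(xin, p["W"], p["b"])
            caches[layer.name] = xin
        elif layer.kind == "batchnorm":
            p = params[layer.name]
            xin = acts[layer.inputs[0]]
            if training:
                out, cache, mean, var = _bn_forward_train(xin, p["gamma"], p["beta"])
                # bias-corrected EMA of batch statistics: exact at small step
                # counts, converges to the plain momentum-0.99 EMA
                ema_m = p.setdefault("ema_mean", np.zeros_like(mean))
                ema_v = p.setdefault("ema_var", np.zeros_like(var))
                steps = p.setdefault("ema_steps", np.zeros(1))
                ema_m *= BN_MOMENTUM
                ema_m += (1 - BN_MOMENTUM) * mean
                ema_v *= BN_MOMENTUM
                ema_v += (1 - BN_MOMENTUM) * var
                steps += 1
                corr = 1.0 - BN_MOMENTUM ** steps[0]
                p["running_mean"] = ema_m / corr
                p["running_var"] = ema_v / corr
                caches[layer.name] = cache
            else:
                out = p["gamma"] * (xin - p["running_mean"]) / np.sqrt(
                    p["running_var"] + BN_EPSILON
                ) + p["beta"]
        elif layer.kind == "activation":
            xin = acts[layer.inputs[0]]
            out = np.where(xin > 0, xin, LEAKY_SLOPE * xin)
            caches[layer.name] = xin > 0
        elif layer.kind == "pool":
            out, cache = _pool_forward(acts[layer.inputs[0]])
            caches[layer.name] = cache
        elif layer.kind == "concat":
            parts = [acts[i] for i in layer.inputs]
            out = np.concatenate(parts, axis=3)
            caches[layer.name] = [p.shape[3] for p in parts]
        elif layer.kind == "global_pool":
            xin = acts[layer.inputs[0]]
            out = xin.mean(axis=(1, 2))
            caches[layer.name] = xin.shape
        elif layer.kind == "dropout":
            xin = acts[layer.inputs[0]]
            if training and layer.rate:
                mask = rng.random(xin.shape) >= layer.rate
                out = xin * mask / (1.0 - layer.rate)
                caches[layer.name] = mask / (1.0 - layer.rate)
            else:
                out = xin
                caches[layer.name] = None
        elif layer.kind == "dense":
            p = params[layer.name]
            xin = acts[layer.inputs[0]]
            out = _softmax(xin @ p["W"] + p["b"])
            caches[layer.name] = xin
        acts[layer.name] = out
        if capture and layer.name in capture:
            caches["__captured__"][layer.name] = out
    return acts[graph.output_layer.name], caches


def backward_batch(
    graph: ArchitectureGraph, params: Params, caches: dict, probs: np.ndarray, y_onehot: np.ndarray
) -> Params:
    """Gradients of mean categorical cross-entropy w.r.t. all trainable params."""
    n = probs.shape[0]
    grads: Params = {}
    upstream: dict[str, np.ndarray] = {}

    def push(name: str, g: np.ndarray) -> None:
        if name in upstream:
            upstream[name] = upstream[name] + g
        else:
            upstream[name] = g

    for layer in reversed(graph.layers):
        if layer.kind == "dense":
            # softmax + cross-entropy combined gradient
            dz = (probs - y_onehot) / n
            xin = caches[layer.name]
            grads[layer.name] = {"W": xin.T @ dz, "b": dz.sum(axis=0)}
            push(layer.inputs[0], dz @ params[layer.name]["W"].T)
            continue
        if layer.kind == "input" or layer.name not in upstream:
            continue
        g = upstream.pop(layer.name)
        if layer.kind == "conv":
            dx, dW, db = _conv_backward(g, caches[layer.name], params[layer.name]["W"])
            grads[layer.name] = {"W": dW, "b": db}
            push(layer.inputs[0], dx)
        elif layer.kind == "batchnorm":
            dx, dgamma, dbeta = _bn_backward(g, caches[layer.name])
            grads[layer.name] = {"gamma": dgamma, "beta": dbeta}
            push(layer.inputs[0], dx)
        elif layer.kind == "activation":
            pos = caches[layer.name]
            push(layer.inputs[0], np.where(pos, g, LEAKY_SLOPE * g))
        elif layer.kind == "pool":
            push(layer.inputs[0], _pool_backward(g, caches[layer.name]))
        elif layer.kind == "concat":
            widths = caches[layer.name]
            offsets = np.cumsum([0] + widths)
            for inp, a, b in zip(layer.inputs, offsets[:-1], offsets[1:]):
                push(inp, g[..., a:b])
        elif layer.kind == "global_pool":
            _, h, w, _ = caches[layer.name]
            push(layer.inputs[0], np.broadcast_to(g[:, None, None, :] / (h * w), caches[layer.name]))
        elif layer.kind == "dropout":
            scale = caches[layer.name]
            push(layer.inputs[0], g if scale is None else g * scale)
    return grads


def cross_entropy(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, None)
    return float(-(y_onehot * np.log(p)).sum(axis=1).mean())


def evaluate_batch(graph: ArchitectureGraph, params: Params, x, y) -> tuple[float, float, np.ndarray]:
    """Inference pass: (loss, accuracy, probs) on a labelled batch."""
    probs, _ = forward_batch(graph, params, x, training=False)
    y_onehot = np.eye(probs.shape[1])[y]
    loss = cross_entropy(probs, y_onehot)
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc, probs


def check_params(graph: ArchitectureGraph, params: Params) -> None:
    """Validate that params are complete and shape-consistent with the graph.

    Raises KeyError / ValueError naming the offending layer.
    """
    shapes = infer_shapes(graph)
    for layer in graph.layers:
        if layer.kind == "conv":
            if layer.name not in params:
                raise KeyError(f"missing parameters for layer {layer.name!r}")
            cin = shapes[layer.inputs[0]].channels
            want = (layer.kernel_h, layer.kernel_w, cin, layer.filters)
            got = params[layer.name]["W"].shape
            if got != want:
                raise ValueError(f"layer {layer.name!r}: weight shape {got} != expected {want}")
        elif layer.kind == "batchnorm":
            if layer.name not in params:
                raise KeyError(f"missing parameters for layer {layer.name!r}")
            c = shapes[layer.inputs[0]].channels
            if params[layer.name]["gamma"].shape != (c,):
                raise ValueError(
                    f"layer {layer.name!r}: batchnorm width "
                    f"{params[layer.name]['gamma'].shape} != expected ({c},)"
                )
        elif layer.kind == "dense":
            if layer.name not in params:
                raise KeyError(f"missing parameters for layer {layer.name!r}")
            cin = shapes[layer.inputs[0]].channels
            if params[layer.name]["W"].shape != (cin, layer.filters):
                raise ValueError(
                    f"layer {layer.name!r}: dense shape {params[layer.name]['W'].shape} "
                    f"!= expected ({cin}, {layer.filters})"
                )


def clone_params(params: Params) -> Params:
    return copy.deepcopy(params)


class Adam:
    """Adam optimiser (lr 0.001, beta1 0.9, beta2 0.999, epsilon 1e-7)."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(v) for n, v in d.items()} for k, d in params.items()}
        self.v = {k: {n: np.zeros_like(v) for n, v in d.items()} for k, d in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        bc1 = 1 - self.beta1**self.t
        bc2 = 1 - self.beta2**self.t
        for lname, d in grads.items():
            for pname, g in d.items():
                m = self.m[lname][pname]
                v = self.v[lname][pname]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                params[lname][pname] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
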