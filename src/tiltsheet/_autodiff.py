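"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small recurrent convolutional restoration
network: stride-1 'same' 2D convolution (batched BLAS matmuls over
kernel-tap slices), batch normalization, the usual pointwise
nonlinearities, channel concatenation/slicing, and a mean-squared-error
head, plus an Adam optimizer.  Tensors are NCHW float32.

The tape is implicit: every op closes over its parents and an accumulate-
into-parent backward function; ``Tensor.backward`` runs a topological sort.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "tanh",
    "concat_channels",
    "slice_channels",
    "conv2d",
    "batchnorm2d",
    "mse",
    "Adam",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None  # intermediate grads are consumed; free them

    def zero_graph_grads(self):
        """Clear grads on every node reachable from this tensor."""
        stack = [self]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            node.grad = None
            stack.extend(node._parents)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(gy):
        if a.requires_grad:
            a._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(gy):
        if a.requires_grad:
            a._accumulate(gy * b.data)
        if b.requires_grad:
            b._accumulate(gy * a.data)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy * (1.0 - out_data**2))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(gy):
        start = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(gy[:, start : start + c])
            start += c

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out_data = x.data[:, start:stop]

    def backward(gy):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[:, start:stop] = gy
            x._accumulate(g)

    return Tensor(out_data, parents=(x,), backward=backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same' convolution; weight is (C_out, C_in, kh, kw), kh/kw odd.

    Computed as one batched channel-mixing matmul per kernel tap on shifted
    slices of the padded input — all BLAS, no patch-matrix gather.
    """
    co, ci, kh, kw = weight.data.shape
    n, _, h, w = x.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def tap(i, j):
        # contiguous (n, ci, h*w) view of the (i, j)-shifted input; built on
        # demand rather than cached, keeping graph memory at one padded copy
        return np.ascontiguousarray(xp[:, :, i : i + h, j : j + w]).reshape(
            n, ci, h * w
        )

    out_flat = np.zeros((n, co, h * w), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out_flat += np.matmul(weight.data[:, :, i, j], tap(i, j))
    out_data = out_flat.reshape(n, co, h, w)
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    def backward(gy):
        gyf = gy.reshape(n, co, h * w)
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.matmul(
                        gyf, tap(i, j).transpose(0, 2, 1)
                    ).sum(axis=0)
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gyf.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            wt = weight.data.transpose(1, 0, 2, 3)  # C_in, C_out, kh, kw
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + w] += np.matmul(
                        wt[:, :, i, j], gyf
                    ).reshape(n, ci, h, w)
            x._accumulate(dxp[:, :, ph : ph + h, pw : pw + w])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=backward)


class BatchNormState:
    """Running statistics carried outside the autodiff graph."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps


def batchnorm2d(
    x: Tensor, gamma: Tensor, beta: Tensor, state: BatchNormState, training: bool
) -> Tensor:
    eps = state.eps
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        state.running_mean = (
            (1 - state.momentum) * state.running_mean + state.momentum * mu
        ).astype(np.float32)
        state.running_var = (
            (1 - state.momentum) * state.running_var + state.momentum * var
        ).astype(np.float32)
    else:
        mu = state.running_mean
        var = state.running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gy):
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                mean_gy = gy.mean(axis=(0, 2, 3), keepdims=True)
                mean_gy_xhat = (gy * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(g * (gy - mean_gy - xhat * mean_gy_xhat))
            else:
                x._accumulate(g * gy)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def mse(pred: Tensor, target: Tensor) -> Tensor:
    diff = pred.data - target.data
    out_data = np.mean(diff**2)

    def backward(gy):
        if pred.requires_grad:
            pred._accumulate(gy * 2.0 * diff / diff.size)

    return Tensor(out_data, parents=(pred,), backward=backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                np.float32
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None
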