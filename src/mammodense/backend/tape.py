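"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation networks need: 2-D
convolution with stride and dilation, transposed convolution (as
zero-stuffing followed by convolution), batch normalization, ReLU,
dropout and channel concatenation.  Tensors are NCHW ``float32``.

Gradients are accumulated by walking the tape in reverse topological
order.  Wrapping a forward pass in :func:`no_grad` skips closure
creation entirely, which also releases the im2col buffers immediately
(important for full-resolution inference).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
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

    def backward(self, grad):
        """Backpropagate ``grad`` (same shape as ``data``) through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _result(data, parents, backward_factory):
    """Build an op result; attach a backward closure only when tracking."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out = Tensor(data, requires_grad=True, parents=tuple(parents))
        out._backward = backward_factory(out)
        return out
    return Tensor(data)


def _pad_pair(padding):
    if isinstance(padding, int):
        return (padding, padding), (padding, padding)
    (pt, pb), (pl, pr) = padding
    return (pt, pb), (pl, pr)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           dilation: int = 1, padding=0) -> Tensor:
    """Cross-correlation of NCHW input with OIHW weights.

    ``padding`` is an int or ``((top, bottom), (left, right))``; dilation
    spaces the kernel taps ``dilation`` pixels apart (atrous convolution).
    """
    N, C, H, W = x.data.shape
    Cout, Cin, k, k2 = w.data.shape
    if k != k2:
        raise ValueError("kernel must be square")
    if Cin != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cin}")
    (pt, pb), (pl, pr) = _pad_pair(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    eff = k + (k - 1) * (dilation - 1)
    Hp, Wp = xp.shape[2], xp.shape[3]
    if Hp < eff or Wp < eff:
        raise ValueError(f"effective kernel {eff} exceeds padded input {Hp}x{Wp}")
    OH = (Hp - eff) // stride + 1
    OW = (Wp - eff) // stride + 1

    win = sliding_window_view(xp, (eff, eff), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * OH * OW, C * k * k)
    Wm = w.data.reshape(Cout, C * k * k)
    out = cols @ Wm.T
    if b is not None:
        out += b.data
    out = np.ascontiguousarray(out.reshape(N, OH, OW, Cout).transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)

    def factory(out_t):
        cols_ref = cols  # kept alive only when gradients are tracked

        def backward(g):
            gm = g.transpose(0, 2, 3, 1).reshape(N * OH * OW, Cout)
            if w.requires_grad:
                w._accumulate((gm.T @ cols_ref).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(gm.sum(axis=0))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        # grad w.r.t. the input pixels tapped at (i, j)
                        dtap = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                        dtap = dtap.transpose(0, 3, 1, 2)
                        hi = i * dilation
                        wj = j * dilation
                        dxp[:, :, hi:hi + stride * OH:stride,
                            wj:wj + stride * OW:stride] += dtap
                x._accumulate(dxp[:, :, pt:pt + H, pl:pl + W])

        return backward

    return _result(out, parents, factory)


def zero_stuff(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between input pixels along H and W."""
    if stride == 1:
        return x
    N, C, H, W = x.data.shape
    out = np.zeros((N, C, (H - 1) * stride + 1, (W - 1) * stride + 1),
                   dtype=np.float32)
    out[:, :, ::stride, ::stride] = x.data

    def factory(out_t):
        def backward(g):
            if x.requires_grad:
                x._accumulate(g[:, :, ::stride, ::stride])
        return backward

    return _result(out, (x,), factory)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 2) -> Tensor:
    """3x3 stride-2 transposed convolution doubling the spatial side.

    Implemented as zero-stuffing followed by a standard convolution with
    asymmetric padding so that output side = ``stride * input side``.
    """
    k = w.data.shape[2]
    stuffed = zero_stuff(x, stride)
    # target side = stride*H; stuffed side = stride*H - (stride-1)
    # valid conv removes k-1, so pad by k-1 + (stride-1) total per axis
    total = (k - 1) + (stride - 1)
    lead = (k - 1) // 2
    pad = ((lead, total - lead), (lead, total - lead))
    return conv2d(stuffed, w, b, stride=1, dilation=1, padding=pad)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)

    def factory(out_t):
        mask = x.data > 0

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * mask)
        return backward

    return _result(out, (x,), factory)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = x.data * keep

    def factory(out_t):
        def backward(g):
            if x.requires_grad:
                x._accumulate(g * keep)
        return backward

    return _result(out, (x,), factory)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def factory(out_t):
        def backward(g):
            off = 0
            for t, c in zip(tensors, sizes):
                if t.requires_grad:
                    t._accumulate(g[:, off:off + c])
                off += c
        return backward

    return _result(out, tuple(tensors), factory)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, *, momentum: float = 0.1, eps: float = 1e-5,
               training: bool = True) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are plain float32 arrays updated in
    place during training and used verbatim at inference.
    """
    g4 = gamma.data.reshape(1, -1, 1, 1)
    b4 = beta.data.reshape(1, -1, 1, 1)
    if not training:
        inv = 1.0 / np.sqrt(running_var.reshape(1, -1, 1, 1) + eps)
        xhat = (x.data - running_mean.reshape(1, -1, 1, 1)) * inv
        out = g4 * xhat + b4

        def factory_eval(out_t):
            def backward(grad):
                if gamma.requires_grad:
                    gamma._accumulate((grad * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accumulate(grad.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    x._accumulate(grad * g4 * inv)
            return backward

        return _result(out, (x, gamma, beta), factory_eval)

    mean = x.data.mean(axis=(0, 2, 3))
    var = x.data.var(axis=(0, 2, 3))
    running_mean *= 1.0 - momentum
    running_mean += momentum * mean
    running_var *= 1.0 - momentum
    running_var += momentum * var
    inv = 1.0 / np.sqrt(var.reshape(1, -1, 1, 1) + eps)
    centered = x.data - mean.reshape(1, -1, 1, 1)
    xhat = centered * inv
    out = g4 * xhat + b4
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def factory(out_t):
        def backward(grad):
            if gamma.requires_grad:
                gamma._accumulate((grad * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = grad * g4
                # standard batch-norm input gradient
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = inv * (dxhat - s1 / m - xhat * s2 / m)
                x._accumulate(dx)
        return backward

    return _result(out, (x, gamma, beta), factory)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable per-pixel softmax over the channel axis."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
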