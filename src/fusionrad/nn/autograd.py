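"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the fusion CNN on a CPU:
tensors with gradient tracking, elementwise arithmetic, matmul, ReLU,
channel concat/slice, 2D (grouped) convolution and transpose convolution,
batch normalization, global average pooling and a fused softmax
cross-entropy loss.  Convolutions are im2col/col2im based; the transpose
convolution is the exact adjoint of the convolution, sharing the same
kernels, so `ConvTranspose2d` forward literally runs the conv backward-data
routine.

Everything is float64 and deterministic; no threads, no in-place aliasing
of tracked data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "concat", "add", "sub", "global_avg_pool",
           "conv2d", "conv_transpose2d", "linear", "batch_norm2d",
           "softmax_cross_entropy"]


class Tensor:
    """A numpy array plus (optionally) a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-topological backpropagation from this tensor."""
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
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce a gradient back to the broadcast source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))
    return _make(a.data - b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    def backward(g):
        x._accumulate(g * mask)
    return _make(x.data * mask, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            t._accumulate(piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    x = _as_tensor(x)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    def backward(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x._accumulate(full)
    return _make(x.data[sl], (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C) spatial mean."""
    x = _as_tensor(x)
    b, c, h, w = x.data.shape
    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())
    return _make(x.data.mean(axis=(2, 3)), (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """y = x @ w.T (+ b); x: (B, Din), w: (Dout, Din)."""
    x, w = _as_tensor(x), _as_tensor(w)
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    def backward(g):
        x._accumulate(g @ w.data)
        w._accumulate(g.T @ x.data)
        if b is not None:
            b._accumulate(g.sum(axis=0))
    return _make(y, parents, backward)


# ---------------------------------------------------------------------------
# convolution primitives (shared by Conv2d and its exact adjoint)
# ---------------------------------------------------------------------------

def _pad2d(x, pad):
    ph, pw = pad
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _im2col(x, kh, kw, stride):
    """(B, C, H, W) -> (B, Ho, Wo, C, kh, kw) strided view (read-only)."""
    sh, sw = stride
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)
    return view.transpose(0, 2, 3, 1, 4, 5)


def conv2d_forward(x, w, stride=(1, 1), pad=(0, 0)):
    """x: (B, Ci, H, W), w: (Co, Ci, kh, kw) -> (B, Co, Ho, Wo)."""
    co, ci, kh, kw = w.shape
    xp = _pad2d(x, pad)
    cols = _im2col(xp, kh, kw, stride)
    b_, ho, wo = cols.shape[:3]
    y = cols.reshape(b_ * ho * wo, ci * kh * kw) @ w.reshape(co, -1).T
    return y.reshape(b_, ho, wo, co).transpose(0, 3, 1, 2)


def conv2d_backward_w(x, dy, w_shape, stride=(1, 1), pad=(0, 0)):
    co, ci, kh, kw = w_shape
    xp = _pad2d(x, pad)
    cols = _im2col(xp, kh, kw, stride)
    b_, ho, wo = cols.shape[:3]
    dyf = dy.transpose(0, 2, 3, 1).reshape(b_ * ho * wo, co)
    dw = dyf.T @ cols.reshape(b_ * ho * wo, ci * kh * kw)
    return dw.reshape(w_shape)


def conv2d_backward_data(dy, w, x_spatial, stride=(1, 1), pad=(0, 0)):
    """Adjoint of conv2d_forward w.r.t. the input; also the forward map of
    the transpose convolution."""
    co, ci, kh, kw = w.shape
    sh, sw = stride
    ph, pw = pad
    b_, _, ho, wo = dy.shape
    h, w_sp = x_spatial
    dyf = dy.transpose(0, 2, 3, 1).reshape(b_ * ho * wo, co)
    dcols = dyf @ w.reshape(co, -1)  # (B*Ho*Wo, Ci*kh*kw)
    dcols = dcols.reshape(b_, ho, wo, ci, kh, kw)
    dxp = np.zeros((b_, ci, h + 2 * ph, w_sp + 2 * pw))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + ho * sh : sh, j : j + wo * sw : sw] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if ph or pw:
        dxp = dxp[:, :, ph : ph + h, pw : pw + w_sp]
    return dxp


def _grouped(fn, groups, x_parts, w_parts, *args, **kw):
    return np.concatenate(
        [fn(xp, wp, *args, **kw) for xp, wp in zip(x_parts, w_parts)], axis=1
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), pad=(0, 0), groups: int = 1) -> Tensor:
    """Grouped 2D convolution; w: (Co, Ci/groups, kh, kw)."""
    x, w = _as_tensor(x), _as_tensor(w)
    if groups == 1:
        y = conv2d_forward(x.data, w.data, stride, pad)
    else:
        xs = np.split(x.data, groups, axis=1)
        ws = np.split(w.data, groups, axis=0)
        y = _grouped(lambda xp, wp: conv2d_forward(xp, wp, stride, pad), groups, xs, ws)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    x_spatial = x.data.shape[2:]

    def backward(g):
        if groups == 1:
            x._accumulate(conv2d_backward_data(g, w.data, x_spatial, stride, pad))
            w._accumulate(conv2d_backward_w(x.data, g, w.data.shape, stride, pad))
        else:
            gs = np.split(g, groups, axis=1)
            xs = np.split(x.data, groups, axis=1)
            ws = np.split(w.data, groups, axis=0)
            dx = np.concatenate(
                [conv2d_backward_data(gp, wp, x_spatial, stride, pad)
                 for gp, wp in zip(gs, ws)], axis=1)
            dw = np.concatenate(
                [conv2d_backward_w(xp, gp, wp.shape, stride, pad)
                 for xp, gp, wp in zip(xs, gs, ws)], axis=0)
            x._accumulate(dx)
            w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=(1, 1), pad=(0, 0)) -> Tensor:
    """Transpose convolution (deconvolution): the exact adjoint of conv2d.

    w: (Ci, Co, kh, kw) where Ci is the input channel count; output spatial
    dims are (H-1)*stride + k - 2*pad.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    ci, co, kh, kw = w.data.shape
    sh, sw = stride
    ph, pw = pad
    h, w_sp = x.data.shape[2:]
    out_spatial = ((h - 1) * sh + kh - 2 * ph, (w_sp - 1) * sw + kw - 2 * pw)
    y = conv2d_backward_data(x.data, w.data, out_spatial, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        x._accumulate(conv2d_forward(g, w.data, stride, pad))
        w._accumulate(conv2d_backward_w(g, x.data, w.data.shape, stride, pad))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(y, parents, backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    In training mode the batch statistics are used and the running
    estimates updated in place; in eval mode the running estimates are
    used (so inference is batch-size independent).
    """
    x = _as_tensor(x)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gam = gamma.data[None, :, None, None]
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gxh = g * gam
            mean_g = gxh.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx = (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
            dx = (gxh - mean_g - xhat * mean_gx) * inv[None, :, None, None]
        else:
            dx = g * gam * inv[None, :, None, None]
        x._accumulate(dx)

    return _make(y, (x, gamma, beta), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels; fused softmax for stability."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = labels.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)

    return _make(np.asarray(loss), (logits,), backward)
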