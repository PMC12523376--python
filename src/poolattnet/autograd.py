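"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the network needs: grouped strided 2-D
convolution, average/max pooling (stride-1 same-padded and strided), batch
normalization (batch-statistics and running-statistics modes), exact
erf-based GELU, sigmoid, elementwise add/multiply, channel concatenation,
global average pooling, a fully connected layer, and fused
softmax/cross-entropy.  Tensors use the NCHW layout.

Gradients are accumulated on every tensor in the graph (not only leaves) so
that saliency methods can read gradients of intermediate activations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf, expit

__all__ = [
    "Tensor", "add", "mul", "concat_channels", "gelu", "sigmoid",
    "conv2d", "avg_pool2d", "max_pool2d", "batch_norm", "global_avg_pool",
    "linear", "softmax_cross_entropy", "softmax",
]


class Tensor:
    """An array node in the computation graph.

    ``requires_grad`` marks graph membership; ``grad`` is populated (for every
    node that required a gradient) after :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; seeds with ``grad`` (default ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: the graph is ~100 nodes deep per stage
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)
    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)
    return _make(a.data * b.data, (a, b), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Depth concatenation; the first operand occupies the lower channels."""
    ca = a.data.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])
    return _make(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x_ = x.data
    phi = 0.5 * (1.0 + erf(x_ * _INV_SQRT2))
    y = x_ * phi

    def backward(g):
        d = phi + x_ * _INV_SQRT2PI * np.exp(-0.5 * x_ * x_)
        x._accumulate(g * d)
    return _make(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))
    return _make(s, (x,), backward)


# ---------------------------------------------------------------------------
# convolution and pooling (im2col based)
# ---------------------------------------------------------------------------

def _pad_nchw(x: np.ndarray, pad: int, value: float = 0.0) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                  mode="constant", constant_values=value)


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> view (N,C,Ho,Wo,kh,kw)."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def _col2im(dcols: np.ndarray, xshape, kh, kw, sh, sw, pad) -> np.ndarray:
    """Scatter-add (N,C,Ho,Wo,kh,kw) window grads back to the input."""
    n, c, h, w = xshape
    ho = (h + 2 * pad - kh) // sh + 1
    wo = (w + 2 * pad - kw) // sw + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += dcols[:, :, :, :, i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution (cross-correlation), weight (Co, Ci/g, kh, kw)."""
    n, ci, h, wdt = x.data.shape
    co, cig, kh, kw = w.data.shape
    if ci != cig * groups or co % groups:
        raise ValueError(
            f"conv2d channel/group mismatch: in={ci}, weight expects "
            f"{cig}*{groups}, out={co} with groups={groups}")
    xp = _pad_nchw(x.data, padding)
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: kernel {kh}x{kw} does not fit input {h}x{wdt}")
    v = _windows(xp, kh, kw, stride, stride)                # (N,C,Ho,Wo,kh,kw)
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, groups, cig * kh * kw, ho * wo)
    wm = w.data.reshape(groups, co // groups, cig * kh * kw)
    out = np.matmul(wm[None], cols).reshape(n, co, ho, wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        g2 = g.reshape(n, groups, co // groups, ho * wo)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wm.transpose(0, 2, 1)[None], g2)
            dcols = dcols.reshape(n, ci, kh, kw, ho, wo).transpose(0, 1, 4, 5, 2, 3)
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, stride, padding))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Average pooling; padded entries count as zeros in the mean."""
    n, c, h, w = x.data.shape
    if h + 2 * padding < kernel or w + 2 * padding < kernel:
        raise ValueError(f"avg_pool2d: window {kernel} exceeds padded input {h}x{w}")
    xp = _pad_nchw(x.data, padding)
    v = _windows(xp, kernel, kernel, stride, stride)
    out = v.sum(axis=(-2, -1)) / (kernel * kernel)
    ho, wo = out.shape[2], out.shape[3]

    def backward(g):
        dcols = np.broadcast_to(
            (g / (kernel * kernel))[:, :, :, :, None, None],
            (n, c, ho, wo, kernel, kernel))
        x._accumulate(_col2im(dcols, x.data.shape, kernel, kernel,
                              stride, stride, padding))
    return _make(out, (x,), backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling; padding uses -inf so it never wins the max."""
    n, c, h, w = x.data.shape
    if h + 2 * padding < kernel or w + 2 * padding < kernel:
        raise ValueError(f"max_pool2d: window {kernel} exceeds padded input {h}x{w}")
    xp = _pad_nchw(x.data, padding, value=-np.inf)
    v = _windows(xp, kernel, kernel, stride, stride)
    ho, wo = v.shape[2], v.shape[3]
    flat = v.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros((n, c, ho, wo, kernel * kernel), dtype=g.dtype)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dcols = dflat.reshape(n, c, ho, wo, kernel, kernel)
        x._accumulate(_col2im(dcols, x.data.shape, kernel, kernel,
                              stride, stride, padding))
    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, var: np.ndarray, eps: float,
               use_batch_stats: bool) -> Tensor:
    """Per-channel normalization on NCHW input.

    With ``use_batch_stats`` the supplied mean/var must be the biased batch
    statistics of ``x`` and the backward pass differentiates through them;
    otherwise they are treated as constants (inference with running stats).
    """
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if use_batch_stats:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                dxhat = g * gamma.data[None, :, None, None]
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
                x._accumulate(dx)
            else:
                x._accumulate(g * gs)
    return _make(y, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# head ops
# ---------------------------------------------------------------------------

def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))
    return _make(out, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map: x (N,C) @ w.T (C,K) + b."""
    out = x.data @ w.data.T + b.data[None, :]

    def backward(g):
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data)
    return _make(out, (x, w, b), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax over the last axis (no graph)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(g * p / n)
    return _make(np.asarray(loss), (logits,), backward)
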