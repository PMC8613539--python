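"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the recurrent U-Net needs — same-padded
2D convolution (im2col + matmul), 2x2 max-pooling, 2x2 nearest-neighbour
upsampling, channel concatenation/slicing, the LSTM gate nonlinearities, and
a mean-absolute-error loss.  Tensors hold float32 data in NCHW layout; the
graph is a simple tape of parent links traversed in reverse topological
order.  Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2",
    "upsample2",
    "sigmoid",
    "tanh",
    "add",
    "mul",
    "concat",
    "channel_slice",
    "mae_loss",
    "Adam",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        """A leaf tensor sharing this tensor's values (TBPTT state carry)."""
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: List[Tensor] = []
        seen = set()
        # iterative topological sort (graphs span chunk_len frames)
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()

        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def _track(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, H*W) patches with 'same' zero padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, k, k, h, w),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
    )
    return np.ascontiguousarray(cols).reshape(b, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back."""
    b, c, h, w = shape
    p = k // 2
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    dcols = dcols.reshape(b, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    if p == 0:
        return dxp
    return dxp[:, :, p : p + h, p : p + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution; w is (O, C, k, k), b is (O,)."""
    o, c, k, _ = w.shape
    bs, cx, h, wd = x.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input {cx}, weight {c}")
    cols = _im2col(x.data, k)  # (B, Ckk, HW)
    w2 = w.data.reshape(o, c * k * k)
    out = np.matmul(w2[None], cols)  # (B, O, HW)
    out = out.reshape(bs, o, h, wd) + b.data[None, :, None, None]

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(bs, o, h * wd)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.shape))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T[None], g2)  # (B, Ckk, HW)
            x._accumulate(_col2im(dcols, x.shape, k))

    return _track(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# resampling


def maxpool2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 needs even spatial dims")
    xr = (
        x.data.reshape(b, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(b, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = (
            dxr.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        x._accumulate(dx)

    return _track(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        b, c, h2, w2 = g.shape
        x._accumulate(
            g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        )

    return _track(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return _track(out, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * (1.0 - out * out))

    return _track(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError("add requires matching shapes")
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _track(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError("mul requires matching shapes")
    out = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    return _track(out, (a, b), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel (axis 1) concatenation."""
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _track(out, (a, b), backward)


def channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    out = x.data[:, start:stop]

    def backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        dx[:, start:stop] = g
        x._accumulate(dx)

    return _track(out, (x,), backward)


def scale(x: Tensor, a: float) -> Tensor:
    """Multiplication by a python scalar."""
    out = x.data * a

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * a)

    return _track(out, (x,), backward)


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target."""
    diff = pred.data - np.asarray(target, dtype=np.float32)
    out = np.array(np.abs(diff).mean(), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate(g * np.sign(diff) / diff.size)

    return _track(out, (pred,), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = pred.data - np.asarray(target, dtype=np.float32)
    out = np.array((diff * diff).mean(), dtype=np.float32)

    def backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate(g * 2.0 * diff / diff.size)

    return _track(out, (pred,), backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive-moment estimation over a list of parameter tensors."""

    def __init__(
        self,
        params: List[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
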