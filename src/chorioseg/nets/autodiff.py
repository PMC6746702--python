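"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine providing exactly the operations the
package's architectures need: broadcast arithmetic, matmul, 2-D convolution
(stride 1, zero padding, via im2col), 2x2 max pooling and nearest-neighbour
upsampling, batch normalisation, dropout, slicing/reshape/transpose/concat,
elementwise nonlinearities, reductions, log-softmax and fused cross-entropy.
Gradient correctness is covered by finite-difference tests.

Arrays keep the dtype they are given; training code uses float32, gradient
checks float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "concat", "maximum", "conv2d", "maxpool2d", "upsample2d",
    "batch_norm", "dropout", "log_softmax", "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the tape machinery for reverse-mode gradients."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents: Sequence["Tensor"] = (),
                 backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        out = Tensor(a.data + b.data, (a, b),
                     lambda g: (_unbroadcast(g, a.data.shape),
                                _unbroadcast(g, b.data.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        out = Tensor(a.data * b.data, (a, b),
                     lambda g: (_unbroadcast(g * b.data, a.data.shape),
                                _unbroadcast(g * a.data, b.data.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        x = self
        out = Tensor(x.data ** exponent, (x,),
                     lambda g: (g * exponent * x.data ** (exponent - 1),))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        out = Tensor(a.data @ b.data, (a, b),
                     lambda g: (g @ b.data.T, a.data.T @ g))
        return out

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        x = self
        out = Tensor(np.maximum(x.data, 0), (x,),
                     lambda g: (g * (x.data > 0),))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,), lambda g: (g * y * (1.0 - y),))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,), lambda g: (g * (1.0 - y * y),))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, (self,), lambda g: (g * y,))
        return out

    def log(self):
        x = self
        out = Tensor(np.log(x.data), (x,), lambda g: (g / x.data,))
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        x = self

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, x.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, x.data.shape).copy(),)

        return Tensor(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        x = self
        return Tensor(x.data.reshape(shape), (x,),
                      lambda g: (g.reshape(x.data.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        x = self
        inv = np.argsort(axes)
        return Tensor(x.data.transpose(axes), (x,),
                      lambda g: (g.transpose(inv),))

    def slice_axis(self, axis: int, start: int, stop: int):
        x = self
        index = [slice(None)] * x.ndim
        index[axis] = slice(start, stop)
        index = tuple(index)

        def backward(g):
            gx = np.zeros_like(x.data)
            gx[index] = g
            return (gx,)

        return Tensor(x.data[index], (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tensors, backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; on exact ties the gradient goes to ``a``."""
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    take_a = a.data >= b.data
    out = Tensor(np.where(take_a, a.data, b.data), (a, b),
                 lambda g: (_unbroadcast(g * take_a, a.data.shape),
                            _unbroadcast(g * ~take_a, b.data.shape)))
    return out


# -- convolution ---------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           pad: tuple[int, int] | None = None) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, stride 1.

    ``pad`` defaults to 'same' padding ((kh-1)//2, (kw-1)//2), which keeps
    the spatial size for odd kernels.
    """
    n, c, h, width = x.data.shape
    f, c_in, kh, kw = w.data.shape
    if c_in != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c_in}")
    if pad is None:
        pad = ((kh - 1) // 2, (kw - 1) // 2)
    ph, pw = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho, wo = h + 2 * ph - kh + 1, width + 2 * pw - kw + 1
    cols = _im2col(xp, kh, kw)
    wmat = w.data.reshape(f, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    y = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, f)
        gw = (gmat.T @ cols).reshape(w.data.shape)
        gcols = gmat @ wmat  # (N*Ho*Wo, C*kh*kw)
        gcols = gcols.reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        gx = gxp[:, :, ph:h + ph, pw:width + pw] if (ph or pw) else gxp
        if b is None:
            return gx, gw
        return gx, gw, gmat.sum(axis=0)

    return Tensor(np.ascontiguousarray(y), parents, backward)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; spatial dims must divide by k."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial size ({h}, {w}) not divisible by {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return (gr.reshape(n, c, h, w),)

    return Tensor(y, (x,), backward)


def upsample2d(x: Tensor, k: int = 2) -> Tensor:
    """Nearest-neighbour upsampling by factor k."""
    n, c, h, w = x.data.shape
    y = x.data.repeat(k, axis=2).repeat(k, axis=3)

    def backward(g):
        return (g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)),)

    return Tensor(y, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               axes: tuple[int, ...], eps: float = 1e-5,
               frozen_stats: tuple[np.ndarray, np.ndarray] | None = None,
               ) -> Tensor:
    """Batch normalisation over ``axes``.

    Training mode (``frozen_stats=None``) normalises by the batch mean and
    variance with the full analytic backward.  Inference mode normalises by
    the supplied (running) statistics, through which no gradient flows.
    """
    if frozen_stats is None:
        mean = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    else:
        mean, var = frozen_stats
    std = np.sqrt(var + eps)
    xhat = (x.data - mean) / std
    y = gamma.data * xhat + beta.data

    def backward_batch(g):
        dgamma = _unbroadcast(g * xhat, gamma.data.shape)
        dbeta = _unbroadcast(g, beta.data.shape)
        dxhat = g * gamma.data
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std
        return dx, dgamma, dbeta

    def backward_frozen(g):
        dgamma = _unbroadcast(g * xhat, gamma.data.shape)
        dbeta = _unbroadcast(g, beta.data.shape)
        return g * (gamma.data / std), dgamma, dbeta

    bwd = backward_batch if frozen_stats is None else backward_frozen
    return Tensor(y, (x, gamma, beta), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: zero with probability p, rescale by 1/(1-p)."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    mask = mask.astype(x.data.dtype)
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - logsumexp
    p = np.exp(y)

    def backward(g):
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(y, (x,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``targets`` over (N, K) ``logits``."""
    n = logits.data.shape[0]
    ls = log_softmax(logits, axis=1)
    picked = ls.data[np.arange(n), targets]
    loss = -picked.mean()
    p = np.exp(ls.data)

    def backward(g):
        onehot = np.zeros_like(logits.data)
        onehot[np.arange(n), targets] = 1.0
        return ((p - onehot) * (g / n),)

    return Tensor(np.asarray(loss), (logits,), backward)
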