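"""Trainable layers built on the autodiff engine.

Weights are initialised with small random values (He-scaled normals) from
an explicit ``numpy.random.Generator`` so every build is reproducible.
Modules expose ``parameters()`` for the optimizer and
``get_weights()``/``set_weights()`` for checkpointing (which also carry
batch-norm running statistics).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Linear", "BatchNorm", "Dropout", "BiRNNSweep"]

DTYPE = np.float32


class Module:
    """Base class: recursive parameter/state collection over attributes."""

    def _children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values() if isinstance(v, Tensor)]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def _state_arrays(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running stats)."""
        state = [v for k, v in sorted(self.__dict__.items())
                 if isinstance(v, np.ndarray)]
        for child in self._children():
            state.extend(child._state_arrays())
        return state

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + \
               [s.copy() for s in self._state_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        state = self._state_arrays()
        if len(weights) != len(params) + len(state):
            raise ValueError(
                f"checkpoint has {len(weights)} arrays, model expects "
                f"{len(params) + len(state)} (architecture mismatch?)")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(
                    f"weight shape {w.shape} does not fit parameter "
                    f"{p.data.shape} (architecture mismatch?)")
            p.data = w.astype(p.data.dtype).copy()
        for s, w in zip(state, weights[len(params):]):
            s[...] = w

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding by default."""

    def __init__(self, c_in: int, c_out: int, kernel: int | tuple[int, int],
                 rng: np.random.Generator, pad: tuple[int, int] | None = None):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        self.weight = Tensor(rng.normal(0, scale, (c_out, c_in, kh, kw)).astype(DTYPE))
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE))
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Tensor(rng.normal(0, scale, (d_in, d_out)).astype(DTYPE))
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalisation for NCHW (n_dims=4) or NK (n_dims=2) inputs."""

    def __init__(self, channels: int, n_dims: int = 4, momentum: float = 0.9):
        shape = (1, channels) + (1,) * (n_dims - 2)
        self.gamma = Tensor(np.ones(shape, dtype=DTYPE))
        self.beta = Tensor(np.zeros(shape, dtype=DTYPE))
        self.running_mean = np.zeros(shape, dtype=DTYPE)
        self.running_var = np.ones(shape, dtype=DTYPE)
        self.axes = tuple(i for i in range(n_dims) if i != 1)
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            m = x.data.mean(axis=self.axes, keepdims=True)
            v = x.data.var(axis=self.axes, keepdims=True)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * m)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * v)
            return ad.batch_norm(x, self.gamma, self.beta, self.axes)
        return ad.batch_norm(x, self.gamma, self.beta, self.axes,
                             frozen_stats=(self.running_mean, self.running_var))


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator,
                 training: bool) -> Tensor:
        return ad.dropout(x, self.p, rng, training)


class _RNNDirection(Module):
    """One directional tanh-RNN pass over a sequence of (B, C) inputs."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.wx = Tensor(rng.normal(0, np.sqrt(1.0 / c_in), (c_in, hidden)).astype(DTYPE))
        self.wh = Tensor((np.eye(hidden) * 0.5
                          + rng.normal(0, 0.01, (hidden, hidden))).astype(DTYPE))
        self.bias = Tensor(np.zeros(hidden, dtype=DTYPE))
        self.hidden = hidden

    def __call__(self, steps: list[Tensor], reverse: bool) -> list[Tensor]:
        order = range(len(steps) - 1, -1, -1) if reverse else range(len(steps))
        outs: list[Tensor | None] = [None] * len(steps)
        h: Tensor | None = None
        for t in order:
            pre = steps[t] @ self.wx + self.bias
            if h is not None:
                pre = pre + h @ self.wh
            h = pre.tanh()
            outs[t] = h
        return outs  # type: ignore[return-value]


class BiRNNSweep(Module):
    """Bidirectional recurrent sweep over a feature map.

    A vertical sweep processes each column top-to-bottom and bottom-to-top
    (every column in parallel as a batch); a horizontal sweep does the same
    along rows.  The two directional outputs are concatenated along the
    feature axis, so the output has ``2 * hidden`` channels.
    """

    def __init__(self, c_in: int, hidden: int, orientation: str,
                 rng: np.random.Generator):
        if orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")
        self.orientation = orientation
        self.fwd = _RNNDirection(c_in, hidden, rng)
        self.bwd = _RNNDirection(c_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        axis = 2 if self.orientation == "vertical" else 3
        length = x.shape[axis]
        # each step: (N * other_dim, C)
        steps = []
        for t in range(length):
            sl = x.slice_axis(axis, t, t + 1)  # (N, C, 1, W) or (N, C, H, 1)
            flat = sl.transpose(0, 2, 3, 1).reshape(-1, c)
            steps.append(flat)
        outs_f = self.fwd(steps, reverse=False)
        outs_b = self.bwd(steps, reverse=True)
        hidden = self.fwd.hidden
        slabs = []
        for f, b in zip(outs_f, outs_b):
            both = ad.concat([f, b], axis=1)  # (B, 2*hidden)
            if axis == 2:
                slab = both.reshape(n, 1, w, 2 * hidden).transpose(0, 3, 1, 2)
            else:
                slab = both.reshape(n, h, 1, 2 * hidden).transpose(0, 3, 1, 2)
            slabs.append(slab)
        return ad.concat(slabs, axis=axis)
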