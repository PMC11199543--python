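"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar result walks the
tape in reverse topological order and accumulates gradients into every
tensor created with ``requires_grad=True``.  Only the operations needed by
the segmentation network are implemented; each backward rule is exercised
against central finite differences in the test suite.

Shapes follow the single-sample convention used throughout the package:
feature maps are ``(channels, z, y, x)`` and volumes are ``(z, y, x)``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic -----------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other: float) -> "Tensor":
        return _as_tensor(other) / self

    # -- reductions ------------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.data.shape)
        )
        return out

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0), parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * sign)
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None) -> "Tensor":
        clipped = np.clip(self.data, lo, hi)
        # pass-through gradient only where no clipping occurred
        mask = clipped == self.data
        out = Tensor(clipped, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def minimum(self, const: float) -> "Tensor":
        return self.clamp(hi=const)

    # -- structural ops --------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def upsample_nearest(self, factor: int) -> "Tensor":
        """Nearest-neighbour upsampling of a (C, z, y, x) map by an integer factor."""
        if factor == 1:
            return self
        c, d, h, w = self.data.shape
        y = (
            self.data.reshape(c, d, 1, h, 1, w, 1)
            .repeat(factor, 2)
            .repeat(factor, 4)
            .repeat(factor, 6)
            .reshape(c, d * factor, h * factor, w * factor)
        )
        out = Tensor(y, parents=(self,))

        def bw(g: np.ndarray) -> None:
            gr = g.reshape(c, d, factor, h, factor, w, factor)
            self._accum(gr.sum(axis=(2, 4, 6)))

        out._backward = bw
        return out

    # -- network primitives ----------------------------------------------

    def conv3d(self, weight: "Tensor", bias: "Tensor", padding: int) -> "Tensor":
        """3-D cross-correlation, stride 1.

        ``self``: (Cin, D, H, W); ``weight``: (Cout, Cin, k, k, k);
        ``bias``: (Cout,).  ``padding`` must equal (k-1)//2 for
        shape-preserving convolution (k odd).
        """
        x = self.data
        wt = weight.data
        cout, cin, k, _, _ = wt.shape
        if k == 1:
            # pointwise: a plain channel matmul, no im2col needed
            c, d, h, w = x.shape
            xm = x.reshape(c, -1)
            wm = wt.reshape(cout, cin)
            y = (wm @ xm).reshape(cout, d, h, w) + bias.data[:, None, None, None]
            out = Tensor(y, parents=(self, weight, bias))

            def bw1(g: np.ndarray) -> None:
                gm = g.reshape(cout, -1)
                if weight.requires_grad:
                    weight._accum((gm @ xm.T).reshape(wt.shape))
                if bias.requires_grad:
                    bias._accum(gm.sum(axis=1))
                if self.requires_grad:
                    self._accum((wm.T @ gm).reshape(x.shape))

            out._backward = bw1
            return out

        xp = np.pad(x, ((0, 0),) + ((padding, padding),) * 3)
        col = _im2col(xp, k)  # (V, Cin*k^3)
        wm = wt.reshape(cout, -1)
        d, h, w = x.shape[1:]
        y = (col @ wm.T).T.reshape(cout, d, h, w) + bias.data[:, None, None, None]
        out = Tensor(y, parents=(self, weight, bias))

        def bw(g: np.ndarray) -> None:
            gm = g.reshape(cout, -1)  # (Cout, V)
            if weight.requires_grad:
                weight._accum((gm @ col).reshape(wt.shape))
            if bias.requires_grad:
                bias._accum(gm.sum(axis=1))
            if self.requires_grad:
                # input gradient = same-padded correlation of g with the
                # spatially flipped kernels, channel roles swapped
                wflip = wt[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                gp = np.pad(g, ((0, 0),) + ((k - 1 - padding, k - 1 - padding),) * 3)
                gcol = _im2col(gp, k)
                gx = (gcol @ wflip.reshape(cin, -1).T).T.reshape(x.shape)
                self._accum(gx)

        out._backward = bw
        return out

    def conv_transpose3d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

        ``self``: (Cin, D, H, W); ``weight``: (Cin, Cout, 2, 2, 2).
        Output: (Cout, 2D, 2H, 2W).  Kernel == stride means output blocks
        never overlap, so the op is a per-voxel linear map.
        """
        x = self.data
        wt = weight.data
        cin, cout = wt.shape[:2]
        d, h, w = x.shape[1:]
        # (Cout,2,2,2,D,H,W) -> (Cout, D,2, H,2, W,2) -> (Cout, 2D,2H,2W)
        t = np.tensordot(wt, x, axes=([0], [0]))
        y = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(cout, 2 * d, 2 * h, 2 * w)
        y += bias.data[:, None, None, None]
        out = Tensor(y, parents=(self, weight, bias))

        def bw(g: np.ndarray) -> None:
            g6 = g.reshape(cout, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5)
            if weight.requires_grad:
                # dW[cin, cout, i, j, l] = sum_v x[cin, v] * g6[cout, i, j, l, v]
                gw = np.tensordot(
                    x.reshape(cin, -1), g6.reshape(cout * 8, -1).T, axes=([1], [0])
                ).reshape(cin, cout, 2, 2, 2)
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(1, 2, 3)))
            if self.requires_grad:
                gx = np.tensordot(
                    wt.reshape(cin, -1), g6.reshape(cout * 8, -1), axes=([1], [0])
                ).reshape(x.shape)
                self._accum(gx)

        out._backward = bw
        return out

    def maxpool3d(self) -> "Tensor":
        """2x2x2 max pooling, stride 2; spatial dims must be even."""
        c, d, h, w = self.data.shape
        xr = (
            self.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        out = Tensor(y, parents=(self,))

        def bw(g: np.ndarray) -> None:
            gz = np.zeros_like(xr)
            np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
            gx = (
                gz.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, d, h, w)
            )
            self._accum(gx)

        out._backward = bw
        return out

    def batchnorm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel normalization over the spatial axes of (C, z, y, x).

        With one sample per step this is the batch-size-1 limit of batch
        normalization; running statistics are updated in place during
        training and used verbatim in evaluation mode.
        """
        x = self.data
        if training:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
        else:
            mu = running_mean
            var = running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        y = gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None]
        out = Tensor(y, parents=(self, gamma, beta))

        def bw(g: np.ndarray) -> None:
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(1, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(1, 2, 3)))
            if self.requires_grad:
                gi = gamma.data[:, None, None, None] * inv[:, None, None, None]
                if training:
                    m1 = g.mean(axis=(1, 2, 3))[:, None, None, None]
                    m2 = (g * xhat).mean(axis=(1, 2, 3))[:, None, None, None]
                    self._accum(gi * (g - m1 - xhat * m2))
                else:
                    self._accum(gi * g)

        out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or p <= 0.0:
            return self
        keep = rng.random(self.data.shape) >= p
        scale = 1.0 / (1.0 - p)
        out = Tensor(self.data * keep * scale, parents=(self,))
        out._backward = lambda g: self._accum(g * keep * scale)
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    if len(ts) == 1:
        return ts[0]
    data = np.concatenate([t.data for t in ts], axis=axis)
    out = Tensor(data, parents=ts)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def _as_tensor(x: "Tensor | float") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """Unfold a padded (C, D, H, W) array into (V, C*k^3) patch rows."""
    v = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C,Do,Ho,Wo,k,k,k)
    c = xp.shape[0]
    return np.ascontiguousarray(
        v.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, c * k**3)
    )
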