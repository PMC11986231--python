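"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates vector-Jacobian products into ``.grad``.  Only the operations the
package's models need are implemented: broadcast arithmetic, matmul, the
usual activations, axis reductions, reshaping/concatenation, and the spatial
primitives (2-D convolution, 2x2 max-pooling, nearest 2x upsampling) written
as single taped ops so the hot loops stay inside BLAS calls.

Dtype behaviour: an input array's floating dtype is preserved end-to-end
(float32 models train in float32); Python scalars never upcast, and
gradients are accumulated in each node's own dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # make numpy defer to the reflected operators so ndarray <op> Tensor
    # builds a taped Tensor instead of an object array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- tape mechanics ------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        if _is_scalar(other):
            def backward(g):
                self._accumulate(g)

            return Tensor._make(self.data + other, (self,), backward)
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if _is_scalar(other):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other if _is_scalar(other) else as_tensor(other) + (-self)

    def __mul__(self, other):
        if _is_scalar(other):
            def backward(g):
                self._accumulate(g * other)

            return Tensor._make(self.data * other, (self,), backward)
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if _is_scalar(other):
            return self * (1.0 / other)
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- activations and elementwise maps ------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions, reshapes, indexing --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.shape[axis] for t in tensors])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


# -- spatial primitives ------------------------------------------------------

def _gemm_for(dtype):
    from scipy.linalg import blas

    return blas.sgemm if dtype == np.float32 else blas.dgemm


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1.

    ``x``: (N, C, H, W); ``w``: (F, C, kh, kw); ``b``: (F,).  Implemented as
    one BLAS GEMM per kernel offset on a channels-first flattened layout, so
    no im2col buffer is gathered — the right layout makes every operand a
    contiguous view and the accumulation happens inside GEMM (beta=1).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {c2}")
    dtype = np.result_type(x.data.dtype, w.data.dtype)
    gemm = _gemm_for(dtype)
    hp, wp = h + 2 * padding, wd + 2 * padding
    oh, ow = hp - kh + 1, wp - kw + 1
    ntot = n * hp * wp
    span = ntot - ((kh - 1) * wp + (kw - 1))
    itemsize = np.dtype(dtype).itemsize

    # padded input in channels-last flattened layout (N*HP*WP, C); row-slice
    # transposes of this array are truly Fortran-contiguous, so every GEMM
    # below operates on views (no im2col gather, no wrapper copies)
    xp2 = np.zeros((n, hp, wp, c), dtype=dtype)
    xp2[:, padding : padding + h, padding : padding + wd, :] = \
        x.data.transpose(0, 2, 3, 1)
    xflat = xp2.reshape(ntot, c)

    wd_ = w.data.astype(dtype, copy=False)
    wcols = [[np.asfortranarray(wd_[:, :, i, j].T) for j in range(kw)]
             for i in range(kh)]  # each (C, F)
    acc = None  # (span, F), F-contiguous
    for i in range(kh):
        for j in range(kw):
            s = i * wp + j
            acc = gemm(1.0, xflat[s : s + span].T, wcols[i][j], trans_a=1,
                       beta=0.0 if acc is None else 1.0, c=acc, overwrite_c=1)
    valid = np.lib.stride_tricks.as_strided(
        acc, shape=(n, oh, ow, f),
        strides=(hp * wp * itemsize, wp * itemsize, itemsize, span * itemsize))
    if b is not None:
        b = as_tensor(b)
        out_data = valid.transpose(0, 3, 1, 2) + b.data[None, :, None, None]
    else:
        out_data = np.ascontiguousarray(valid.transpose(0, 3, 1, 2))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        g = np.asarray(g, dtype=dtype)
        # embed the output gradient in the padded flattened geometry
        gacc = np.zeros((span, f), dtype=dtype)
        gview = np.lib.stride_tricks.as_strided(
            gacc, shape=(n, oh, ow, f),
            strides=(hp * wp * f * itemsize, wp * f * itemsize,
                     f * itemsize, itemsize))
        gview[:] = g.transpose(0, 2, 3, 1)
        gacc_t = gacc.T  # (F, span), F-contiguous
        if w.requires_grad:
            dw = np.empty((kh, kw, c, f), dtype=dtype)
            for i in range(kh):
                for j in range(kw):
                    s = i * wp + j
                    # (C, span) @ (span, F)
                    dw[i, j] = gemm(1.0, xflat[s : s + span].T, gacc_t,
                                    trans_b=1)
            w._accumulate(dw.transpose(3, 2, 0, 1))
        if x.requires_grad:
            dxp = np.zeros((ntot, c), dtype=dtype)
            for i in range(kh):
                for j in range(kw):
                    s = i * wp + j
                    # (C, F) @ (F, span) accumulated into the shifted slice
                    gemm(1.0, wcols[i][j], gacc_t, beta=1.0,
                         c=dxp[s : s + span].T, overwrite_c=1)
            dxp4 = dxp.reshape(n, hp, wp, c)
            if padding:
                dxp4 = dxp4[:, padding:-padding, padding:-padding, :]
            x._accumulate(dxp4.transpose(0, 3, 1, 2))

    return Tensor._make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pooling, stride 2.  On ties the gradient is the sum
    subgradient (all tied entries receive the pooled gradient)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    d = x.data
    rows = np.maximum(d[:, :, 0::2, :], d[:, :, 1::2, :])
    out_data = np.maximum(rows[:, :, :, 0::2], rows[:, :, :, 1::2])

    def backward(g):
        up = np.empty((n, c, h, w), dtype=g.dtype)
        u4 = up.reshape(n, c, h // 2, 2, w // 2, 2)
        u4[:] = g[:, :, :, None, :, None]
        ref = np.empty_like(up)
        r4 = ref.reshape(n, c, h // 2, 2, w // 2, 2)
        r4[:] = out_data[:, :, :, None, :, None]
        x._accumulate(np.where(d == ref, up, 0.0))

    return Tensor._make(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out_data = np.empty((n, c, 2 * h, 2 * w), dtype=x.data.dtype)
    out_data.reshape(n, c, h, 2, w, 2)[:] = x.data[:, :, :, None, :, None]

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean softmax cross-entropy; returns (loss, probabilities)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean()

    def backward(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(float(g) * d / n)

    return Tensor._make(np.asarray(nll), (logits,), backward), probs
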