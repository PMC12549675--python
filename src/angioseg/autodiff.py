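"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor backend for the trainable blocks in this package: a
tape-based scalar-loss autograd with exactly the operator set the
segmentation network needs (dense/depthwise convolution, linear maps,
normalisation, gating nonlinearities, separable linear resampling and a
first-order linear recurrence for state-space scans), plus AdamW and a
cosine learning-rate schedule.  Arrays are NHWC throughout.

Design notes
------------
* ``Tensor`` wraps an ``np.ndarray``; the graph is built eagerly and freed
  after ``backward``.  Broadcasting follows numpy; gradients are
  un-broadcast by summation.
* Heavy kernels (conv2d, linear_scan) store closures over their inputs and
  implement hand-written backward passes; everything else composes.
* A global :func:`no_grad` switch skips graph construction in evaluation.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "ModuleList", "Linear", "Conv2d",
    "DepthwiseConv2d", "LayerNorm", "BatchNorm2d", "AdamW",
    "CosineAnnealingLR", "no_grad", "is_grad_enabled",
    "concat", "linear_scan", "axis_linear_map", "avg_pool2d", "conv1d_k3",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward: Callable[[], None]):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._backward = backward
            out._prev = tuple(parents)
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the tape
        for node in topo:
            node._backward = None
            node._prev = ()

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        a, b = self, other
        out_data = a.data + b.data

        def backward():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.shape))

        out = Tensor._make(out_data, (a, b), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        a, b = self, other
        out_data = a.data * b.data

        def backward():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.shape))

        out = Tensor._make(out_data, (a, b), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        a = self
        out_data = a.data ** p

        def backward():
            if a.requires_grad:
                a._accum(out.grad * p * a.data ** (p - 1.0))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def __matmul__(self, other):
        a, b = self, _as_tensor(other, self.dtype)
        out_data = a.data @ b.data

        def backward():
            if a.requires_grad:
                a._accum(out.grad @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ out.grad)

        out = Tensor._make(out_data, (a, b), backward)
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * out_data)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad / a.data)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def sqrt(self):
        return self.pow(0.5)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * (1.0 - out_data ** 2))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward():
            if a.requires_grad:
                a._accum(out.grad * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = np.where(mask, a.data, 0.0)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * mask)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def silu(self):
        a = self
        sig = 1.0 / (1.0 + np.exp(-a.data))
        out_data = a.data * sig

        def backward():
            if a.requires_grad:
                a._accum(out.grad * (sig + a.data * sig * (1.0 - sig)))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def gelu(self):
        # tanh approximation
        a = self
        k = math.sqrt(2.0 / math.pi)
        inner = k * (a.data + 0.044715 * a.data ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * a.data * (1.0 + t)

        def backward():
            if a.requires_grad:
                dinner = k * (1.0 + 3 * 0.044715 * a.data ** 2)
                grad = 0.5 * (1.0 + t) + 0.5 * a.data * (1.0 - t ** 2) * dinner
                a._accum(out.grad * grad)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def softplus(self):
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def backward():
            if a.requires_grad:
                a._accum(out.grad / (1.0 + np.exp(-a.data)))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def clamp(self, lo: float, hi: float):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = (a.data > lo) & (a.data < hi)

        def backward():
            if a.requires_grad:
                a._accum(out.grad * mask)

        out = Tensor._make(out_data, (a,), backward)
        return out

    # -- reductions & reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if a.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = a.data.reshape(shape)

        def backward():
            if a.requires_grad:
                a._accum(out.grad.reshape(a.shape))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def transpose(self, *perm):
        a = self
        if len(perm) == 1 and isinstance(perm[0], (tuple, list)):
            perm = tuple(perm[0])
        inv = np.argsort(perm)
        out_data = a.data.transpose(perm)

        def backward():
            if a.requires_grad:
                a._accum(out.grad.transpose(inv))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def flip(self, axis: int):
        a = self
        out_data = np.flip(a.data, axis=axis)

        def backward():
            if a.requires_grad:
                a._accum(np.flip(out.grad, axis=axis))

        out = Tensor._make(out_data, (a,), backward)
        return out

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        parts = idx if isinstance(idx, tuple) else (idx,)
        simple = all(isinstance(p, (slice, int)) for p in parts)

        def backward():
            if a.requires_grad:
                g = np.zeros_like(a.data)
                if simple:
                    g[idx] += out.grad      # slices cannot alias
                else:
                    np.add.at(g, idx, out.grad)
                a._accum(g)

        out = Tensor._make(out_data, (a,), backward)
        return out

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis."""
        a = self
        pads = [(0, 0)] * a.ndim
        pads[axis] = (before, after)
        out_data = np.pad(a.data, pads)
        sl = [slice(None)] * a.ndim
        sl[axis] = slice(before, before + a.shape[axis])
        sl = tuple(sl)

        def backward():
            if a.requires_grad:
                a._accum(out.grad[sl])

        out = Tensor._make(out_data, (a,), backward)
        return out


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype if dtype is not None else None)
    return Tensor(arr)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tensors, backward)
    return out


def axis_linear_map(x: Tensor, mh: np.ndarray | None, mw: np.ndarray | None) -> Tensor:
    """Apply fixed linear maps along the H and W axes of an NHWC tensor.

    ``y[b, o, p, c] = sum_{h,w} mh[o,h] * x[b,h,w,c] * mw[p,w]``.  This one
    primitive covers bilinear resizing, area/adaptive average pooling and
    strip pooling, all of which are separable linear resamplings; the
    backward pass is the transposed map.
    """
    a = x
    data = a.data
    if mh is not None:
        data = np.einsum("oh,bhwc->bowc", mh, data)
    if mw is not None:
        data = np.einsum("pw,bhwc->bhpc", mw, data)

    def backward():
        if a.requires_grad:
            g = out.grad
            if mw is not None:
                g = np.einsum("pw,bhpc->bhwc", mw, g)
            if mh is not None:
                g = np.einsum("oh,bowc->bhwc", mh, g)
            a._accum(g)

    out = Tensor._make(data, (a,), backward)
    return out


def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D resampling matrix (align_corners=False bilinear
    for upsampling, area averaging for downsampling)."""
    m = np.zeros((n_out, n_in))
    if n_out >= n_in:
        scale = n_in / n_out
        for o in range(n_out):
            pos = (o + 0.5) * scale - 0.5
            lo = int(np.floor(pos))
            frac = pos - lo
            lo_c = min(max(lo, 0), n_in - 1)
            hi_c = min(max(lo + 1, 0), n_in - 1)
            m[o, lo_c] += 1.0 - frac
            m[o, hi_c] += frac
    else:
        # area (box) averaging: exact for integer factors
        edges = np.linspace(0.0, n_in, n_out + 1)
        for o in range(n_out):
            a, b = edges[o], edges[o + 1]
            for i in range(int(np.floor(a)), int(np.ceil(b))):
                w = min(b, i + 1) - max(a, i)
                if w > 0:
                    m[o, i] = w / (b - a)
    return m


def resize_bilinear(x: Tensor, h_out: int, w_out: int) -> Tensor:
    """Separable bilinear/area resize of an NHWC tensor (linear operator)."""
    b, h, w, c = x.shape
    mh = None if h_out == h else interp_matrix(h_out, h).astype(x.dtype)
    mw = None if w_out == w else interp_matrix(w_out, w).astype(x.dtype)
    if mh is None and mw is None:
        return x
    return axis_linear_map(x, mh, mw)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k average pooling of an NHWC tensor."""
    b, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by {k}")
    return resize_bilinear(x, h // k, w // k)


def conv1d_k3(x: Tensor, w: Tensor, axis: int) -> Tensor:
    """Kernel-3, zero-padded, stride-1 convolution with a shared 3-vector
    weight along one axis (used by the attention gating branches)."""
    xp = x.pad_axis(axis, 1, 1)
    n = x.shape[axis]

    def sl(lo):
        s = [slice(None)] * x.ndim
        s[axis] = slice(lo, lo + n)
        return tuple(s)

    return w[0] * xp[sl(0)] + w[1] * xp[sl(1)] + w[2] * xp[sl(2)]


def linear_scan(a: Tensor, bx: Tensor) -> Tensor:
    """First-order linear recurrence ``h[t] = a[t] * h[t-1] + bx[t]``.

    Inputs have shape (B, L, ...) with the recurrence along axis 1 and
    ``h[-1] = 0``.  Forward runs a vectorised time loop; backward is exact
    BPTT over the stored state sequence.
    """
    ad, bd = a.data, bx.data
    B, L = ad.shape[:2]
    h = np.empty_like(bd)
    prev = np.zeros_like(bd[:, 0])
    for t in range(L):
        prev = ad[:, t] * prev + bd[:, t]
        h[:, t] = prev

    def backward():
        g = out.grad
        da = np.empty_like(ad) if a.requires_grad else None
        db = np.empty_like(bd) if bx.requires_grad else None
        carry = np.zeros_like(bd[:, 0])
        for t in range(L - 1, -1, -1):
            dh = g[:, t] + carry
            if db is not None:
                db[:, t] = dh
            if da is not None:
                da[:, t] = dh * (h[:, t - 1] if t > 0 else 0.0)
            carry = dh * ad[:, t]
        if da is not None:
            a._accum(da)
        if db is not None:
            bx._accum(db)

    out = Tensor._make(h, (a, bx), backward)
    return out


def conv2d_op(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
              padding: int = 0) -> Tensor:
    """Dense 2-D convolution, NHWC input, weight (kh, kw, cin, cout)."""
    kh, kw, cin, cout = w.shape
    s = stride
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    B, Hp, Wp, _ = xd.shape
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(1, 2))
    win = win[:, ::s, ::s]                     # (B, Ho, Wo, cin, kh, kw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * Ho * Wo, kh * kw * cin)
    wm = w.data.reshape(kh * kw * cin, cout)
    y = cols @ wm
    if b is not None:
        y = y + b.data
    y = y.reshape(B, Ho, Wo, cout)

    def backward():
        gy = out.grad.reshape(B * Ho * Wo, cout)
        if w.requires_grad:
            w._accum((cols.T @ gy).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=0))
        if x.requires_grad:
            dcols = (gy @ wm.T).reshape(B, Ho, Wo, kh, kw, cin)
            dxp = np.zeros((B, Hp, Wp, cin), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, i, j]
            if padding:
                dxp = dxp[:, padding:Hp - padding, padding:Wp - padding]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(y, parents, backward)
    return out


def dwconv2d_op(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """Depthwise (per-channel) 2-D convolution, weight (kh, kw, c), stride 1."""
    kh, kw, c = w.shape
    xd = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    B, Hp, Wp, _ = xd.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    y = np.zeros((B, Ho, Wo, c), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            y += xd[:, i:i + Ho, j:j + Wo] * w.data[i, j]
    if b is not None:
        y = y + b.data

    def backward():
        gy = out.grad
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[i, j] = (xd[:, i:i + Ho, j:j + Wo] * gy).sum(axis=(0, 1, 2))
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + Ho, j:j + Wo] += gy * w.data[i, j]
            x._accum(dxp[:, padding:Hp - padding, padding:Wp - padding])

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(y, parents, backward)
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. batch-norm running statistics),
        yielded as (name, owning module, attribute name)."""
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Module):
                yield from v.named_buffers(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")
        for k in getattr(self, "buffer_names", ()):
            yield f"{prefix}{k}", self, k

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, mod, attr in self.named_buffers():
            out[name] = np.array(getattr(mod, attr), copy=True)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (mod, attr) for name, mod, attr in self.named_buffers()}
        own = set(params) | set(buffers)
        missing = own - set(state)
        extra = set(state) - own
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} "
                           f"unexpected={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.array(state[k], dtype=p.data.dtype)
        for k, (mod, attr) in buffers.items():
            cur = getattr(mod, attr)
            if cur.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            setattr(mod, attr, np.array(state[k], dtype=cur.dtype))


class ModuleList(Module):
    def __init__(self, mods: Sequence[Module] = ()):
        super().__init__()
        self.items = list(mods)

    def named_parameters(self, prefix: str = ""):
        # flatten the "items" level out of parameter names
        for i, item in enumerate(self.items):
            yield from item.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, item in enumerate(self.items):
            yield from item.named_buffers(f"{prefix}{i}.")

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, m: Module):
        self.items.append(m)


DTYPE = np.float64


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False,
                 init_scale: float = 1.0):
        super().__init__()
        if zero_init:
            self.weight = Parameter(np.zeros((cin, cout), dtype=DTYPE))
        else:
            self.weight = Parameter(init_scale * _kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shp = x.shape
        y = x.reshape(-1, shp[-1]) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(*shp[:-1], self.weight.shape[1])


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, (k, k, cin, cout), k * k * cin))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d_op(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.padding = k // 2
        self.weight = Parameter(_kaiming(rng, (k, k, c), k * k))
        self.bias = Parameter(np.zeros(c, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return dwconv2d_op(x, self.weight, self.bias, self.padding)


class LayerNorm(Module):
    """Normalisation over the trailing channel axis at each spatial site."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(c, dtype=DTYPE))
        self.bias = Parameter(np.zeros(c, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps).pow(-0.5)
        return xhat * self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel, NHWC layout."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(c, dtype=DTYPE))
        self.bias = Parameter(np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.buffer_names = ("running_mean", "running_var")
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - self.running_mean) * \
                (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.weight + self.bias


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (no AMSGrad)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


class CosineAnnealingLR:
    """Cosine decay of the learning rate from lr0 to lr_min over t_max steps."""

    def __init__(self, opt: AdamW, t_max: int, lr_min: float = 0.0):
        self.opt = opt
        self.lr0 = opt.lr
        self.t_max = t_max
        self.lr_min = lr_min
        self.epoch = 0

    def step(self):
        self.epoch += 1
        self.opt.lr = self.lr_min + 0.5 * (self.lr0 - self.lr_min) * (
            1.0 + math.cos(math.pi * self.epoch / self.t_max))
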