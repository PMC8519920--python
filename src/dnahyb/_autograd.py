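"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the yield regressors need: broadcasted
arithmetic, matmul, 1-D convolution (im2col), element-wise nonlinearities,
reductions, slicing/concatenation and an embedding gather, plus small layer
wrappers (Linear, Conv1d, BatchNorm, Dropout, Embedding, LSTM) and an Adam
optimiser.  Everything is float32 and deterministic given seeded
``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self) -> None:
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
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))
        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))
        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))
        out._backward = bw
        return out

    # -- reductions and shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(
            np.float32(1.0 / count))

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
        out._backward = bw
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(start, stop)
                t._accumulate(g[tuple(index)])
    out._backward = bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution: ``x (B, Cin, W)`` * ``w (Cout, Cin, K)`` + ``b``."""
    kernel = w.data.shape[2]
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    windows = sliding_window_view(xd, kernel, axis=2)  # (B, Cin, W', K)
    out_data = np.einsum("bcwk,ock->bow", windows, w.data, optimize=True)
    out_data += b.data[None, :, None]
    out = Tensor(out_data, parents=(x, w, b))
    width_out = out_data.shape[2]

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bow,bcwk->ock", g, windows, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for k in range(kernel):
                gx[:, :, k:k + width_out] += np.einsum(
                    "bow,oc->bcw", g, w.data[:, :, k], optimize=True)
            if padding:
                gx = gx[:, :, padding:gx.shape[2] - padding]
            x._accumulate(gx)
    out._backward = bw
    return out


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows of ``weight (V, E)`` by integer ``ids (B, T)``."""
    out = Tensor(weight.data[ids], parents=(weight,))

    def bw(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids, g)
            weight._accumulate(full)
    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base layer: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (copies)."""
        out: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str):
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    out[key] = value.data.copy()
                elif isinstance(value, np.ndarray):
                    out[key] = value.copy()
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
        visit(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def visit(obj: "Module", prefix: str):
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    value.data = state[key].astype(np.float32).reshape(value.data.shape)
                elif isinstance(value, np.ndarray):
                    setattr(obj, name, state[key].reshape(value.shape).astype(value.dtype))
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
        visit(self, "")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm(Module):
    """Batch normalisation over all axes except the channel axis."""

    def __init__(self, n_channels: int, channel_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.channel_axis = channel_axis
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.data.ndim) if i != self.channel_axis)
        shape = [1] * x.data.ndim
        shape[self.channel_axis] = -1
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=axes, keepdims=True)
            batch_mean = mean.data.reshape(-1)
            batch_var = var.data.reshape(-1)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * batch_mean
            self.running_var = (1 - m) * self.running_var + m * batch_var
            inv_std = (var + Tensor(np.float32(self.eps))) ** -0.5
            normed = centred * inv_std
        else:
            mean = self.running_mean.reshape(shape)
            inv_std = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            normed = (x - Tensor(mean)) * Tensor(inv_std)
        return normed * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = (self.rng.random(x.data.shape) >= self.rate).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.rate))


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.1, (vocab_size, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class LSTMLayer(Module):
    """Single-direction LSTM over a list of per-timestep tensors."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(hidden)
        self.w_ih = Tensor(rng.uniform(-bound, bound, (n_in, 4 * hidden)),
                           requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-bound, bound, (hidden, 4 * hidden)),
                           requires_grad=True)
        self.bias = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.hidden = hidden

    def __call__(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        batch = xs[0].data.shape[0]
        h = Tensor(np.zeros((batch, self.hidden)))
        c = Tensor(np.zeros((batch, self.hidden)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        outputs: list[Tensor | None] = [None] * len(xs)
        H = self.hidden
        for t in order:
            gates = xs[t].matmul(self.w_ih) + h.matmul(self.w_hh) + self.bias
            i = gates[:, 0 * H:1 * H].sigmoid()
            f = gates[:, 1 * H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return outputs  # type: ignore[return-value]


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                np.float32)
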