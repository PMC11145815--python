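"""Neural-network building blocks (layers, modules, optimizer).

Thin layer abstractions over :mod:`deeplip.autodiff`: parameter
registration, train/eval mode, state dicts for serialization, and the
specific layers the affinity model needs (linear, 1D conv block with
batch norm and PReLU, dropout, GRU-style gated update, Adam).
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .autodiff import Tensor, conv1d


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._named_buffers():
            state[name] = mod.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype)
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _named_buffers(self, prefix: str = ""):
        for name, buf in getattr(self, "_buffers", {}).items():
            yield prefix + name, buf
        for name, mod in self._modules.items():
            yield from mod._named_buffers(prefix + name + ".")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = Tensor(_glorot(rng, (in_dim, out_dim), dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    __call__ = forward


class PReLU(Module):
    """PReLU with a single learnable slope (init 0.25)."""

    def __init__(self, dtype=np.float32):
        super().__init__()
        self.alpha = Tensor(np.asarray([0.25], dtype=dtype),
                            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        pos = x.relu()
        return pos + self.alpha * (x - pos)

    __call__ = forward


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel for (B, C, L),
    or over the batch axis for (B, C) inputs.  Running statistics are used
    in eval mode, making inference deterministic."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        object.__setattr__(self, "_buffers", {
            "running_mean": np.zeros(channels, dtype=np.float64),
            "running_var": np.ones(channels, dtype=np.float64),
        })

    def forward(self, x: Tensor) -> Tensor:
        conv_layout = x.ndim == 3  # (B, C, L)
        axes = (0, 2) if conv_layout else (0,)
        if conv_layout:
            shape = (1, -1, 1)
        else:
            shape = (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            dt = x.data.dtype
            mu = self._buffers["running_mean"].astype(dt).reshape(shape)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).astype(dt)
            xhat = (x - mu) * (1.0 / sd.reshape(shape))
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)

    __call__ = forward


class Conv1d(Module):
    """Stride-1, 'same'-padded 1D convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(_glorot(rng, (out_ch, in_ch, kernel), dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in train mode without an RNG; "
                               "call set_rng() on the model first")
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))

    __call__ = forward


class GRUUpdate(Module):
    """GRU-style gated node update ``h' = (1 - z) * h + z * n``.

    z = sigmoid(m Wz + h Uz + bz)      (update gate)
    r = sigmoid(m Wr + h Ur + br)      (reset gate)
    n = tanh(m Wn + (r * h) Un + bn)   (candidate)
    """

    def __init__(self, dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        for gate in ("z", "r", "n"):
            setattr(self, f"W{gate}",
                    Tensor(_glorot(rng, (dim, dim), dtype), requires_grad=True))
            setattr(self, f"U{gate}",
                    Tensor(_glorot(rng, (dim, dim), dtype), requires_grad=True))
            setattr(self, f"b{gate}",
                    Tensor(np.zeros(dim, dtype=dtype), requires_grad=True))

    def forward(self, h: Tensor, m: Tensor) -> Tensor:
        z = (m @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (m @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (m @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
        return (1.0 - z) * h + z * n

    __call__ = forward


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = p.data - update.astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
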