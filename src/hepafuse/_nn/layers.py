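"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Module", "Dense", "Conv2d", "BatchNorm2d", "Dropout"]


class Module:
    """Base class with parameter bookkeeping (torch-like, minimal)."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, child in self._walk_modules(""):
            if isinstance(child, BatchNorm2d):
                state[name + ".running_mean"] = child.running_mean.copy()
                state[name + ".running_var"] = child.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, child in self._walk_modules(""):
            if isinstance(child, BatchNorm2d):
                child.running_mean = np.array(state[name + ".running_mean"])
                child.running_var = np.array(state[name + ".running_var"])

    def _walk_modules(self, prefix: str):
        for cname, child in self._children.items():
            full = prefix + cname if not prefix else prefix + "." + cname
            yield full, child
            yield from child._walk_modules(full)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# float32 keeps the GEMM-bound training loops fast on CPU; gradient-check
# tests build float64 tensors directly, which the autodiff core preserves
DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_he_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.w = Tensor(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor((1.0 / sd).astype(self.running_var.dtype))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)
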