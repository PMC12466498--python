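"""Layer abstractions over the autograd core, torch-like but minimal."""

from __future__ import annotations

import contextlib
import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, _make, as_tensor, silu, sigmoid

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity", "Conv2d", "BatchNorm2d",
    "Linear", "SiLU", "Sigmoid", "MaxPool2d", "Upsample", "seed_all", "profile_scope",
]

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the weight-initialization RNG (call before building a model)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


# ------------------------------------------------------------------ profiling

_PROFILE_STACK: list[list] = []


@contextlib.contextmanager
def profile_scope():
    """Collect (kind, macs, extra_ops) records from every layer executed."""
    records: list[tuple[str, float, float]] = []
    _PROFILE_STACK.append(records)
    try:
        yield records
    finally:
        _PROFILE_STACK.pop()


def _record(kind: str, macs: float, extra: float = 0.0) -> None:
    if _PROFILE_STACK:
        _PROFILE_STACK[-1].append((kind, macs, extra))


class Module:
    def __init__(self):
        self.training = True

    # -- registry ----------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[prefix + name] = val.data.copy()
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = val.copy()
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, val in list(vars(self).items()):
            key = prefix + name
            if isinstance(val, Parameter) and key in sd:
                val.data = np.asarray(sd[key], dtype=np.float32).reshape(val.shape)
            elif isinstance(val, np.ndarray) and name.startswith("running_") and key in sd:
                setattr(self, name, np.asarray(sd[key], dtype=np.float32))
        for name, child in self._children():
            child.load_state_dict(sd, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __len__(self):
        return len(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, f"m{len(self._items)}", m)
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def forward(self, x):  # pragma: no cover
        raise RuntimeError("ModuleList is a container, not callable")


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_ch % groups:
            raise ValueError(f"in_ch={in_ch} not divisible by groups={groups}")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.dilation, self.groups = kernel, stride, dilation, groups
        self.padding = (dilation * (kernel - 1)) // 2 if padding is None else padding
        fan_in = in_ch // groups * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            _RNG.uniform(-bound, bound, (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(_RNG.uniform(-bound, bound, out_ch)) if bias else None

    def forward(self, x):
        y = F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                     self.dilation, self.groups)
        out_el = y.size
        _record("conv", out_el * (self.kernel ** 2) * (self.in_ch // self.groups),
                out_el if self.bias is not None else 0.0)
        return y


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        bound = 1.0 / math.sqrt(in_f)
        self.weight = Parameter(_RNG.uniform(-bound, bound, (out_f, in_f)))
        self.bias = Parameter(_RNG.uniform(-bound, bound, out_f)) if bias else None

    def forward(self, x):
        y = x @ self.weight.transpose()
        if self.bias is not None:
            y = y + self.bias
        _record("linear", (y.size // self.out_f) * self.in_f * self.out_f,
                y.size if self.bias is not None else 0.0)
        return y


class BatchNorm2d(Module):
    # eps/momentum fixed at the substrate family's defaults; not load-bearing
    def __init__(self, ch: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x):
        x = as_tensor(x)
        _record("bn", 0.0, 2.0 * x.size)
        b, c, h, w = x.shape
        gamma, beta = self.weight, self.bias
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = b * h * w
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (
                var * n / max(n - 1, 1) - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate(np.sum(g * xhat, axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(np.sum(g, axis=(0, 2, 3)))
            gs = gamma.data[None, :, None, None] / std[None, :, None, None]
            if training:
                mg = g.mean(axis=(0, 2, 3), keepdims=True)
                mgx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = gs * (g - mg - xhat * mgx)
            else:
                gx = gs * g
            x._accumulate(gx.astype(np.float32))

        return _make(out, (x, gamma, beta), backward)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest2d(x, self.scale)
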