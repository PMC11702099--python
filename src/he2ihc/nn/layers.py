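"""Module system and layer zoo.

Weight sharing is by object identity: referencing the same layer instance
from two sub-networks makes ``parameters()`` (which de-duplicates by id)
count and update the shared storage once.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F


class Module:
    """Base class; sub-modules and parameters are discovered via __dict__."""

    training: bool = True
    _buffer_names: tuple = ()

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{prefix}{name}.{i}.")

    def train(self, flag: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def named_buffers(self):
        for mod_name, mod in self.named_modules():
            for bname in mod._buffer_names:
                yield f"{mod_name}{bname}", mod, bname

    def parameters(self) -> list[Tensor]:
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        seen, out = set(), {}
        for name, p in self.named_parameters():
            if id(p) in seen:
                continue
            seen.add(id(p))
            out[name] = p.data.copy()
        for name, mod, bname in self.named_buffers():
            out[name] = np.asarray(getattr(mod, bname)).copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        own = {}
        seen = set()
        for name, p in self.named_parameters():
            if id(p) in seen:
                continue
            seen.add(id(p))
            own[name] = p
        buffers = {name: (mod, bname) for name, mod, bname in self.named_buffers()}
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, (mod, bname) in buffers.items():
            setattr(mod, bname, np.asarray(state[name], dtype=np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, init="gauss", *, rng):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        std = _he_std(cin * k * k) if init == "he" else 0.02
        self.w = _init(rng, (cout, cin, k, k), std)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Stride-2 3×3 transposed conv doubling the spatial side."""

    def __init__(self, cin, cout, k=3, stride=2, pad=1, bias=True, *, rng):
        self.stride = stride
        self.pad = pad
        self.w = _init(rng, (cin, cout, k, k))
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, c, k=3, stride=1, bias=True, init="gauss", *, rng):
        self.stride = stride
        self.pad = k // 2
        std = _he_std(k * k) if init == "he" else 0.02
        self.w = _init(rng, (c, k, k), std)
        self.b = Tensor(np.zeros(c, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(x, self.w, self.b, self.stride, self.pad)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, init="gauss", *, rng):
        std = _he_std(cin) if init == "he" else 0.02
        self.w = _init(rng, (cin, cout), std)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = x.matmul(self.w)
        return y + self.b if self.b is not None else y


class InstanceNorm2d(Module):
    def __init__(self, c, affine=True, eps=1e-5):
        self.eps = eps
        if affine:
            self.g = Tensor(np.ones(c, np.float32), requires_grad=True)
            self.be = Tensor(np.zeros(c, np.float32), requires_grad=True)
        else:
            self.g = self.be = None

    def forward(self, x):
        return F.instance_norm(x, self.g, self.be, self.eps)


class BatchNorm2d(Module):
    """Batch normalization with running statistics (train/eval modes)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, c, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.g = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.be = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            y = xc * (var + self.eps).pow(-0.5)
        else:
            rm = self.running_mean.reshape(1, -1, 1, 1)
            rv = self.running_var.reshape(1, -1, 1, 1)
            y = (x - Tensor(rm)) * Tensor(1.0 / np.sqrt(rv + self.eps))
        return y * self.g.reshape(1, -1, 1, 1) + self.be.reshape(1, -1, 1, 1)


class Embedding(Module):
    def __init__(self, n, dim, *, rng):
        self.w = _init(rng, (n, dim))

    def forward(self, idx):
        return F.embedding(idx, self.w)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class HardSwish(Module):
    def forward(self, x):
        return x.hardswish()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()
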