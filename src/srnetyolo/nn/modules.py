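"""Layer modules built on the autodiff tensor."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "BatchNorm2d", "Linear", "PReLU", "ConvBNSiLU", "LayerNorm2d",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules(""):
            for bname, buf in m._buffers().items():
                out[f"{name}{bname}"] = buf.copy()
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = {
            f"{name}{bname}": (m, bname)
            for name, m in self._named_modules("")
            for bname in m._buffers()
        }
        for key, value in state.items():
            value = np.asarray(value)
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.astype(params[key].data.dtype)
            elif key in buffers:
                m, bname = buffers[key]
                setattr(m, bname, value.astype(np.float32))
            else:
                raise KeyError(f"unexpected key {key!r} in state dict")

    def _named_modules(self, prefix):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m._named_modules(f"{prefix}{name}.")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng):
    bound = float(np.sqrt(2.0 / fan_in))
    return (rng.standard_normal(shape) * bound).astype(np.float32)


_GLOBAL_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reset the weight-initialisation stream (call before building a model)."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, stride=1, padding=0,
                 groups=1, bias=True, zero_init=False):
        super().__init__()
        k = kernel_size
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = in_ch // groups * k * k
        w = np.zeros((out_ch, in_ch // groups, k, k), dtype=np.float32) if zero_init \
            else _kaiming((out_ch, in_ch // groups, k, k), fan_in, _GLOBAL_RNG)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with learnable affine and running stats."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / C
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class LayerNorm2d(Module):
    """LayerNorm over the channel axis of a (B, C, H, W) map."""

    def __init__(self, num_features, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        C = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.weight = Tensor(_kaiming((in_features, out_features), in_features, _GLOBAL_RNG),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class PReLU(Module):
    def __init__(self, init=0.25):
        super().__init__()
        self.alpha = Tensor(np.asarray([init], dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return x.maximum(0.0) + x.minimum(0.0) * self.alpha.reshape(1, 1, 1, 1)


class _SiLU(Module):
    def forward(self, x):
        return x.silu()


class ConvBNSiLU(Module):
    """Conv -> BatchNorm -> SiLU, the basic block of CSP-style backbones."""

    def __init__(self, in_ch, out_ch, kernel_size=1, stride=1, padding=None, groups=1):
        super().__init__()
        if padding is None:
            padding = (kernel_size - 1) // 2
        self.conv = Conv2d(in_ch, out_ch, kernel_size, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()
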