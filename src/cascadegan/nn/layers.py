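"""Neural-network modules on top of the tape engine.

The ``Module`` container mimics the familiar parameters/state-dict idiom.
Weight initialisation is zero-mean Gaussian with sigma 0.02 from an
explicit ``numpy.random.Generator``, so every network build is a pure
function of its seed.
"""

from __future__ import annotations

import hashlib
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

from . import tensor as T
from .conv import conv2d, upsample_nearest
from .tensor import Tensor

INIT_SIGMA = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with recursive traversal."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> Iterator:
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def param_digest(self) -> str:
        """SHA-256 over all parameter bytes, in traversal order."""
        h = hashlib.sha256()
        for k, p in sorted(self.named_parameters()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            rng.normal(0.0, INIT_SIGMA,
                       (out_ch, in_ch, kernel, kernel)).astype(np.float32))
        self.bias = (Parameter(np.zeros((1, out_ch, 1, 1), dtype=np.float32))
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.stride, self.padding)
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, ch: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gamma = Parameter(np.ones((1, ch, 1, 1), dtype=np.float32))
            self.beta = Parameter(np.zeros((1, ch, 1, 1), dtype=np.float32))
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        out = xc * T.pow_(var + self.eps, -0.5)
        if self.gamma is not None:
            out = out * self.gamma + self.beta
        return out


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.tanh(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Upsample(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest(x, self.factor)


class Adam:
    """Adam with optional linear decay of the learning rate to zero over
    the second half of training (set via ``set_epoch``)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 2e-4,
                 betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr0 = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def set_lr_factor(self, f: float) -> None:
        self.lr = self.lr0 * max(f, 0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
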