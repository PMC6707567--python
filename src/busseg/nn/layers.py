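"""Layer modules over the autodiff engine: parameter containers with
He-normal seeded initialization, train/eval switching and state export."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d"]


class Parameter(T.Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks child modules, parameters and non-grad buffers."""

    def __init__(self):
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix=""):
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data.copy()
        for k, b in self._buffers.items():
            out[prefix + k] = b.copy()
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state):
        for k, p in self._params.items():
            p.data[...] = state[k]
        for k in self._buffers:
            self._buffers[k][...] = state[k]
            getattr(self, k)[...] = state[k]
        for k, m in self._modules.items():
            m.load_state_dict({kk[len(k) + 1:]: v for kk, v in state.items()
                               if kk.startswith(k + ".")})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """SAME-padded convolution; He-normal kernel init, zero bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(he_normal(
            rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x):
        return T.batch_norm(x, self.gamma, self.beta,
                            self.running_mean, self.running_var,
                            training=self.training, momentum=self.momentum,
                            eps=self.eps)
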