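"""Layer abstractions over the autograd engine: parameters, conv, norm, linear."""

from __future__ import annotations

import math

import numpy as np

from .tensor import DTYPE, Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval switching, call protocol.

    Subclasses list non-trained state (e.g. batch-norm running statistics)
    in ``_buffer_names`` so checkpoints capture it.
    """

    _buffer_names: tuple = ()

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_buffers(self, prefix: str = ""):
        for prefix_m, mod in self.named_modules():
            for bname in mod._buffer_names:
                full = f"{prefix_m}.{bname}" if prefix_m else bname
                yield (f"{prefix}.{full}" if prefix else full), mod, bname

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod, bname in self.named_buffers():
            out[name] = getattr(mod, bname).copy()
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        buffers = {name: (mod, bname) for name, mod, bname in self.named_buffers()}
        missing = (set(own) | set(buffers)) - set(state)
        extra = set(state) - set(own) - set(buffers)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, (mod, bname) in buffers.items():
            setattr(mod, bname, np.asarray(state[name], dtype=DTYPE).copy())


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Square-kernel convolution; records the input spatial size for cost reports."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        bound = math.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, bound, size=(out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.last_input_hw: tuple | None = None

    def forward(self, x: Tensor) -> Tensor:
        self.last_input_hw = x.shape[2:]
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        mu4 = mu.reshape(1, -1, 1, 1).astype(DTYPE)
        std4 = std.reshape(1, -1, 1, 1)
        xhat_data = (x.data - mu4) / std4
        gamma, beta = self.weight, self.bias
        out_data = gamma.data.reshape(1, -1, 1, 1) * xhat_data + beta.data.reshape(1, -1, 1, 1)

        training = self.training

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat_data).sum(axis=axes))
            if x.requires_grad:
                gsc = g * gamma.data.reshape(1, -1, 1, 1)
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    dx = (
                        gsc
                        - gsc.sum(axis=axes, keepdims=True) / m
                        - xhat_data * (gsc * xhat_data).sum(axis=axes, keepdims=True) / m
                    ) / std4
                else:
                    dx = gsc / std4
                x._accumulate(dx)

        return Tensor._make(out_data, (x, gamma, beta), backward)


class LayerNorm(Module):
    """Normalisation over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x.data - mu) / std
        gamma, beta = self.weight, self.bias
        out_data = gamma.data * xhat + beta.data

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
            if x.requires_grad:
                gsc = g * gamma.data
                m = g.shape[-1]
                dx = (
                    gsc
                    - gsc.mean(axis=-1, keepdims=True)
                    - xhat * (gsc * xhat).mean(axis=-1, keepdims=True)
                ) / std
                x._accumulate(dx)

        return Tensor._make(out_data, (x, gamma, beta), backward)
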