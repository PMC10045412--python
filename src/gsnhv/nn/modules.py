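"""Layer containers over the autodiff tensors: parameters, convolutions,
activations, and Kaiming initialisation."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "DepthwiseConv2d", "ReLU",
           "Sequential", "softmax", "kaiming_normal"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-normal initialisation with ReLU gain sqrt(2/fan_in)."""
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Minimal container: recursive parameter discovery, train/eval mode,
    flat state dict keyed by attribute path."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization ----------------------------------------------------

    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buf::" + k: v.copy() for k, v in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key.startswith("buf::"):
                self._set_buffer(key[5:], value)
            else:
                params[key].data = np.asarray(value, dtype=np.float32)

    def _set_buffer(self, path: str, value: np.ndarray) -> None:
        parts = path.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], np.asarray(value, dtype=np.float32))


class Conv2d(Module):
    """2-D convolution, bias-free (normalisation layers supply the shift)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    """Depthwise convolution with a channel multiplier (the ghost 'cheap
    linear operation'); weight (C, multiplier, k, k), bias-free."""

    def __init__(self, channels: int, kernel_size: int = 3, multiplier: int = 1,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.multiplier = multiplier
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            rng, (channels, multiplier, kernel_size, kernel_size), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, stride=self.stride, padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
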