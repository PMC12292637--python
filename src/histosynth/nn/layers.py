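"""Network building blocks on top of the autodiff engine.

Modules follow the familiar container pattern: a :class:`Module` owns
parameter tensors and submodules, ``parameters()`` walks them recursively,
and ``state_dict``/``load_state_dict`` give flat name→array views used by
the checkpoint writers.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, silu

__all__ = ["Module", "Parameter", "Linear", "Conv2d", "Sequential", "ResidualBlock"]


class Parameter(Tensor):
    """A tensor that is part of a module's trainable state."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def unfreeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = True

    # -- flat state for checkpoints -----------------------------------------

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        named: list[tuple[str, Parameter]] = []
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                named.append((key, v))
            elif isinstance(v, Module):
                named.extend(v.named_parameters(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        named.append((f"{key}.{i}", item))
        return named

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
    ):
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x) if isinstance(m, Module) else m(x)
        return x


class ResidualBlock(Module):
    """Two 3x3 convolutions with SiLU, plus an identity (or 1x1) shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.shortcut = None if c_in == c_out else Conv2d(c_in, c_out, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(silu(self.conv1(x)))
        s = x if self.shortcut is None else self.shortcut(x)
        return silu(h + s)
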