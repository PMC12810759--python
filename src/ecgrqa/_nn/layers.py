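"""Layers and the Adam optimiser for the in-repo autodiff engine."""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d


class Module:
    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match module parameters")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=p.data.dtype).reshape(p.shape)


#: dtype of trainable parameters (float32 halves memory and runtime; the
#: gradcheck tests exercise the float64 path through plain Tensors).
PARAM_DTYPE = np.float32


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(PARAM_DTYPE),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.w = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                          in_ch * kernel * kernel)
        self.b = Tensor(np.zeros(out_ch, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.w = _he_init(rng, (in_ch, out_ch, kernel, kernel),
                          in_ch * kernel * kernel)
        self.b = Tensor(np.zeros(out_ch, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = _he_init(rng, (in_f, out_f), in_f)
        self.b = Tensor(np.zeros(out_f, dtype=PARAM_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.w) + self.b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
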