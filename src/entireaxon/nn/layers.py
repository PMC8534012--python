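"""Parameterised layers built on the autodiff :class:`Tensor`."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .tensor import Tensor, concatenate, conv2d


def he_init(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{prefix}{k}"] = v.data
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.asarray(state[f"{prefix}{k}"], dtype=np.float64)
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Tensor(glorot_init(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """Same-size convolution, stride 1, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.w = Tensor(he_init(rng, out_ch, in_ch, k, k), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class GRUCell(Module):
    """Single gated recurrent unit layer.

    z = sigmoid(x Wz + h Uz + bz)        (update gate)
    r = sigmoid(x Wr + h Ur + br)        (reset gate)
    n = tanh(x Wn + (r * h) Un + bn)     (candidate state)
    h' = (1 - z) * n + z * h
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wz = Tensor(glorot_init(rng, in_dim, hidden), requires_grad=True)
        self.uz = Tensor(glorot_init(rng, hidden, hidden), requires_grad=True)
        self.bz = Tensor(np.zeros(hidden), requires_grad=True)
        self.wr = Tensor(glorot_init(rng, in_dim, hidden), requires_grad=True)
        self.ur = Tensor(glorot_init(rng, hidden, hidden), requires_grad=True)
        self.br = Tensor(np.zeros(hidden), requires_grad=True)
        self.wn = Tensor(glorot_init(rng, in_dim, hidden), requires_grad=True)
        self.un = Tensor(glorot_init(rng, hidden, hidden), requires_grad=True)
        self.bn = Tensor(np.zeros(hidden), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.wz + h @ self.uz + self.bz).sigmoid()
        r = (x @ self.wr + h @ self.ur + self.br).sigmoid()
        n = (x @ self.wn + (r * h) @ self.un + self.bn).tanh()
        return (1.0 - z) * n + z * h


class GRUStack(Module):
    """Multi-layer GRU applied one time step at a time.

    The input feeds layer 0; each layer's new state feeds the next layer.
    Dropout (if any) is applied between layers, not on the output.
    """

    def __init__(
        self,
        in_dim: int,
        hidden: int,
        n_layers: int,
        rng: np.random.Generator,
        dropout: float = 0.0,
    ):
        self.hidden = hidden
        self.n_layers = n_layers
        self.cells = [
            GRUCell(in_dim if i == 0 else hidden, hidden, rng)
            for i in range(n_layers)
        ]
        self.drop = Dropout(dropout)

    def init_state(self, batch: int) -> list[Tensor]:
        return [Tensor(np.zeros((batch, self.hidden))) for _ in self.cells]

    def step(
        self, x: Tensor, states: list[Tensor], rng: np.random.Generator
    ) -> tuple[Tensor, list[Tensor]]:
        """One time step; returns (top-layer state, all new layer states)."""
        new_states = []
        inp = x
        for i, cell in enumerate(self.cells):
            h = cell(inp, states[i])
            new_states.append(h)
            inp = self.drop(h, rng) if i < self.n_layers - 1 else h
        return inp, new_states
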