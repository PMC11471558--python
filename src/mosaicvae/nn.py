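"""Neural-network building blocks on top of the autodiff core.

Hidden blocks follow the Linear -> LayerNorm -> Mish -> Dropout recipe used
throughout the model; weights are initialized from seeded generators so that
training is bit-reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from ._autograd import Tensor, concat  # noqa: F401  (concat re-exported for model code)

__all__ = ["Module", "Linear", "LayerNorm", "HiddenBlock", "MLP", "AdamW"]


class Module:
    """Bare-bones container; children and parameters are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(f"parameter count mismatch: {len(arrays)} vs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class HiddenBlock(Module):
    """Linear -> LayerNorm -> Mish -> Dropout."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dropout: float = 0.0):
        self.lin = Linear(d_in, d_out, rng)
        self.norm = LayerNorm(d_out)
        self.dropout = dropout

    def __call__(self, x: Tensor, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        h = self.norm(self.lin(x)).mish()
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask = rng.random(h.shape) < keep
            h = h * Tensor(mask / keep)
        return h


class MLP(Module):
    """Hidden blocks followed by a plain linear output layer."""

    def __init__(self, d_in: int, hidden: Sequence[int], d_out: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        sizes = [d_in, *hidden]
        self.blocks = [HiddenBlock(a, b, rng, dropout) for a, b in zip(sizes[:-1], sizes[1:])]
        self.head = Linear(sizes[-1], d_out, rng)

    def __call__(self, x: Tensor, train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        for blk in self.blocks:
            x = blk(x, train=train, rng=rng)
        return self.head(x)


class AdamW:
    """Adam with decoupled weight decay (decay 0 by default)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
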