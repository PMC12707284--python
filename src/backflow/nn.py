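"""Layers, parameter management and the AdamW optimizer.

Everything is built on :mod:`backflow.autodiff`.  A :class:`Module` collects
its :class:`~backflow.autodiff.Parameter` leaves recursively from instance
attributes (including lists and dicts of submodules), which is all the
structure the desk-scale trunk needs.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Transition", "AdamW"]


class Module:
    """Base class providing parameter traversal and checkpoint (de)serialisation."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            yield from _walk(full, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != np.asarray(state[name]).shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _walk(prefix: str, value) -> Iterator[tuple[str, Parameter]]:
    if isinstance(value, Parameter):
        yield prefix, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix + ".")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _walk(f"{prefix}.{i}", v)
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _walk(f"{prefix}.{k}", v)


class Linear(Module):
    """Affine map on the last axis.

    ``init='zero'`` gives exact-zero output at initialisation, which the trunk
    uses for residual output projections and the logit head so that a fresh
    model is an exact identity / uniform predictor.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 init: str = "lecun", bias: bool = True):
        if init == "zero":
            w = np.zeros((d_in, d_out))
        else:
            if rng is None:
                raise ValueError("rng required for non-zero init")
            scale = 1.0 / np.sqrt(d_in)
            w = rng.normal(0.0, scale, size=(d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Transition(Module):
    """Pre-norm two-layer MLP with residual, zero-init output projection."""

    def __init__(self, d: int, expand: int, rng: np.random.Generator):
        self.norm = LayerNorm(d)
        self.fc1 = Linear(d, d * expand, rng)
        self.fc2 = Linear(d * expand, d, init="zero")

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.fc2(self.fc1(self.norm(x)).relu())


class AdamW:
    """AdamW with optional global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01, clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
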