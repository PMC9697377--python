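"""Layers, initialisation, optimiser and checkpointing for the detector.

Modules are plain Python objects exposing ``named_params()``; a checkpoint
is a flat ``name -> ndarray`` mapping stored with :func:`numpy.savez`.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "SGD", "save_params", "load_params"]


class Module:
    """Base class: children are discovered by attribute walk."""

    def named_params(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        def walk(obj, path):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    yield path, obj
            elif isinstance(obj, Module):
                yield from obj.named_params(f"{path}.")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    yield from walk(item, f"{path}{'.' if not path.endswith('.') else ''}{i}")

        for name, val in vars(self).items():
            yield from walk(val, f"{prefix}{name}")

    def params(self) -> list[Tensor]:
        return [p for _, p in self.named_params()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_params())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for k, t in own.items():
            if t.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {t.data.shape} vs {state[k].shape}")
            t.data[...] = state[k]

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int,
                 stride: int = 1, pad: int | None = None,
                 bias: bool = True, zero_init: bool = False):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            w = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, din: int, dout: int,
                 zero_init: bool = False):
        w = np.zeros((din, dout)) if zero_init else he_init(
            rng, (din, dout), din)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(dout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class SGD:
    """SGD with momentum and global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float,
                 momentum: float = 0.9, clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, v, g in zip(self.params, self.vel, grads):
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def save_params(path, state: dict[str, np.ndarray], **meta) -> None:
    import json

    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_params(path) -> tuple[dict[str, np.ndarray], dict]:
    import json

    with np.load(path) as z:
        state = {k: z[k] for k in z.files if k != "__meta__"}
        meta = json.loads(z["__meta__"].tobytes().decode()) if "__meta__" in z.files else {}
    return state, meta
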