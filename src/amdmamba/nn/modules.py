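"""Layer primitives: Module base class, Linear, LayerNorm, feed-forward."""

from __future__ import annotations

import hashlib

import numpy as np

from .tensor import Tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "FeedForward"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery.

    Submodules may live in attributes, lists or tuples.  Parameter names are
    dotted paths, which gives stable state dicts for checkpointing, freezing
    and hashing.
    """

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{key}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{key}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on: {sorted(missing)}")
        for name, arr in state.items():
            own[name].data = np.array(arr, dtype=np.float64)

    def state_hash(self) -> str:
        """SHA-256 over all parameter bytes, in name order."""
        h = hashlib.sha256()
        for name in sorted(dict(self.named_parameters())):
            p = dict(self.named_parameters())[name]
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalization over the last axis with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.weight + self.bias


class FeedForward(Module):
    """Two-layer MLP with GELU, no internal residual."""

    def __init__(self, dim: int, ratio: float, rng: np.random.Generator):
        hidden = max(1, int(round(dim * ratio)))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())
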