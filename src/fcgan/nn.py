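"""Neural-network building blocks used by the generative and classifier models.

Layers follow the conventions of the architectures they serve: linear maps
with optional spectral normalization (weight divided by its leading singular
value, estimated by power iteration), batch normalization with running
statistics for evaluation mode, layer normalization, inverted dropout and a
class-embedding table. Optimization is plain Adam.

Every layer exposes ``__call__(x: Tensor, train: bool) -> Tensor`` and
``parameters()``; parameter initialization is driven by an explicit
``numpy.random.Generator`` so that builds are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Linear",
    "Embedding",
    "BatchNorm1d",
    "LayerNorm",
    "Dropout",
    "Adam",
    "bce_with_logits",
    "mse_loss",
    "concat",
]


class Module:
    def _children(self):
        for value in self.__dict__.values():
            items = value if isinstance(value, (list, tuple)) else (value,)
            for item in items:
                yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for item in self._children():
            if isinstance(item, Tensor) and item.requires_grad:
                params.append(item)
            elif isinstance(item, Module):
                params.extend(item.parameters())
        return params

    def _extra_arrays(self) -> list[np.ndarray]:
        """Non-parameter state (running statistics, power-iteration vectors)."""
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module, in deterministic traversal order."""
        arrays: list[np.ndarray] = []
        for item in self._children():
            if isinstance(item, Tensor) and item.requires_grad:
                arrays.append(item.data)
            elif isinstance(item, Module):
                arrays.extend(item.state_arrays())
        arrays.extend(self._extra_arrays())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(arrays):
            raise ValueError(f"state mismatch: module has {len(targets)} arrays, "
                             f"got {len(arrays)}")
        for tgt, src in zip(targets, arrays):
            if tgt.shape != np.asarray(src).shape:
                raise ValueError("state array shape mismatch")
            tgt[...] = src


class Linear(Module):
    """y = x W + b, optionally with spectral normalization of W.

    Spectral normalization divides W by its largest singular value,
    estimated with one power-iteration step per forward call (the estimate
    is treated as a constant during backprop).
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 spectral_norm: bool = False):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.spectral_norm = spectral_norm
        if spectral_norm:
            u = rng.standard_normal(n_out)
            self._u = u / np.linalg.norm(u)

    def _sigma(self, update: bool) -> float:
        w = self.weight.data
        u = self._u
        v = w @ u
        v /= max(np.linalg.norm(v), 1e-12)
        u_new = w.T @ v
        sigma = float(np.linalg.norm(u_new))
        if update and sigma > 0:
            self._u = u_new / sigma
        return max(sigma, 1e-12)

    def normalized_weight(self, update_power_iter: bool = False) -> Tensor:
        if not self.spectral_norm:
            return self.weight
        return self.weight * (1.0 / self._sigma(update_power_iter))

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return x @ self.normalized_weight(update_power_iter=train) + self.bias

    def _extra_arrays(self):
        return [self._u] if self.spectral_norm else []


class Embedding(Module):
    """Lookup table mapping integer class indices to learned vectors."""

    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.standard_normal((n_classes, dim)) * 0.1,
                             requires_grad=True)
        self.n_classes = n_classes

    def __call__(self, idx: np.ndarray, train: bool = True) -> Tensor:
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.n_classes:
            raise ValueError(f"class index out of range [0, {self.n_classes})")
        return self.weight.take_rows(idx)


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def _extra_arrays(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        if train and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            norm = centered / (var + self.eps).sqrt()
        else:
            norm = (x - self.running_mean) * (1.0
                                              / np.sqrt(self.running_var + self.eps))
        return norm * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; the mask is drawn from the rng passed at call time."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, train: bool = True,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not train or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bias1 = 1 - self.b1**self.t
        bias2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p.data -= self.lr * (self.m[i] / bias1) / (np.sqrt(self.v[i] / bias2)
                                                       + self.eps)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Binary cross-entropy on raw logits, numerically stable.

    mean( softplus(z) - t*z ) == mean( -t*log σ(z) - (1-t)*log(1-σ(z)) ).
    """
    targets = np.asarray(targets, dtype=np.float64)
    return (logits.softplus() - logits * targets).mean()


def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(target)
    return ((pred - target) ** 2).mean()
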