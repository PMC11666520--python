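"""Small neural-network layer library on top of the autodiff core.

Weight initialization is Glorot-uniform from a caller-supplied numpy
Generator, so whole models are reproducible from a single seed. Dropout
draws from the same generator during training and is the identity in
evaluation mode.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Tensor], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params: list[Tensor], seen: set[int]) -> None:
        if isinstance(value, Tensor) and value.requires_grad:
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for v in value:
                Module._collect_value(v, params, seen)

    def _modules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def train(self) -> "Module":
        self.training = True
        for m in self._modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules():
            m.eval()
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class Adam:
    """Adam with bias-corrected moments and optional decoupled weight decay.

    Weight decay multiplies every parameter of rank >= 2 (weight matrices,
    not biases or normalization gains) by ``1 - lr * weight_decay`` each
    step, before the Adam update.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.weight_decay:
            shrink = 1.0 - self.lr * self.weight_decay
            for p in self.params:
                if p.data.ndim >= 2:
                    p.data = p.data * shrink
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw logits."""
    labels = np.asarray(labels, dtype=int)
    n, n_class = logits.shape
    onehot = np.zeros((n, n_class))
    onehot[np.arange(n), labels] = 1.0
    lse = logits.logsumexp(axis=-1)  # (n, 1)
    picked = (logits * Tensor(onehot)).sum(axis=-1, keepdims=True)
    return (lse - picked).mean()
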