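"""Neural-network building blocks on the numpy autodiff core.

Layers are plain objects holding :class:`~thermoseq._autodiff.Tensor`
parameters; ``forward`` takes an explicit ``training`` flag (dropout masks
and batch-norm batch statistics are active only in training mode, so
inference is deterministic). All randomness (initialization, dropout) flows
from seeded ``numpy.random.RandomState`` instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "Dropout",
    "BatchNorm1d",
    "LayerNorm",
    "Embedding",
    "HeadClassifier",
    "LSTM",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerBlock",
    "Adam",
    "TrainingConfig",
    "logits_cross_entropy",
    "get_state",
    "set_state",
]


class Module:
    """Base class providing recursive parameter / buffer discovery."""

    _buffer_names: tuple[str, ...] = ()

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values() if isinstance(v, Tensor) and v.requires_grad]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[tuple["Module", str]]:
        bufs = [(self, name) for name in self._buffer_names]
        for child in self._children():
            bufs.extend(child.buffers())
        return bufs

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def get_state(module: Module) -> list[np.ndarray]:
    state = [p.data.copy() for p in module.parameters()]
    state += [getattr(mod, name).copy() for mod, name in module.buffers()]
    return state


def set_state(module: Module, state: list[np.ndarray]) -> None:
    params = module.parameters()
    for p, arr in zip(params, state):
        p.data = arr.copy()
    for (mod, name), arr in zip(module.buffers(), state[len(params):]):
        setattr(mod, name, arr.copy())


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.RandomState):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.RandomState):
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if not training or self.p <= 0.0:
            return x
        keep = (self.rng.random_sample(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class BatchNorm1d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.RandomState):
        self.W = Tensor(0.1 * rng.standard_normal((n_tokens, dim)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.W[idx]


class HeadClassifier(Module):
    """Shared feedforward classification head.

    FC (d → d/2) + ReLU + batch normalization, dropout, FC output layer
    yielding two logits. The first FC layer is optional (the pooled-embedding
    MLP variant tunes whether to include it); with it disabled the head is
    dropout + output layer only.
    """

    def __init__(self, d: int, dropout: float, rng: np.random.RandomState, first_fc: bool = True):
        self.first_fc = first_fc
        hidden = d // 2 if first_fc else d
        if first_fc:
            self.fc1 = Linear(d, hidden, rng)
            self.bn = BatchNorm1d(hidden)
        self.drop = Dropout(dropout, rng)
        self.fc_out = Linear(hidden, 2, rng)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if self.first_fc:
            x = self.bn.forward(self.fc1.forward(x).relu(), training)
        x = self.drop.forward(x, training)
        return self.fc_out.forward(x)


class LSTM(Module):
    """Single-direction LSTM layer (batch, time, features) → (batch, time, hidden)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.RandomState):
        self.hidden = hidden
        limit = np.sqrt(6.0 / (n_in + 4 * hidden))
        self.Wx = Tensor(rng.uniform(-limit, limit, (n_in, 4 * hidden)), requires_grad=True)
        limit_h = np.sqrt(6.0 / (hidden + 4 * hidden))
        self.Wh = Tensor(rng.uniform(-limit_h, limit_h, (hidden, 4 * hidden)), requires_grad=True)
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(bias, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, T, E = x.shape
        H = self.hidden
        xp = (x.reshape(B * T, E) @ self.Wx + self.b).reshape(B, T, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        states = []
        for t in range(T):
            gates = xp[:, t] + h @ self.Wh
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            states.append(h.reshape(B, 1, H))
        return concat(states, axis=1)


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.RandomState):
        if d % n_heads:
            raise ValueError(f"model width {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        B, T, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q.forward(x)), split(self.k.forward(x)), split(self.v.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.out.forward(ctx)


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.RandomState):
        self.fc1 = Linear(d, d_ff, rng)
        self.fc2 = Linear(d_ff, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2.forward(self.fc1.forward(x).relu())


class TransformerBlock(Module):
    """Pre-layer-norm block: LN → attention → residual, LN → FF → residual."""

    def __init__(self, d: int, n_heads: int, d_ff: int, dropout: float, rng: np.random.RandomState):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(d, d_ff, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None, training: bool) -> Tensor:
        x = x + self.drop.forward(self.attn.forward(self.ln1.forward(x), mask), training)
        x = x + self.drop.forward(self.ff.forward(self.ln2.forward(x)), training)
        return x


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999) with mutable learning rate."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainingConfig:
    """Shared optimization settings for all neural families.

    Only the learning rate is typically tuned; the remaining values are
    conventional defaults (plateau factor 0.1 / patience 5, early-stop
    patience 10, at most 200 epochs). ``early_stop_patience = 0`` disables
    early stopping (the run uses all epochs).
    """

    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 10
    lr: float = 1e-3
    lr_plateau_factor: float = 0.1
    lr_plateau_patience: int = 5
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs) <= 0 or self.lr <= 0:
            raise ValueError("batch_size, max_epochs and lr must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be smaller than max_epochs")


def logits_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of two-class logits against 0/1 labels."""
    probs = softmax(logits, axis=-1)
    picked = probs[np.arange(len(labels)), labels]
    return -((picked + 1e-12).log().mean())
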