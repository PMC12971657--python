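"""Neural-network building blocks on top of the autodiff engine.

Provides the ``Module`` container with recursive parameter discovery and a
state-dict interface, plus the layers the backbone needs: ``Linear``,
``LayerNorm``, feed-forward helpers and stable softmax / cross-entropy.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, astensor


def parameter(data) -> Tensor:
    # leaf parameters stay trainable even when created inside no_grad()
    # (e.g. a model rebuilt from a checkpoint during evaluation)
    t = Tensor(np.asarray(data, dtype=DTYPE))
    t.requires_grad = True
    return t


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal init (resampled beyond 2 std), the transformer default."""
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Minimal module container: attribute-scanned parameters, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield from m.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, ModuleList):
                for m in value:
                    m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """A list of modules that participates in parameter discovery."""


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            rng = rng or np.random.default_rng(0)
            w = trunc_normal(rng, (in_features, out_features))
        self.weight = parameter(w)
        self.bias = parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = astensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Token-wise normalization over the trailing (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = parameter(np.ones(dim))
        self.bias = parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.weight + self.bias


def gelu(x: Tensor) -> Tensor:
    """tanh-approximation GELU."""
    x = astensor(x)
    c = float(np.sqrt(2.0 / np.pi))
    return x * 0.5 * (1.0 + (c * (x + 0.044715 * x * x * x)).tanh())


class FeedForward(Module):
    """Two-layer MLP with GELU, the transformer FFN."""

    def __init__(self, dim: int, hidden_ratio: float, rng: np.random.Generator,
                 zero_init_out: bool = False):
        super().__init__()
        hidden = int(round(dim * hidden_ratio))
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng, zero_init=zero_init_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x - x.data.max(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (N, K)."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=np.int64)]
    return -picked.mean()
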