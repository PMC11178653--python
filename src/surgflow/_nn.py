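"""Dense and recurrent layers, AdamW, and losses on the autodiff engine.

Just enough torch-like machinery for this package's three model stages:
``Dense``/``MLP`` for the contrastive encoder and VAE experts, ``LSTM`` for
the online classifiers, decoupled-weight-decay Adam for all of them.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Dense",
    "MLP",
    "LSTM",
    "AdamW",
    "apply_dropout",
    "l2_normalize",
    "softmax_cross_entropy",
    "softmax",
]


class Module:
    """Base class: recursively collects ``Tensor`` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr


class Dense(Module):
    """Affine layer ``x @ W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Stack of Dense layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class LSTM(Module):
    """Single-layer LSTM; returns the full hidden-state sequence.

    Strictly causal: the hidden state at step t is a function of inputs
    1..t only, which is what makes the downstream classifier online.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        s_x = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.Wx = Tensor(rng.normal(0, s_x, size=(n_in, 4 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0, s_h, size=(n_hidden, 4 * n_hidden)), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias: remember by default
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, D) -> hidden states (B, T, H)."""
        B, T, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs: list[Tensor] = []
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h.reshape(B, 1, H))
        return concat(hs, axis=1)


class AdamW(Module):
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


def apply_dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def l2_normalize(x: Tensor, eps: float = 1e-12, guard: bool = True):
    """Row-wise L2 normalization of the last axis.

    With ``guard``, rows whose pre-normalization norm is below 1e-12 are
    replaced by the first basis vector (a defined unit vector instead of
    NaN); guarded rows do not backpropagate.
    """
    sq = (x * x).sum(axis=-1, keepdims=True)
    norm = (sq + eps * eps).sqrt()
    out = x / norm
    if guard:
        bad = np.sqrt(sq.data.squeeze(-1)) < 1e-12
        if np.any(bad):
            data = out.data.copy()
            data[bad] = 0.0
            data[bad, ..., 0] = 1.0
            fixed = Tensor(data)
            # keep graph for good rows only
            keep = Tensor((~bad)[..., None].astype(float))
            out = out * keep + fixed * Tensor(bad[..., None].astype(float))
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax over the last axis (for inference)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: Tensor) -> Tensor:
    m = Tensor(logits.data.max(axis=-1, keepdims=True))  # detached shift
    z = logits - m
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    return z - lse


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Mean cross-entropy over unmasked rows.

    logits: (N, C); labels: (N,) ints; mask: (N,) bool, True = count the row.
    Rows with label < 0 are always excluded.
    """
    labels = np.asarray(labels)
    valid = labels >= 0
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no labeled rows in the batch")
    C = logits.shape[-1]
    onehot = np.zeros((labels.shape[0], C))
    onehot[valid, labels[valid]] = 1.0
    logp = log_softmax(logits)
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)
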