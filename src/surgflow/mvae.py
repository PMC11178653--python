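"""Multimodal variational autoencoder with product-of-experts fusion.

Each modality (visual features v, left-arm and right-arm kinematics) has its
own Gaussian encoder q(z|x_m) and decoder p(x_m|z).  Per-frame posteriors are
fused by a product of experts: precisions add, and a standard-normal prior
expert N(0, I) is always part of the product, so inference from any subset of
modalities — down to a single one — is well defined.  Conditional
independence of the modalities given z is the modeling assumption that makes
the product the exact joint posterior.

The training loss sums, over a batch:

* for each modality m, a unimodal ELBO — reconstructing only x_m from its own
  prior-fused posterior, with a beta-weighted KL to the prior; and
* one joint ELBO — reconstructing all modalities (weights lambda_m) from the
  PoE-fused joint posterior, again with a beta-weighted KL.

The unimodal terms stop any single modality from dominating the shared code.
Decoders are unit-variance diagonal Gaussians, i.e. squared-error
reconstruction plus the Gaussian normalizing constant.  With one modality the
loss is exactly twice the standard beta-VAE loss.

Training uses AdamW and early stopping on held-out demonstrations: never
stop before ``min_epochs``, stop after ``patience`` epochs without a new
validation minimum, hard cap at ``max_epochs``; the best-validation weights
are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._nn import MLP, AdamW, Module
from .data import Demonstration

__all__ = [
    "GaussianBelief",
    "MVAEConfig",
    "poe_combine",
    "kl_to_prior",
    "mvae_loss",
    "EarlyStopping",
    "MultimodalVAE",
    "MVAEResults",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-6


@dataclass
class GaussianBelief:
    """Diagonal-Gaussian belief over the shared latent z (possibly batched:
    arrays are (..., Z))."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and variance shapes differ")
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.var)):
            raise ValueError("belief must be finite")
        if np.any(self.var <= 0):
            raise ValueError("variance must be positive")


def poe_combine(experts: list[GaussianBelief], include_prior: bool = True) -> GaussianBelief:
    """Product of diagonal-Gaussian experts (optionally including N(0, I)).

    Precisions add; the mean is the precision-weighted average of expert
    means (the prior contributes precision 1 and mean 0 per coordinate).
    """
    if not experts and not include_prior:
        raise ValueError("empty expert list without a prior")
    precision = 1.0 if include_prior else 0.0
    weighted = 0.0
    for e in experts:
        precision = precision + 1.0 / e.var
        weighted = weighted + e.mean / e.var
    var = 1.0 / precision
    return GaussianBelief(mean=weighted * var, var=var)


def kl_to_prior(q: GaussianBelief) -> float:
    """Closed-form KL( q || N(0, I) ), summed over dimensions (and averaged
    over any batch axes)."""
    per_dim = 0.5 * (q.mean**2 + q.var - 1.0 - np.log(q.var))
    per_sample = per_dim.sum(axis=-1)
    return float(np.mean(per_sample))


@dataclass
class MVAEConfig:
    """Architecture and optimization settings.

    Reference-scale defaults: kinematic encoder hidden {200, 500}, visual
    hidden {1000}, shared z of 500, beta 0.1, lr 1e-4, batch 256, early
    stopping between 25 and 300 epochs with patience 15.  Desk-scale runs
    override sizes via the experiment configuration.
    """

    modalities: tuple[str, ...] = ("visual", "kin_left", "kin_right")
    input_dims: dict = field(default_factory=dict)
    hidden: dict = field(
        default_factory=lambda: {
            "visual": (1000,),
            "kin_left": (200, 500),
            "kin_right": (200, 500),
        }
    )
    z_dim: int = 500
    beta: float = 0.1
    lambdas: dict = field(default_factory=dict)  # default 1.0 per modality
    lr: float = 1e-4
    batch_size: int = 256
    min_epochs: int = 25
    patience: int = 15
    max_epochs: int = 300
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if len(self.modalities) < 1:
            raise ValueError("need at least one modality")
        for m in self.modalities:
            self.lambdas.setdefault(m, 1.0)
            if self.lambdas[m] < 0:
                raise ValueError("lambda weights must be >= 0")


class _ModalityEncoder(Module):
    """MLP trunk with mean and variance heads (softplus + floor)."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], z_dim: int, rng):
        self.trunk = MLP([n_in, *hidden, 2 * z_dim], rng)
        self.z_dim = z_dim

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        out = self.trunk(x)
        mean = out[..., : self.z_dim]
        var = out[..., self.z_dim :].softplus() + _VAR_FLOOR
        return mean, var


class _MVAENet(Module):
    def __init__(self, config: MVAEConfig, rng):
        self.config = config
        self.encoders = {}
        self.decoders = {}
        for m in config.modalities:
            d = config.input_dims[m]
            h = tuple(config.hidden.get(m, (64,)))
            self.encoders[m] = _ModalityEncoder(d, h, config.z_dim, rng)
            self.decoders[m] = MLP([config.z_dim, *reversed(h), d], rng)

    def parameters(self):
        params = []
        for m in self.config.modalities:
            params.extend(self.encoders[m].parameters())
            params.extend(self.decoders[m].parameters())
        return params


def _poe_tensors(
    experts: list[tuple[Tensor, Tensor]], include_prior: bool = True
) -> tuple[Tensor, Tensor]:
    """Differentiable PoE on (mean, var) Tensor pairs."""
    if not experts and not include_prior:
        raise ValueError("empty expert list without a prior")
    precision = None
    weighted = None
    for mean, var in experts:
        p = 1.0 / var
        w = mean / var
        precision = p if precision is None else precision + p
        weighted = w if weighted is None else weighted + w
    if include_prior:
        precision = 1.0 + precision if precision is not None else None
    if precision is None:  # prior only
        raise ValueError("prior-only fusion has no tensor inputs")
    var = 1.0 / precision
    mean = weighted * var
    return mean, var


def _kl_tensor(mean: Tensor, var: Tensor) -> Tensor:
    return (0.5 * (mean * mean + var - 1.0 - var.log())).sum(axis=-1).mean()


def _gauss_nll(x: np.ndarray, recon: Tensor) -> Tensor:
    """Unit-variance Gaussian negative log likelihood, mean over the batch."""
    d = x.shape[-1]
    sq = ((recon - Tensor(x)) ** 2).sum(axis=-1)
    return (0.5 * sq).mean() + 0.5 * d * _LOG2PI


def mvae_loss(
    net: _MVAENet,
    batch: dict[str, np.ndarray],
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Total multimodal ELBO loss and a per-term breakdown.

    One reparameterized sample per expectation; ``eps`` (a (B, Z) array)
    fixes the same noise for every term — with ``eps=None`` fresh noise is
    drawn per term from ``rng`` (or zeros if no rng, i.e. posterior means).
    """
    cfg = net.config
    missing = [m for m in cfg.modalities if m not in batch]
    if missing:
        raise ValueError(f"batch is missing modalities: {missing}")
    B = next(iter(batch.values())).shape[0]

    def draw(shape):
        if eps is not None:
            return eps
        if rng is None:
            return np.zeros(shape)
        return rng.normal(size=shape)

    beliefs = {}
    for m in cfg.modalities:
        mean, var = net.encoders[m](Tensor(np.asarray(batch[m], dtype=float)))
        if not (np.all(np.isfinite(mean.data)) and np.all(np.isfinite(var.data))):
            raise FloatingPointError(f"non-finite encoder output for modality {m!r}")
        beliefs[m] = (mean, var)

    total = None
    breakdown: dict[str, float] = {}

    def accumulate(term: Tensor, name: str):
        nonlocal total
        if not np.isfinite(term.item()):
            raise FloatingPointError(f"non-finite loss term {name!r}")
        breakdown[name] = term.item()
        total = term if total is None else total + term

    # unimodal ELBOs: each modality reconstructs only itself from its own
    # prior-fused posterior
    for m in cfg.modalities:
        q_mean, q_var = _poe_tensors([beliefs[m]], include_prior=True)
        z = q_mean + q_var.sqrt() * Tensor(draw((B, cfg.z_dim)))
        accumulate(_gauss_nll(batch[m], net.decoders[m](z)), f"recon_{m}|{m}")
        accumulate(cfg.beta * _kl_tensor(q_mean, q_var), f"kl_{m}")

    # joint ELBO: all modalities from the fused posterior
    q_mean, q_var = _poe_tensors(list(beliefs.values()), include_prior=True)
    z = q_mean + q_var.sqrt() * Tensor(draw((B, cfg.z_dim)))
    for m in cfg.modalities:
        accumulate(
            cfg.lambdas[m] * _gauss_nll(batch[m], net.decoders[m](z)),
            f"recon_{m}|joint",
        )
    accumulate(cfg.beta * _kl_tensor(q_mean, q_var), "kl_joint")
    return total, breakdown


class EarlyStopping:
    """Min-epochs / patience / cap stopping on a validation loss.

    ``update`` is called once per completed epoch (1-based) and returns True
    when training should stop: never before ``min_epochs``, when ``patience``
    epochs have passed without a new minimum, always at ``max_epochs``.
    """

    def __init__(self, min_epochs: int = 25, patience: int = 15, max_epochs: int = 300):
        self.min_epochs = min_epochs
        self.patience = patience
        self.max_epochs = max_epochs
        self.best = np.inf
        self.best_epoch = 0
        self.improved = False

    def update(self, epoch: int, val_loss: float) -> bool:
        self.improved = val_loss < self.best
        if self.improved:
            self.best = val_loss
            self.best_epoch = epoch
        if epoch >= self.max_epochs:
            return True
        if epoch < self.min_epochs:
            return False
        return (epoch - self.best_epoch) >= self.patience


class MultimodalVAE:
    """Model object: per-demo modality streams plus the MVAE configuration.

    Built either from :class:`Demonstration` objects (with precomputed visual
    features substituted via ``visual_features``) or from raw per-demo arrays.
    """

    def __init__(
        self,
        demos: list[Demonstration],
        config: MVAEConfig | None = None,
        visual_features: dict[str, np.ndarray] | None = None,
    ):
        if not demos:
            raise ValueError("need at least one demonstration")
        self.demos = demos
        streams: dict[str, dict[str, np.ndarray]] = {}
        for d in demos:
            vis = visual_features[d.demo_id] if visual_features else d.visual
            if vis.shape[0] != d.n_frames:
                raise ValueError(f"visual features of {d.demo_id} not frame-aligned")
            streams[d.demo_id] = {
                "visual": np.asarray(vis, dtype=float),
                "kin_left": d.kin_left,
                "kin_right": d.kin_right,
            }
        self.streams = streams
        config = config or MVAEConfig()
        dims = {m: streams[demos[0].demo_id][m].shape[1] for m in config.modalities}
        if config.input_dims:
            for m, v in dims.items():
                if config.input_dims.get(m, v) != v:
                    raise ValueError(f"configured input dim for {m} does not match data")
        config.input_dims = dims
        self.config = config

    def fit(self, seed: int = 0, out_dir: str | Path | None = None) -> "MVAEResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        net = _MVAENet(cfg, rng)
        optim = AdamW(net.parameters(), lr=cfg.lr)

        ids = sorted(self.streams)
        n_val = max(1, int(round(cfg.val_fraction * len(ids))))
        if n_val >= len(ids):
            raise ValueError("validation split leaves no training demonstrations")
        perm = rng.permutation(len(ids))
        val_ids = [ids[i] for i in perm[:n_val]]
        train_ids = [ids[i] for i in perm[n_val:]]

        def stacked(which: list[str]) -> dict[str, np.ndarray]:
            return {
                m: np.concatenate([self.streams[i][m] for i in which], axis=0)
                for m in cfg.modalities
            }

        train = stacked(train_ids)
        val = stacked(val_ids)
        n_train = next(iter(train.values())).shape[0]

        stopper = EarlyStopping(cfg.min_epochs, cfg.patience, cfg.max_epochs)
        train_history: list[float] = []
        val_history: list[float] = []
        best_state = net.state_dict()
        epoch = 0
        while True:
            epoch += 1
            order = rng.permutation(n_train)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = {m: train[m][idx] for m in cfg.modalities}
                loss, _ = mvae_loss(net, batch, rng=rng)
                optim.zero_grad()
                loss.backward()
                optim.step()
                epoch_loss += loss.item()
                n_batches += 1
            train_history.append(epoch_loss / n_batches)
            val_loss, _ = mvae_loss(net, val, rng=None)  # posterior means: stable
            val_history.append(val_loss.item())
            stop = stopper.update(epoch, val_loss.item())
            if stopper.improved:
                best_state = {k: v.copy() for k, v in net.state_dict().items()}
            if stop:
                break
        net.load_state_dict(best_state)
        results = MVAEResults(
            model=self,
            net=net,
            train_history=train_history,
            val_history=val_history,
            stopped_epoch=epoch,
            best_epoch=stopper.best_epoch,
            best_val_loss=stopper.best,
            val_ids=val_ids,
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            np.savez(out / "mvae_best.npz", **net.state_dict())
            np.savetxt(out / "mvae_val_loss.txt", np.asarray(val_history))
        return results


@dataclass
class MVAEResults:
    model: MultimodalVAE
    net: _MVAENet
    train_history: list[float]
    val_history: list[float]
    stopped_epoch: int
    best_epoch: int
    best_val_loss: float
    val_ids: list[str]

    def encode_modality(self, name: str, x: np.ndarray) -> GaussianBelief:
        if name not in self.net.config.modalities:
            raise KeyError(f"unknown modality {name!r}")
        mean, var = self.net.encoders[name](Tensor(np.asarray(x, dtype=float)))
        return GaussianBelief(mean.data, var.data)

    def infer_z(
        self,
        inputs: Demonstration | dict[str, np.ndarray],
        modalities: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        """Posterior-mean latent sequence from any non-empty modality subset
        (deterministic; the prior expert is always in the product)."""
        cfg = self.net.config
        modalities = cfg.modalities if modalities is None else tuple(modalities)
        if not modalities:
            raise ValueError("modality subset must be non-empty")
        for m in modalities:
            if m not in cfg.modalities:
                raise KeyError(f"unknown modality {m!r}")
        if isinstance(inputs, Demonstration):
            data = {m: inputs.modality(m) for m in modalities}
        else:
            data = inputs
        experts = [self.encode_modality(m, data[m]) for m in modalities]
        return poe_combine(experts, include_prior=True).mean

    def posterior(
        self, inputs: dict[str, np.ndarray], modalities: tuple[str, ...] | None = None
    ) -> GaussianBelief:
        cfg = self.net.config
        modalities = tuple(modalities) if modalities else cfg.modalities
        experts = [self.encode_modality(m, inputs[m]) for m in modalities]
        return poe_combine(experts, include_prior=True)

    def reconstruct(self, z: np.ndarray, modality: str) -> np.ndarray:
        if modality not in self.net.config.modalities:
            raise KeyError(f"unknown modality {modality!r}")
        return self.net.decoders[modality](Tensor(np.asarray(z, dtype=float))).data

    def summary(self) -> str:
        cfg = self.net.config
        return "\n".join(
            [
                "Multimodal VAE (product-of-experts fusion)",
                f"  modalities: {', '.join(cfg.modalities)}  z-dim: {cfg.z_dim}  "
                f"beta: {cfg.beta}",
                f"  stopped at epoch {self.stopped_epoch} "
                f"(best validation {self.best_val_loss:.3f} at epoch {self.best_epoch})",
                f"  validation demos: {', '.join(self.val_ids)}",
            ]
        )
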