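"""Single-view time-contrastive representation learning for video frames.

A base encoder f maps a frame to a visual feature v; an MLP projection head
g followed by L2 normalization maps v to an embedding b on the unit sphere.
Training minimizes a triplet loss over (anchor, positive, negative) frames
of the same demonstration:

    L = mean  [ ||b_a - b_p||^2 - ||b_a - b_n||^2 + alpha ]_+

with the positive within ``positive_range`` sampled frames of the anchor and
the negative beyond ``margin_range``.  Temporal neighbors end up closer in
embedding space than distant frames, which makes within-task progression
(and hence gesture structure) linearly visible in v without any labels.
Downstream stages consume v, which retains more information than the
normalized b.

Defaults follow the reference training recipe: 3 FPS training rate,
positive range 6 and margin range 12 (2 s and 4 s), margin 0.2, batch 128,
embedding dimension 32, AdamW with lr 5e-4 and weight decay 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from ._nn import MLP, AdamW, Dense, Module, l2_normalize
from .data import Demonstration, resample

__all__ = [
    "TripletConfig",
    "EncoderSpec",
    "FrameTriplet",
    "sample_triplets",
    "triplet_loss",
    "TimeContrastiveEncoder",
    "TCNResults",
]


@dataclass
class TripletConfig:
    """Triplet sampling and optimization settings (ranges are in sampled-frame
    units at ``train_fps``)."""

    train_fps: float = 3.0
    positive_range: int = 6
    margin_range: int = 12
    margin: float = 0.2
    batch_size: int = 128
    lr: float = 5e-4
    weight_decay: float = 0.01
    epochs: int = 100
    triplets_per_epoch: int = 2048
    holdout_fraction: float = 0.1  # of triplets, for the satisfaction diagnostic
    resample_each_epoch: bool = True  # False: one fixed triplet set for all epochs

    def __post_init__(self):
        if not 0 < self.positive_range < self.margin_range:
            raise ValueError("need 0 < positive_range < margin_range")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class EncoderSpec:
    """Architecture of the base encoder f and projection head g.

    ``backbone`` is "mlp" for precomputed feature vectors or "conv" for
    small grayscale image stacks (a single 5x5 convolution + pooling + MLP;
    a large pretrained backbone is outside desk scale).
    """

    backbone: str = "mlp"
    input_dim: int | tuple[int, int] = 32  # F for mlp, (H, W) for conv
    backbone_hidden: tuple[int, ...] = (64,)
    feature_dim: int = 32  # dimension of v
    projection_hidden: tuple[int, ...] = (1000, 500)
    embed_dim: int = 32  # dimension of b

    def __post_init__(self):
        if self.embed_dim < 2:
            raise ValueError("embedding dim must be >= 2")
        if self.backbone not in ("mlp", "conv", "identity"):
            raise ValueError("backbone must be 'mlp', 'conv' or 'identity'")


@dataclass(frozen=True)
class FrameTriplet:
    demo_id: str
    t_a: int
    t_p: int
    t_n: int


def sample_triplets(
    demo_lengths: dict[str, int],
    config: TripletConfig,
    n: int,
    rng: np.random.Generator,
) -> list[FrameTriplet]:
    """Sample ``n`` triplets uniformly: demo, then anchor, then positive in
    the symmetric window, then negative beyond the margin range (same demo).

    Demos not longer than ``2 * margin_range + 1`` frames are skipped with a
    warning (every anchor there would lack a guaranteed negative).
    """
    r_p, r_m = config.positive_range, config.margin_range
    usable = {d: L for d, L in demo_lengths.items() if L > 2 * r_m + 1}
    skipped = set(demo_lengths) - set(usable)
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} demos shorter than {2 * r_m + 2} sampled frames",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no demonstration is long enough for triplet sampling")
    ids = sorted(usable)
    out: list[FrameTriplet] = []
    for _ in range(n):
        demo = ids[rng.integers(len(ids))]
        L = usable[demo]
        t_a = int(rng.integers(L))
        lo, hi = max(0, t_a - r_p), min(L - 1, t_a + r_p)
        window = [t for t in range(lo, hi + 1) if t != t_a]
        t_p = int(window[rng.integers(len(window))])
        n_left = max(0, t_a - r_m)  # negatives in [0, t_a - r_m)
        n_right = max(0, L - (t_a + r_m + 1))  # and (t_a + r_m, L)
        k = int(rng.integers(n_left + n_right))
        t_n = k if k < n_left else t_a + r_m + 1 + (k - n_left)
        out.append(FrameTriplet(demo, t_a, t_p, t_n))
    return out


def triplet_loss(b_a: Tensor, b_p: Tensor, b_n: Tensor, alpha: float) -> Tensor:
    """Batch-mean hinge loss max(0, d^2_ap - d^2_an + alpha) on unit vectors."""
    if not (b_a.shape == b_p.shape == b_n.shape):
        raise ValueError("triplet embeddings must share a shape")
    d_ap = ((b_a - b_p) ** 2).sum(axis=-1)
    d_an = ((b_a - b_n) ** 2).sum(axis=-1)
    return (d_ap - d_an + alpha).relu().mean()


class _ConvStem(Module):
    """One 5x5/stride-2 convolution (via im2col) + ReLU + global average pool."""

    def __init__(self, hw: tuple[int, int], channels: int, rng: np.random.Generator):
        H, W = hw
        k, s = 5, 2
        oh = (H - k) // s + 1
        ow = (W - k) // s + 1
        rows = []
        for i in range(oh):
            for j in range(ow):
                base = np.arange(k)[:, None] * W + np.arange(k)[None, :]
                rows.append((base + (i * s) * W + j * s).ravel())
        self._idx = np.array(rows)  # (oh*ow, k*k)
        self._hw = (H, W)
        self.proj = Dense(k * k, channels, rng)
        self.out_dim = channels

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        flat = x.reshape(B, self._hw[0] * self._hw[1])
        patches = flat[:, self._idx]  # (B, P, k*k)
        feat = self.proj(patches).relu()  # (B, P, C)
        return feat.mean(axis=1)  # global average pool


class _Encoder(Module):
    """Base encoder f (backbone) + projection head g."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        if spec.backbone == "mlp":
            dims = [int(spec.input_dim), *spec.backbone_hidden, spec.feature_dim]
            self.base = MLP(dims, rng)
        elif spec.backbone == "conv":
            self.stem = _ConvStem(tuple(spec.input_dim), spec.backbone_hidden[0], rng)
            self.head = MLP([self.stem.out_dim, spec.feature_dim], rng)
            self.base = None
        else:  # identity: v is the raw feature vector
            spec.feature_dim = int(spec.input_dim)
            self.base = None
        self.projection = MLP(
            [spec.feature_dim, *spec.projection_hidden, spec.embed_dim], rng
        )

    def features(self, x: Tensor) -> Tensor:
        if self.spec.backbone == "identity":
            return x
        if self.base is not None:
            return self.base(x)
        return self.head(self.stem(x).relu())

    def embed(self, x: Tensor) -> tuple[Tensor, Tensor]:
        v = self.features(x)
        b = l2_normalize(self.projection(v.relu()))
        return v, b


def _frames_to_array(demo: Demonstration) -> np.ndarray:
    if demo.visual_mode == "features":
        return np.asarray(demo.visual, dtype=float)
    imgs = np.asarray(demo.visual, dtype=float) / 255.0
    if imgs.ndim == 4:  # collapse channels to grayscale
        imgs = imgs.mean(axis=-1)
    return imgs


class TimeContrastiveEncoder:
    """Model object: a set of demonstrations plus encoder/triplet settings.

    ``fit`` trains the encoder with the triplet objective at the training
    frame rate and returns a :class:`TCNResults`.
    """

    def __init__(
        self,
        demos: list[Demonstration],
        spec: EncoderSpec | None = None,
        config: TripletConfig | None = None,
    ):
        if not demos:
            raise ValueError("need at least one demonstration")
        self.demos = demos
        self.config = config or TripletConfig()
        if spec is None:
            first = demos[0]
            if first.visual_mode == "features":
                spec = EncoderSpec(backbone="mlp", input_dim=first.visual.shape[1])
            else:
                spec = EncoderSpec(backbone="conv", input_dim=first.visual.shape[1:3])
        self.spec = spec

    def fit(self, seed: int = 0, out_dir: str | Path | None = None) -> "TCNResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        encoder = _Encoder(self.spec, rng)
        optim = AdamW(encoder.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

        train_demos = [resample(d, cfg.train_fps) for d in self.demos]
        frames = {d.demo_id: _frames_to_array(d) for d in train_demos}
        lengths = {d.demo_id: d.n_frames for d in train_demos}

        n_hold = max(1, int(cfg.triplets_per_epoch * cfg.holdout_fraction))
        holdout = sample_triplets(lengths, cfg, n_hold, rng)

        def batch_embed(triplets: list[FrameTriplet]) -> tuple[Tensor, Tensor, Tensor]:
            xa = np.stack([frames[t.demo_id][t.t_a] for t in triplets])
            xp = np.stack([frames[t.demo_id][t.t_p] for t in triplets])
            xn = np.stack([frames[t.demo_id][t.t_n] for t in triplets])
            x = np.concatenate([xa, xp, xn], axis=0)
            _, b = encoder.embed(Tensor(x))
            B = len(triplets)
            return b[:B], b[B : 2 * B], b[2 * B :]

        def satisfaction(triplets: list[FrameTriplet]) -> float:
            ba, bp, bn = batch_embed(triplets)
            d_ap = ((ba.data - bp.data) ** 2).sum(axis=1)
            d_an = ((ba.data - bn.data) ** 2).sum(axis=1)
            return float(np.mean(d_ap + cfg.margin < d_an))

        initial_satisfaction = satisfaction(holdout)
        loss_history: list[float] = []
        out_dir = Path(out_dir) if out_dir is not None else None
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
        fixed_triplets = (
            None
            if cfg.resample_each_epoch
            else sample_triplets(lengths, cfg, cfg.triplets_per_epoch, rng)
        )
        for epoch in range(cfg.epochs):
            triplets = (
                sample_triplets(lengths, cfg, cfg.triplets_per_epoch, rng)
                if fixed_triplets is None
                else fixed_triplets
            )
            perm = rng.permutation(len(triplets))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(triplets), cfg.batch_size):
                batch = [triplets[i] for i in perm[start : start + cfg.batch_size]]
                ba, bp, bn = batch_embed(batch)
                loss = triplet_loss(ba, bp, bn, cfg.margin)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"triplet loss diverged (non-finite) at epoch {epoch}"
                    )
                optim.zero_grad()
                loss.backward()
                optim.step()
                epoch_loss += loss.item()
                n_batches += 1
            loss_history.append(epoch_loss / max(n_batches, 1))
            if out_dir is not None:
                np.savez(out_dir / f"tcn_epoch{epoch:03d}.npz", **encoder.state_dict())
        final_satisfaction = satisfaction(holdout)
        results = TCNResults(
            model=self,
            encoder=encoder,
            loss_history=loss_history,
            initial_satisfaction=initial_satisfaction,
            final_satisfaction=final_satisfaction,
        )
        if out_dir is not None:
            results.save(out_dir / "tcn_final.npz")
            np.savetxt(out_dir / "tcn_loss.txt", np.asarray(loss_history))
        return results


@dataclass
class TCNResults:
    """Trained encoder plus training diagnostics."""

    model: TimeContrastiveEncoder
    encoder: _Encoder
    loss_history: list[float]
    initial_satisfaction: float
    final_satisfaction: float

    def embed(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map frames to (v, b); rows of b are unit-normalized."""
        v, b = self.encoder.embed(Tensor(np.asarray(frames, dtype=float)))
        return v.data, b.data

    def extract_features(
        self,
        demos: list[Demonstration],
        out_fps: float | None = None,
        out_dir: str | Path | None = None,
    ) -> dict[str, np.ndarray]:
        """Per-demo feature matrices v, index-aligned with the kinematics at
        ``out_fps`` (default: the demos' native rate)."""
        out: dict[str, np.ndarray] = {}
        for demo in demos:
            if out_fps is not None and out_fps != demo.fps:
                demo = resample(demo, out_fps)
            v, _ = self.embed(_frames_to_array(demo))
            out[demo.demo_id] = v
            if out_dir is not None:
                from .data import save_array

                path = Path(out_dir) / f"{demo.demo_id}_v.npy"
                save_array(
                    path, v, meta={"demo_id": demo.demo_id, "fps": demo.fps}
                )
        return out

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.encoder.state_dict())

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.encoder.load_state_dict(dict(data))

    def summary(self) -> str:
        spec, cfg = self.model.spec, self.model.config
        lines = [
            "Time-contrastive encoder",
            f"  backbone: {spec.backbone}  v-dim: {spec.feature_dim}  b-dim: {spec.embed_dim}",
            f"  train fps: {cfg.train_fps}  r_p: {cfg.positive_range}  "
            f"r_m: {cfg.margin_range}  alpha: {cfg.margin}",
            f"  epochs: {len(self.loss_history)}  "
            f"final loss: {self.loss_history[-1]:.4f}" if self.loss_history else "  untrained",
            f"  holdout triplet satisfaction: {self.initial_satisfaction:.3f} -> "
            f"{self.final_satisfaction:.3f}",
        ]
        return "\n".join(lines)
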