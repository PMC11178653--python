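"""Online per-granularity workflow classifiers over the shared latent z.

One single-layer LSTM per granularity level (phase / step / gesture), fed
the per-frame latent sequence and trained with masked cross-entropy; frames
labeled -1 (unlabeled) and padding frames contribute nothing to the loss.
Inference is strictly causal: the prediction at frame t depends on z_1..z_t
only, so predictions on any prefix equal the corresponding prefix of the
full-sequence predictions.

Reference-scale defaults: 300 hidden units, 50% dropout on the input and on
the recurrent output, AdamW with lr 1e-3 and weight decay 0.05, batches of
3 demonstrations, 70 epochs, inference at 5 or 30 FPS.

Semi-supervised label budgets are expressed per demonstration:
:func:`mask_labels` keeps the labels of a seeded subset of training
demonstrations and hides the rest (which still feed representation
learning upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from ._nn import LSTM, AdamW, Dense, Module, apply_dropout, softmax, softmax_cross_entropy

__all__ = [
    "ClassifierConfig",
    "PredictionSequence",
    "WorkflowClassifier",
    "ClassifierResults",
    "mask_labels",
]


@dataclass
class ClassifierConfig:
    granularity: str = "gesture"
    n_classes: int | None = None  # inferred from labels when None
    hidden: int = 300
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 0.05
    batch_size: int = 3  # demonstrations per batch
    epochs: int = 70
    fps: float = 5.0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class PredictionSequence:
    """Per-frame class probabilities and the argmax label track."""

    demo_id: str
    fps: float
    probs: np.ndarray  # (T, C), rows sum to 1

    def __post_init__(self):
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError("probability rows must sum to 1")

    @property
    def labels(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


class _Net(Module):
    def __init__(self, n_in: int, hidden: int, n_classes: int, rng):
        self.lstm = LSTM(n_in, hidden, rng)
        self.head = Dense(hidden, n_classes, rng)


class WorkflowClassifier:
    """Model object: latent sequences + frame labels for one granularity.

    ``z_seqs`` maps demo_id -> (T, Z) array; ``labels`` maps demo_id -> (T,)
    int vector with -1 for unlabeled frames.  Demos appearing in ``z_seqs``
    but carrying no labels at all are ignored for training.
    """

    def __init__(
        self,
        z_seqs: dict[str, np.ndarray],
        labels: dict[str, np.ndarray],
        config: ClassifierConfig | None = None,
    ):
        self.config = config or ClassifierConfig()
        usable = {}
        for demo_id, z in z_seqs.items():
            lab = labels.get(demo_id)
            if lab is None:
                continue
            if len(lab) != z.shape[0]:
                raise ValueError(f"labels of {demo_id} not aligned with z")
            if np.any(np.asarray(lab) >= 0):
                usable[demo_id] = (np.asarray(z, dtype=float), np.asarray(lab))
        if not usable:
            raise ValueError("no demonstration has any labeled frame")
        self.sequences = usable
        all_labels = np.concatenate([lab for _, lab in usable.values()])
        observed = np.unique(all_labels[all_labels >= 0])
        n_classes = self.config.n_classes or int(observed.max()) + 1
        if len(observed) < n_classes:
            missing = sorted(set(range(n_classes)) - set(observed.tolist()))
            warnings.warn(
                f"classes {missing} absent from training labels; "
                "they can never be predicted",
                stacklevel=2,
            )
        self.n_classes = n_classes
        self.z_dim = next(iter(usable.values()))[0].shape[1]

    def fit(self, seed: int = 0) -> "ClassifierResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        net = _Net(self.z_dim, cfg.hidden, self.n_classes, rng)
        optim = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        ids = sorted(self.sequences)
        loss_history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(ids))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(ids), cfg.batch_size):
                batch_ids = [ids[i] for i in order[start : start + cfg.batch_size]]
                zs = [self.sequences[i][0] for i in batch_ids]
                ys = [self.sequences[i][1] for i in batch_ids]
                T = max(z.shape[0] for z in zs)
                B = len(zs)
                x = np.zeros((B, T, self.z_dim))
                y = np.full((B, T), -1, dtype=int)
                for k, (z, lab) in enumerate(zip(zs, ys)):
                    x[k, : z.shape[0]] = z
                    y[k, : len(lab)] = lab  # padding stays -1 -> masked
                xt = apply_dropout(Tensor(x), cfg.dropout, rng, train=True)
                h = net.lstm(xt)
                h = apply_dropout(h, cfg.dropout, rng, train=True)
                logits = net.head(h.reshape(B * T, cfg.hidden))
                loss = softmax_cross_entropy(logits, y.reshape(-1))
                if not np.isfinite(loss.item()):
                    raise FloatingPointError("classifier loss diverged")
                optim.zero_grad()
                loss.backward()
                optim.step()
                epoch_loss += loss.item()
                n_batches += 1
            loss_history.append(epoch_loss / n_batches)
        return ClassifierResults(model=self, net=net, loss_history=loss_history)


@dataclass
class ClassifierResults:
    model: WorkflowClassifier
    net: _Net
    loss_history: list[float]

    def predict_online(self, z_seq: np.ndarray, demo_id: str = "") -> PredictionSequence:
        """Causal frame-wise prediction (dropout off, deterministic)."""
        z_seq = np.asarray(z_seq, dtype=float)
        if z_seq.ndim != 2 or z_seq.shape[1] != self.model.z_dim:
            raise ValueError(
                f"expected (T, {self.model.z_dim}) latent sequence, got {z_seq.shape}"
            )
        h = self.net.lstm(Tensor(z_seq[None]))
        logits = self.net.head(h[0]).data
        return PredictionSequence(
            demo_id=demo_id, fps=self.model.config.fps, probs=softmax(logits)
        )

    def summary(self) -> str:
        cfg = self.model.config
        return "\n".join(
            [
                f"Online LSTM classifier ({cfg.granularity})",
                f"  classes: {self.model.n_classes}  hidden: {cfg.hidden}  "
                f"dropout: {cfg.dropout}  fps: {cfg.fps}",
                f"  epochs: {len(self.loss_history)}  "
                f"final loss: {self.loss_history[-1]:.4f}",
                f"  training demos: {len(self.model.sequences)}",
            ]
        )


def mask_labels(
    demo_ids: list[str],
    seed: int,
    labeled_fraction: float | None = None,
    n_labeled: int | None = None,
) -> set[str]:
    """Choose the seeded subset of training demonstrations that keep labels.

    Exactly one of ``labeled_fraction`` (0 < f <= 1) or ``n_labeled`` must be
    given.  The unchosen demos are label-free but still usable for
    representation learning.
    """
    if (labeled_fraction is None) == (n_labeled is None):
        raise ValueError("give exactly one of labeled_fraction or n_labeled")
    if labeled_fraction is not None:
        if not 0 < labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")
        n_labeled = int(round(labeled_fraction * len(demo_ids)))
    if n_labeled < 1:
        raise ValueError("label budget rounds to zero labeled demonstrations")
    if n_labeled > len(demo_ids):
        raise ValueError("label budget exceeds the number of demonstrations")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(demo_ids), size=n_labeled, replace=False)
    ordered = sorted(demo_ids)
    return {ordered[i] for i in sorted(chosen)}
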