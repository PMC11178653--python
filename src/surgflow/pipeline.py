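"""End-to-end orchestration of the three-stage semi-supervised pipeline.

Stage order: time-contrastive encoder on the visual stream (no labels) ->
per-frame visual features v -> multimodal VAE fusing v with both kinematic
streams (no labels) -> shared latents z -> per-granularity online LSTM
classifiers (labels, possibly only for a subset of demonstrations) ->
frame accuracy / edit score / AD-accuracy on held-out demonstrations.

Stages are isolated through per-fold artifacts (:class:`FoldArtifacts`), so
the modality-ablation and label-budget experiments reuse one trained
representation instead of retraining it per condition: modality subsets are
handled by product-of-experts subset inference, label budgets by masking
which training demonstrations keep labels.

``desk_config`` holds the desk-scale problem sizes used throughout the test
suite and the worked examples: the default synthetic benchmark (24 demos,
6 gestures, ~300 frames at 30 Hz) with small encoders and a 32-dimensional
shared latent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .classify import ClassifierConfig, WorkflowClassifier, mask_labels
from .data import (
    CVSplit,
    DatasetIndex,
    Demonstration,
    apply_normalization,
    fit_normalization,
    make_splits,
    resample,
)
from .metrics import MetricConfig, evaluate_fold
from .mvae import MVAEConfig, MultimodalVAE
from .simulate import BenchmarkConfig, make_benchmark
from .tcn import EncoderSpec, TimeContrastiveEncoder, TripletConfig

__all__ = [
    "ExperimentConfig",
    "desk_config",
    "FoldArtifacts",
    "prepare_fold",
    "classify_and_eval",
    "run_pipeline",
    "run_ablation",
    "run_label_sweep",
]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs: data source, CV scheme, stage
    configurations, metric settings, and the global seed."""

    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    scheme: str = "LOUO"
    granularities: tuple[str, ...] = ("phase", "step", "gesture")
    modalities: tuple[str, ...] = ("visual", "kin_left", "kin_right")
    tcn: TripletConfig = field(default_factory=TripletConfig)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    mvae: MVAEConfig = field(default_factory=MVAEConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    feature_fps: float = 30.0
    seed: int = 0
    max_folds: int | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_serializable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _serializable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def desk_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale experiment: small encoders, 32-dim shared latent, training
    runs of a few minutes on one CPU."""
    return ExperimentConfig(
        benchmark=BenchmarkConfig(),
        tcn=TripletConfig(epochs=20, triplets_per_epoch=1024),
        encoder=EncoderSpec(
            backbone="mlp",
            input_dim=32,
            backbone_hidden=(64,),
            feature_dim=32,
            projection_hidden=(64,),
            embed_dim=32,
        ),
        mvae=MVAEConfig(
            hidden={"visual": (64,), "kin_left": (64,), "kin_right": (64,)},
            z_dim=32,
            lr=1e-3,
            min_epochs=10,
            patience=6,
            max_epochs=60,
            val_fraction=0.15,
        ),
        classifier=ClassifierConfig(hidden=64, epochs=50, lr=3e-3, fps=5.0),
        metric=MetricConfig(transition_delay_ms=500.0, fps=5.0),
        seed=seed,
    )


def _stage_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    state = np.random.SeedSequence([seed, *key]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# per-fold representation learning
# ---------------------------------------------------------------------------


@dataclass
class FoldArtifacts:
    """Trained representation stages and caches for one CV fold."""

    split: CVSplit
    config: ExperimentConfig
    demos: dict[str, Demonstration]  # normalized, native fps
    visual_features: dict[str, np.ndarray]  # v per demo at native fps
    tcn_results: object | None
    mvae_results: object
    _z_cache: dict = field(default_factory=dict)

    def latents(
        self, demo_id: str, fps: float, subset: tuple[str, ...] | None = None
    ) -> np.ndarray:
        """Latent sequence for a demo at the requested frame rate, from the
        given modality subset (cached)."""
        subset = tuple(subset) if subset else tuple(self.config.modalities)
        key = (demo_id, fps, subset)
        if key not in self._z_cache:
            demo = self.demos[demo_id]
            stride = int(round(demo.fps / fps))
            inputs = {}
            for m in subset:
                if m == "visual":
                    inputs[m] = self.visual_features[demo_id][::stride]
                else:
                    inputs[m] = demo.modality(m)[::stride]
            self._z_cache[key] = self.mvae_results.infer_z(inputs, subset)
        return self._z_cache[key]

    def labels(self, demo_id: str, fps: float, granularity: str) -> np.ndarray:
        demo = self.demos[demo_id]
        stride = int(round(demo.fps / fps))
        return demo.labels[granularity][::stride]


def prepare_fold(
    demos: list[Demonstration],
    split: CVSplit,
    config: ExperimentConfig,
    labeled_ids: set[str] | None = None,
) -> FoldArtifacts:
    """Fit normalization + representation stages on the training side of one
    fold; returns artifacts for any downstream classification experiment.

    Representation learning never sees labels, so ``labeled_ids`` does not
    affect this stage.
    """
    by_id = {d.demo_id: d for d in demos}
    train = [by_id[i] for i in split.train_ids]
    stats = fit_normalization(train)
    normed = {d.demo_id: apply_normalization(d, stats) for d in demos}
    train_n = [normed[i] for i in split.train_ids]

    use_visual = "visual" in config.modalities
    tcn_results = None
    if use_visual:
        spec = replace(config.encoder)
        first = train_n[0]
        if first.visual_mode == "features":
            spec.input_dim = first.visual.shape[1]
        else:
            spec.backbone = "conv"
            spec.input_dim = first.visual.shape[1:3]
        tcn = TimeContrastiveEncoder(train_n, spec=spec, config=config.tcn)
        tcn_results = tcn.fit(seed=_stage_seed(config.seed, split.fold_id, 1))
        visual_features = tcn_results.extract_features(
            list(normed.values()), out_fps=config.feature_fps
        )
    else:
        visual_features = {}

    mvae_cfg = replace(
        config.mvae,
        modalities=tuple(config.modalities),
        input_dims={},
        lambdas=dict(config.mvae.lambdas),
    )
    mvae = MultimodalVAE(
        train_n,
        config=mvae_cfg,
        visual_features=visual_features if use_visual else None,
    )
    mvae_results = mvae.fit(seed=_stage_seed(config.seed, split.fold_id, 2))
    return FoldArtifacts(
        split=split,
        config=config,
        demos=normed,
        visual_features=visual_features,
        tcn_results=tcn_results,
        mvae_results=mvae_results,
    )


def classify_and_eval(
    artifacts: FoldArtifacts,
    granularity: str,
    n_classes: int,
    labeled_ids: set[str] | None = None,
    subset: tuple[str, ...] | None = None,
    seed_key: int = 0,
) -> dict:
    """Train one classifier on the fold's training latents and evaluate it on
    the fold's test demonstrations."""
    cfg = artifacts.config
    clf_cfg = replace(cfg.classifier, granularity=granularity, n_classes=n_classes)
    fps = clf_cfg.fps
    train_ids = list(artifacts.split.train_ids)
    if labeled_ids is not None:
        label_src = [i for i in train_ids if i in labeled_ids]
    else:
        label_src = train_ids
    if not label_src:
        raise ValueError("no labeled training demonstrations")
    z_train = {i: artifacts.latents(i, fps, subset) for i in label_src}
    y_train = {i: artifacts.labels(i, fps, granularity) for i in label_src}
    clf = WorkflowClassifier(z_train, y_train, clf_cfg)
    results = clf.fit(
        seed=_stage_seed(cfg.seed, artifacts.split.fold_id, 3, seed_key)
    )
    predictions, references = {}, {}
    for demo_id in artifacts.split.test_ids:
        z = artifacts.latents(demo_id, fps, subset)
        predictions[demo_id] = results.predict_online(z, demo_id).labels
        references[demo_id] = artifacts.labels(demo_id, fps, granularity)
    metric_cfg = replace(cfg.metric, fps=fps)
    report = evaluate_fold(predictions, references, metric_cfg)
    report["granularity"] = granularity
    report["classifier_summary"] = results.summary()
    return report


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def _folds(demos, index, config) -> list[CVSplit]:
    splits = make_splits(index, config.scheme)
    if config.max_folds is not None:
        splits = splits[: config.max_folds]
    return splits


def _aggregate_folds(fold_reports: list[dict]) -> dict:
    out = {}
    for metric in ("accuracy", "edit_score", "ad_accuracy"):
        vals = [r["aggregate"][metric]["mean"] for r in fold_reports]
        out[metric] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return out


def run_pipeline(
    config: ExperimentConfig,
    demos: list[Demonstration] | None = None,
    index: DatasetIndex | None = None,
    labeled_ids: set[str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """The full experiment: cross-validated three-stage pipeline + metrics.

    Returns a manifest with per-fold, per-granularity reports and
    cross-fold aggregates; written as JSON when ``out_dir`` is given.
    """
    if demos is None:
        demos, index = make_benchmark(config.benchmark, seed=config.seed)
    results: dict = {
        "seed": config.seed,
        "scheme": config.scheme,
        "config_hash": config.config_hash(),
        "folds": [],
    }
    for split in _folds(demos, index, config):
        artifacts = prepare_fold(demos, split, config)
        fold_entry = {"fold_id": split.fold_id, "test_ids": split.test_ids, "reports": {}}
        for g in config.granularities:
            n_classes = len(index.granularities[g])
            fold_entry["reports"][g] = classify_and_eval(
                artifacts, g, n_classes, labeled_ids=labeled_ids
            )
        results["folds"].append(fold_entry)
    results["aggregate"] = {
        g: _aggregate_folds([f["reports"][g] for f in results["folds"]])
        for g in config.granularities
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(results, indent=1))
    return results


def run_ablation(
    config: ExperimentConfig,
    modality_subsets: list[tuple[str, ...]],
    demos: list[Demonstration] | None = None,
    index: DatasetIndex | None = None,
    granularity: str = "gesture",
) -> dict:
    """Modality-ablation table: one row per input-modality subset.

    The representation (trained once per fold on all modalities) is queried
    with each subset via product-of-experts subset inference; the classifier
    is retrained per subset.
    """
    if not modality_subsets:
        raise ValueError("modality_subsets must be non-empty")
    if demos is None:
        demos, index = make_benchmark(config.benchmark, seed=config.seed)
    n_classes = len(index.granularities[granularity])
    rows: dict[tuple[str, ...], list[dict]] = {tuple(s): [] for s in modality_subsets}
    for split in _folds(demos, index, config):
        artifacts = prepare_fold(demos, split, config)
        for k, subset in enumerate(modality_subsets):
            report = classify_and_eval(
                artifacts, granularity, n_classes, subset=tuple(subset), seed_key=10 + k
            )
            rows[tuple(subset)].append(report)
    table = {}
    for subset, reports in rows.items():
        table["+".join(subset)] = _aggregate_folds(reports)
    return {"granularity": granularity, "rows": table}


def run_label_sweep(
    config: ExperimentConfig,
    labeled_counts: list[int],
    demos: list[Demonstration] | None = None,
    index: DatasetIndex | None = None,
    granularity: str = "gesture",
) -> dict:
    """Accuracy versus number of labeled training demonstrations.

    Representation stages are trained once per fold on every training
    demonstration (no labels involved); only the classifier is retrained for
    each label budget, on a seeded subset of demonstrations that keep labels.
    """
    if not labeled_counts:
        raise ValueError("labeled_counts must be non-empty")
    if demos is None:
        demos, index = make_benchmark(config.benchmark, seed=config.seed)
    n_classes = len(index.granularities[granularity])
    curve: dict[int, list[dict]] = {int(c): [] for c in labeled_counts}
    for split in _folds(demos, index, config):
        artifacts = prepare_fold(demos, split, config)
        for count in labeled_counts:
            count = int(count)
            if count >= len(split.train_ids):
                labeled = None  # full supervision
            else:
                labeled = mask_labels(
                    list(split.train_ids),
                    seed=_stage_seed(config.seed, split.fold_id, 4, count),
                    n_labeled=count,
                )
            report = classify_and_eval(
                artifacts,
                granularity,
                n_classes,
                labeled_ids=labeled,
                seed_key=100 + count,
            )
            curve[count].append(report)
    points = {
        count: _aggregate_folds(reports) for count, reports in curve.items()
    }
    return {"granularity": granularity, "points": points}
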