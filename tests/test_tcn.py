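"""Time-contrastive encoder: triplet sampling, loss, training, extraction."""

import numpy as np
import pytest

from surgflow._autodiff import Tensor
from surgflow.simulate import BenchmarkConfig, make_benchmark
from surgflow.tcn import (
    EncoderSpec,
    FrameTriplet,
    TimeContrastiveEncoder,
    TripletConfig,
    sample_triplets,
    triplet_loss,
)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def test_triplet_config_validation():
    with pytest.raises(ValueError):
        TripletConfig(positive_range=12, margin_range=6)
    with pytest.raises(ValueError):
        TripletConfig(margin=0.0)


# -- sampling ----------------------------------------------------------------


def test_sample_triplets_windows_respect_ranges():
    cfg = TripletConfig(positive_range=6, margin_range=12)
    rng = np.random.default_rng(0)
    triplets = sample_triplets({"d": 100}, cfg, 3000, rng)
    for t in triplets:
        assert t.t_p != t.t_a and abs(t.t_p - t.t_a) <= 6
        assert abs(t.t_n - t.t_a) > 12
        assert 0 <= t.t_p < 100 and 0 <= t.t_n < 100
    # for anchors at 50 the stated windows are hit exactly
    at50 = [t for t in triplets if t.t_a == 50]
    assert at50, "expected some anchors at frame 50"
    assert all(44 <= t.t_p <= 56 for t in at50)
    assert all(t.t_n <= 37 or t.t_n >= 63 for t in at50)


def test_sample_triplets_skips_short_demos_and_errors_when_none_usable():
    cfg = TripletConfig(positive_range=6, margin_range=12)
    with pytest.warns(UserWarning, match="skipping"):
        triplets = sample_triplets(
            {"short": 25, "long": 40}, cfg, 100, np.random.default_rng(0)
        )
    assert all(t.demo_id == "long" for t in triplets)
    with pytest.raises(ValueError, match="long enough"):
        sample_triplets({"short": 25}, cfg, 10, np.random.default_rng(0))


def test_sample_triplets_deterministic_under_seed():
    cfg = TripletConfig()
    a = sample_triplets({"d": 80}, cfg, 50, np.random.default_rng(5))
    b = sample_triplets({"d": 80}, cfg, 50, np.random.default_rng(5))
    assert a == b


# -- loss --------------------------------------------------------------------


def test_triplet_loss_analytic_cases():
    e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    # anchor == positive, far negative: hinge inactive
    val = triplet_loss(
        Tensor(e1[None]), Tensor(e1[None]), Tensor(e2[None]), alpha=0.2
    ).item()
    assert val == pytest.approx(max(0.0, 0.0 - 2.0 + 0.2))  # = 0
    # all three coincide: loss equals the margin
    val = triplet_loss(Tensor(e1[None]), Tensor(e1[None]), Tensor(e1[None]), 0.2).item()
    assert val == pytest.approx(0.2)
    # hand arithmetic: a=(1,0), p=(-1,0), n=(0,1) -> 4 - 2 + 0.2
    val = triplet_loss(
        Tensor(e1[None]), Tensor(-e1[None]), Tensor(e2[None]), 0.2
    ).item()
    assert val == pytest.approx(2.2)


def test_batched_triplet_loss_equals_per_triplet_loop():
    rng = np.random.default_rng(1)
    B, D = 64, 8
    ba = np.stack([unit(rng.normal(size=D)) for _ in range(B)])
    bp = np.stack([unit(rng.normal(size=D)) for _ in range(B)])
    bn = np.stack([unit(rng.normal(size=D)) for _ in range(B)])
    batched = triplet_loss(Tensor(ba), Tensor(bp), Tensor(bn), 0.2).item()
    loop = np.mean(
        [
            max(
                0.0,
                np.sum((ba[i] - bp[i]) ** 2) - np.sum((ba[i] - bn[i]) ** 2) + 0.2,
            )
            for i in range(B)
        ]
    )
    assert batched == pytest.approx(loop, abs=1e-6)


def test_triplet_loss_shape_mismatch_errors():
    with pytest.raises(ValueError):
        triplet_loss(Tensor(np.ones((2, 3))), Tensor(np.ones((2, 4))), Tensor(np.ones((2, 3))), 0.2)


# -- embedding contract ------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_dataset():
    cfg = BenchmarkConfig(n_users=2, trials_per_user=1, t_target=300)
    demos, _ = make_benchmark(cfg, seed=2)
    return demos


def desk_spec(F=32):
    return EncoderSpec(
        input_dim=F, backbone_hidden=(32,), feature_dim=16,
        projection_hidden=(32,), embed_dim=8,
    )


def quick_config(**kw):
    defaults = dict(epochs=2, triplets_per_epoch=256, batch_size=64)
    defaults.update(kw)
    return TripletConfig(**defaults)


def test_embed_rows_unit_normalized_and_deterministic(tiny_dataset):
    model = TimeContrastiveEncoder(tiny_dataset, desk_spec(), quick_config(epochs=1))
    results = model.fit(seed=0)
    frames = tiny_dataset[0].visual[:17]
    v, b = results.embed(frames)
    assert np.allclose(np.linalg.norm(b, axis=1), 1.0, atol=1e-5)
    v2, b2 = results.embed(frames)
    assert np.array_equal(v, v2) and np.array_equal(b, b2)
    # identical frames give identical rows
    rep = np.repeat(frames[:1], 4, axis=0)
    vr, br = results.embed(rep)
    assert np.allclose(vr, vr[0]) and np.allclose(br, br[0])


def test_training_improves_triplet_satisfaction(tiny_dataset):
    model = TimeContrastiveEncoder(
        tiny_dataset, desk_spec(), quick_config(epochs=10, triplets_per_epoch=512)
    )
    results = model.fit(seed=0)
    assert results.final_satisfaction > results.initial_satisfaction
    assert len(results.loss_history) == 10
    assert results.loss_history[-1] < results.loss_history[0]


def test_frozen_encoder_loss_constant(tiny_dataset):
    model = TimeContrastiveEncoder(
        tiny_dataset,
        desk_spec(),
        quick_config(epochs=3, lr=0.0, weight_decay=0.0, resample_each_epoch=False),
    )
    results = model.fit(seed=0)
    assert np.allclose(results.loss_history, results.loss_history[0], atol=1e-9)


def test_checkpoints_written_per_epoch(tiny_dataset, tmp_path):
    model = TimeContrastiveEncoder(tiny_dataset, desk_spec(), quick_config(epochs=2))
    model.fit(seed=0, out_dir=tmp_path)
    assert (tmp_path / "tcn_epoch000.npz").exists()
    assert (tmp_path / "tcn_epoch001.npz").exists()
    assert (tmp_path / "tcn_loss.txt").exists()


def test_extract_features_identity_backbone_returns_input(tiny_dataset):
    spec = EncoderSpec(
        backbone="identity", input_dim=32, projection_hidden=(16,), embed_dim=8
    )
    model = TimeContrastiveEncoder(tiny_dataset, spec, quick_config(epochs=1))
    results = model.fit(seed=0)
    feats = results.extract_features(tiny_dataset, out_fps=30.0)
    for demo in tiny_dataset:
        assert np.allclose(feats[demo.demo_id], demo.visual)


def test_extract_features_resamples_to_out_fps(tiny_dataset):
    model = TimeContrastiveEncoder(tiny_dataset, desk_spec(), quick_config(epochs=1))
    results = model.fit(seed=0)
    feats = results.extract_features(tiny_dataset, out_fps=3.0)
    demo = tiny_dataset[0]
    assert feats[demo.demo_id].shape[0] == int(np.ceil(demo.n_frames / 10))
    with pytest.raises(ValueError):
        results.extract_features(tiny_dataset, out_fps=7.0)


def test_neighbors_closer_than_distant_after_training(tiny_dataset):
    """The property the time-contrastive objective optimizes: embeddings of
    temporal neighbors end up closer than those of distant frames."""
    cfg = quick_config(epochs=12, triplets_per_epoch=512)
    model = TimeContrastiveEncoder(tiny_dataset, desk_spec(), cfg)
    results = model.fit(seed=1)
    from surgflow.data import resample

    rng = np.random.default_rng(0)
    near, far = [], []
    for demo in [resample(d, 3.0) for d in tiny_dataset]:
        _, b = results.embed(demo.visual)
        L = len(b)
        for _ in range(200):
            t = rng.integers(L)
            tp = np.clip(t + rng.integers(1, cfg.positive_range + 1), 0, L - 1)
            candidates = np.concatenate(
                [np.arange(0, max(t - cfg.margin_range, 0)),
                 np.arange(min(t + cfg.margin_range + 1, L), L)]
            )
            if len(candidates) == 0 or tp == t:
                continue
            tn = int(rng.choice(candidates))
            near.append(np.sum((b[t] - b[tp]) ** 2))
            far.append(np.sum((b[t] - b[tn]) ** 2))
    assert np.mean(near) < np.mean(far)


def test_conv_backbone_trains_on_image_stacks():
    cfg = BenchmarkConfig(
        n_users=1, trials_per_user=1, render_images=True, t_target=300
    )
    demos, _ = make_benchmark(cfg, seed=1)
    model = TimeContrastiveEncoder(
        demos,
        EncoderSpec(
            backbone="conv", input_dim=(64, 64), backbone_hidden=(8,),
            feature_dim=16, projection_hidden=(16,), embed_dim=8,
        ),
        quick_config(epochs=1, triplets_per_epoch=64, batch_size=32),
    )
    results = model.fit(seed=0)
    v, b = results.embed(demos[0].visual[:5].astype(float) / 255.0)
    assert v.shape == (5, 16)
    assert np.allclose(np.linalg.norm(b, axis=1), 1.0, atol=1e-5)
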