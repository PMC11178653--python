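"""Synthetic workflow generator: semi-Markov sampling, emissions, benchmark."""

import numpy as np
import pytest

from surgflow.data import read_transcript, write_transcript
from surgflow.simulate import (
    BenchmarkConfig,
    EmissionModel,
    WorkflowHierarchy,
    emit_observations,
    left_to_right_hierarchy,
    make_benchmark,
    random_emission_model,
    sample_workflow,
)


def single_gesture_hierarchy():
    return WorkflowHierarchy(
        gesture_to_step=[0],
        step_to_phase=[0],
        min_duration=[1],
        mean_duration=[5],
        transition=[[1.0]],
        initial=[1.0],
    )


def test_hierarchy_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        WorkflowHierarchy([0, 0], [0], [1, 1], [2, 2], [[0.5, 0.4], [0, 1]], [1, 0])
    with pytest.raises(ValueError, match="min duration"):
        WorkflowHierarchy([0], [0], [0], [2], [[1.0]], [1.0])


def test_sample_workflow_degenerate_single_gesture_is_constant():
    labels = sample_workflow(single_gesture_hierarchy(), 20, np.random.default_rng(0))
    assert np.all(labels["gesture"] == 0)
    assert np.all(labels["phase"] == 0)


def test_sample_workflow_forced_left_to_right_chain():
    h = left_to_right_hierarchy(
        n_phases=1, n_steps=1, n_gestures=3, mean_duration=5, min_duration=5
    )
    labels = sample_workflow(h, 15, np.random.default_rng(1))
    assert labels["gesture"].tolist() == [0] * 5 + [1] * 5 + [2] * 5


def test_sample_workflow_unreachable_duration_errors():
    h = left_to_right_hierarchy(n_gestures=3, mean_duration=5, min_duration=5)
    with pytest.raises(ValueError, match="minimum admissible"):
        sample_workflow(h, 4, np.random.default_rng(0))


def test_sample_workflow_deterministic_under_seed():
    h = left_to_right_hierarchy()
    a = sample_workflow(h, 300, np.random.default_rng(42))
    b = sample_workflow(h, 300, np.random.default_rng(42))
    assert np.array_equal(a["gesture"], b["gesture"])


def test_label_hierarchy_containment_at_every_frame():
    h = left_to_right_hierarchy(n_phases=2, n_steps=3, n_gestures=6, skip_prob=0.2)
    labels = sample_workflow(h, 400, np.random.default_rng(3))
    g2s = np.asarray(h.gesture_to_step)
    s2p = np.asarray(h.step_to_phase)
    assert np.array_equal(labels["step"], g2s[labels["gesture"]])
    assert np.array_equal(labels["phase"], s2p[labels["step"]])


def test_state_occupancy_matches_markov_oracle():
    """Empirical per-state frame frequency over many sampled demos matches
    the semi-Markov occupancy pi_i * E[dur_i] computed from the chain."""
    # cyclic 3-state chain so a stationary distribution exists
    trans = np.array([[0, 0.7, 0.3], [0.2, 0, 0.8], [0.5, 0.5, 0]])
    mean_dur = np.array([4.0, 6.0, 8.0])
    h = WorkflowHierarchy(
        gesture_to_step=[0, 0, 0],
        step_to_phase=[0],
        min_duration=[2, 2, 2],
        mean_duration=mean_dur,
        transition=trans,
        initial=[1 / 3, 1 / 3, 1 / 3],
    )
    # oracle: stationary dist of the embedded jump chain, weighted by mean dur
    w, v = np.linalg.eig(trans.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = pi / pi.sum()
    occ = pi * mean_dur
    occ = occ / occ.sum()

    rng = np.random.default_rng(7)
    T, n_demos = 200, 400
    counts = np.zeros(3)
    for _ in range(n_demos):
        g = sample_workflow(h, T, rng)["gesture"]
        counts += np.bincount(g, minlength=3)
    freq = counts / counts.sum()
    # 3 standard errors of a frequency over the effective number of segments
    n_segments = counts.sum() / occ @ mean_dur  # rough effective sample size
    se = np.sqrt(occ * (1 - occ) / n_segments)
    assert np.all(np.abs(freq - occ) < 3 * se + 0.01)


# -- emissions ---------------------------------------------------------------


def noiseless_model(n_gestures=3, K=2, F=4):
    rng = np.random.default_rng(0)
    em = random_emission_model(
        n_gestures, rng, kin_dim=K, feature_dim=F, kin_noise=0.0, visual_noise=0.0,
        pull_rate=1.0, drift_norm=0.0,
    )
    return em


def test_emit_kinematics_fixed_point_with_pull_rate_one():
    em = noiseless_model()
    labels = {"gesture": np.array([0] * 4 + [1] * 4 + [2] * 4)}
    _, kin_l, _ = emit_observations(labels, em, np.random.default_rng(0))
    for g, sl in ((0, slice(1, 4)), (1, slice(5, 8)), (2, slice(9, 12))):
        assert np.allclose(kin_l[sl], em.kin_targets_left[g])


def test_emit_visual_piecewise_constant_without_drift_or_noise():
    em = noiseless_model()
    labels = {"gesture": np.array([0, 0, 1, 1, 2, 2])}
    visual, _, _ = emit_observations(labels, em, np.random.default_rng(0))
    assert np.allclose(visual, em.visual_prototypes[labels["gesture"]])


def test_visual_class_means_approach_prototype_plus_half_drift():
    rng = np.random.default_rng(2)
    em = random_emission_model(
        2, rng, feature_dim=6, kin_noise=0.0, visual_noise=0.05, drift_norm=3.0
    )
    labels = {"gesture": np.repeat(np.tile([0, 1], 200), 10)}
    visual, _, _ = emit_observations(labels, em, rng)
    for g in (0, 1):
        mean = visual[labels["gesture"] == g].mean(axis=0)
        expected = em.visual_prototypes[g] + 0.5 * em.visual_drift[g]
        assert np.allclose(mean, expected, atol=0.1)


def test_emission_model_rejects_identical_joint_parameters():
    with pytest.raises(ValueError, match="identical joint"):
        EmissionModel(
            kin_targets_left=np.zeros((2, 2)),
            kin_targets_right=np.zeros((2, 2)),
            pull_rate=0.5,
            kin_noise=0.1,
            visual_prototypes=np.zeros((2, 3)),
            visual_drift=np.zeros((2, 3)),
            visual_noise=0.1,
        )


def test_complementarity_knob_shares_parameters_within_one_modality():
    rng = np.random.default_rng(0)
    em = random_emission_model(
        4, rng, visual_confusable_pairs=((0, 1),), kinematic_confusable_pairs=((2, 3),)
    )
    assert np.array_equal(em.visual_prototypes[0], em.visual_prototypes[1])
    assert not np.array_equal(em.kin_targets_left[0], em.kin_targets_left[1])
    assert np.array_equal(em.kin_targets_left[2], em.kin_targets_left[3])
    assert not np.array_equal(em.visual_prototypes[2], em.visual_prototypes[3])


def test_single_modality_bayes_ceiling_vs_joint():
    """With a visually confusable gesture pair, a per-frame Gaussian
    classifier on visual features alone cannot exceed the ceiling set by the
    confused pair's occupancy, while the joint classifier can."""
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    cfg = BenchmarkConfig(n_users=6, trials_per_user=2)
    demos, _ = make_benchmark(cfg, seed=5)
    train = demos[: len(demos) // 2]
    test = demos[len(demos) // 2 :]

    def streams(ds):
        vis = np.concatenate([d.visual for d in ds])
        kin = np.concatenate([np.hstack([d.kin_left, d.kin_right]) for d in ds])
        y = np.concatenate([d.labels["gesture"] for d in ds])
        return vis, kin, np.hstack([vis, kin]), y

    vis_tr, kin_tr, joint_tr, y_tr = streams(train)
    vis_te, kin_te, joint_te, y_te = streams(test)

    def acc(X_tr, X_te):
        clf = QuadraticDiscriminantAnalysis(reg_param=0.05).fit(X_tr, y_tr)
        return (clf.predict(X_te) == y_te).mean()

    pair_occupancy = np.isin(y_te, cfg.visual_confusable_pairs[0]).mean()
    ceiling = 1.0 - 0.5 * pair_occupancy  # best case: loses half the pair's frames
    assert acc(vis_tr, vis_te) <= ceiling + 0.02
    assert acc(joint_tr, joint_te) > acc(vis_tr, vis_te)
    assert acc(joint_tr, joint_te) > acc(kin_tr, kin_te)


# -- benchmark ---------------------------------------------------------------


def test_make_benchmark_empty_and_determinism(tmp_path):
    demos, index = make_benchmark(n_demos=0, seed=0)
    assert demos == [] and index.demos == []
    cfg = BenchmarkConfig(n_users=2, trials_per_user=1)
    a, _ = make_benchmark(cfg, seed=3)
    b, _ = make_benchmark(cfg, seed=3)
    for da, db in zip(a, b):
        assert np.array_equal(da.visual, db.visual)
        assert np.array_equal(da.kin_left, db.kin_left)
        assert np.array_equal(da.labels["gesture"], db.labels["gesture"])


def test_benchmark_transcripts_round_trip(tmp_path):
    cfg = BenchmarkConfig(n_users=2, trials_per_user=1)
    demos, index = make_benchmark(cfg, seed=4, out_dir=tmp_path)
    for demo in demos:
        for g, vocab in index.granularities.items():
            path = tmp_path / "transcripts" / g / f"{demo.demo_id}.txt"
            back = read_transcript(path, demo.n_frames, vocab)
            assert np.array_equal(back, demo.labels[g])


def test_rendered_image_mode_produces_uint8_stacks():
    cfg = BenchmarkConfig(
        n_users=1, trials_per_user=1, render_images=True, t_target=150
    )
    demos, _ = make_benchmark(cfg, seed=0)
    d = demos[0]
    assert d.visual_mode == "images"
    assert d.visual.dtype == np.uint8 and d.visual.ndim == 3
    assert d.visual.shape[1:] == (64, 64)
    assert d.visual.max() > 0
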