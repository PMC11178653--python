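"""Synthetic multimodal surgical-workflow benchmark generator.

Emulates the structure of robot-assisted surgery datasets (JIGSAWS-like):
several users, each performing several trials of a task whose workflow is a
three-level hierarchy (phase > step > gesture).  Gesture sequences follow a
semi-Markov process — a left-to-right transition chain with explicit
per-gesture duration laws (shifted Poisson) — and coarser labels are
deterministic containment maps of the gesture state.

Each demonstration carries three synchronized streams at a common frame rate:

* kinematics of the left and right arms: first-order spring pull toward a
  per-gesture target pose plus Gaussian noise;
* visual features: a per-gesture prototype plus a within-segment progression
  drift (so temporal position within a segment is visible to a
  time-contrastive learner) plus Gaussian noise; optionally rendered as
  64x64 grayscale images with two instrument glyphs driven by the
  kinematics.

The default configuration deliberately contains *complementary* modalities:
one gesture pair shares its visual prototype (telling them apart needs
kinematics) and another shares its kinematic targets (telling them apart
needs vision), so single-modality models face a ceiling that the fused
model does not.  A per-user "skill" scalar scales durations and noise to
create the inter-user variability that motivates leave-one-user-out
evaluation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .data import DatasetIndex, Demonstration, DemoRecord, write_dataset

__all__ = [
    "WorkflowHierarchy",
    "EmissionModel",
    "BenchmarkConfig",
    "left_to_right_hierarchy",
    "sample_workflow",
    "emit_observations",
    "random_emission_model",
    "make_benchmark",
]

GRANULARITIES = ("phase", "step", "gesture")


@dataclass
class WorkflowHierarchy:
    """The generator's phase->step->gesture state machine.

    ``gesture_to_step`` and ``step_to_phase`` are containment maps, so labels
    at coarser levels are deterministic functions of the gesture state.
    Durations are shifted Poisson: ``min + Poisson(mean - min)`` frames.
    """

    gesture_to_step: list[int]
    step_to_phase: list[int]
    min_duration: np.ndarray  # per gesture, frames
    mean_duration: np.ndarray
    transition: np.ndarray  # (G, G) row-stochastic over gestures
    initial: np.ndarray  # distribution over starting gestures

    def __post_init__(self):
        G = len(self.gesture_to_step)
        self.min_duration = np.asarray(self.min_duration, dtype=float)
        self.mean_duration = np.asarray(self.mean_duration, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (G, G):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.min_duration < 1):
            raise ValueError("min duration must be >= 1 frame")
        if np.any(self.mean_duration < self.min_duration):
            raise ValueError("mean duration must be >= min duration")
        n_steps = max(self.gesture_to_step) + 1
        if len(self.step_to_phase) != n_steps:
            raise ValueError("step_to_phase must cover every step")

    @property
    def n_gestures(self) -> int:
        return len(self.gesture_to_step)

    @property
    def n_steps(self) -> int:
        return max(self.gesture_to_step) + 1

    @property
    def n_phases(self) -> int:
        return max(self.step_to_phase) + 1

    def vocabularies(self) -> dict[str, list[str]]:
        return {
            "phase": [f"P{i}" for i in range(self.n_phases)],
            "step": [f"S{i}" for i in range(self.n_steps)],
            "gesture": [f"G{i}" for i in range(self.n_gestures)],
        }

    def min_path_duration(self) -> float:
        """Shortest total min-duration from any start state to any absorbing
        state (Dijkstra over the transition graph)."""
        G = self.n_gestures
        absorbing = [g for g in range(G) if self.transition[g, g] == 1.0]
        dist = {g: np.inf for g in range(G)}
        heap = []
        for g in range(G):
            if self.initial[g] > 0:
                dist[g] = self.min_duration[g]
                heapq.heappush(heap, (dist[g], g))
        while heap:
            d, g = heapq.heappop(heap)
            if d > dist[g]:
                continue
            for h in range(G):
                if h != g and self.transition[g, h] > 0:
                    nd = d + self.min_duration[h]
                    if nd < dist[h]:
                        dist[h] = nd
                        heapq.heappush(heap, (nd, h))
        if not absorbing:  # cyclic chain: any state can pad out the sequence
            return min(dist.values())
        return min(dist[g] for g in absorbing)


def left_to_right_hierarchy(
    n_phases: int = 2,
    n_steps: int = 3,
    n_gestures: int = 6,
    mean_duration: float = 50.0,
    min_duration: float = 25.0,
    skip_prob: float = 0.0,
) -> WorkflowHierarchy:
    """Strict left-to-right gesture chain with optional single-gesture skips;
    gestures are assigned evenly to steps, steps evenly to phases."""
    gesture_to_step = [min(g * n_steps // n_gestures, n_steps - 1) for g in range(n_gestures)]
    step_to_phase = [min(s * n_phases // n_steps, n_phases - 1) for s in range(n_steps)]
    trans = np.zeros((n_gestures, n_gestures))
    for g in range(n_gestures - 1):
        if skip_prob > 0 and g + 2 <= n_gestures - 1:
            trans[g, g + 1] = 1.0 - skip_prob
            trans[g, g + 2] = skip_prob
        else:
            trans[g, g + 1] = 1.0
    trans[n_gestures - 1, n_gestures - 1] = 1.0  # terminal gesture absorbs
    initial = np.zeros(n_gestures)
    initial[0] = 1.0
    return WorkflowHierarchy(
        gesture_to_step=gesture_to_step,
        step_to_phase=step_to_phase,
        min_duration=np.full(n_gestures, min_duration),
        mean_duration=np.full(n_gestures, mean_duration),
        transition=trans,
        initial=initial,
    )


def sample_workflow(
    hierarchy: WorkflowHierarchy, t_target: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample frame-wise labels of length ``t_target`` at all three levels.

    Gestures follow the semi-Markov chain; the sequence is truncated at
    ``t_target`` (absorbing states extend to fill).  Raises if ``t_target``
    is below the minimum reachable total duration.
    """
    if t_target < hierarchy.min_path_duration():
        raise ValueError(
            f"t_target={t_target} below minimum admissible path duration "
            f"{hierarchy.min_path_duration():.0f}"
        )
    G = hierarchy.n_gestures
    state = int(rng.choice(G, p=hierarchy.initial))
    gestures = np.empty(t_target, dtype=int)
    t = 0
    while t < t_target:
        lam = hierarchy.mean_duration[state] - hierarchy.min_duration[state]
        dur = int(hierarchy.min_duration[state]) + int(rng.poisson(lam))
        end = min(t + dur, t_target)
        gestures[t:end] = state
        t = end
        if t < t_target:
            state = int(rng.choice(G, p=hierarchy.transition[state]))
    g2s = np.asarray(hierarchy.gesture_to_step)
    s2p = np.asarray(hierarchy.step_to_phase)
    steps = g2s[gestures]
    phases = s2p[steps]
    return {"phase": phases, "step": steps, "gesture": gestures}


@dataclass
class EmissionModel:
    """Per-gesture emission parameters for the three streams.

    Kinematics: first-order pull ``k_t = k_{t-1} + rate * (target - k_{t-1})
    + noise``.  Visual: ``prototype + progress * drift + noise`` where
    progress runs 0..1 within each gesture segment.
    """

    kin_targets_left: np.ndarray  # (G, K)
    kin_targets_right: np.ndarray  # (G, K)
    pull_rate: float
    kin_noise: float
    visual_prototypes: np.ndarray  # (G, F)
    visual_drift: np.ndarray  # (G, F)
    visual_noise: float
    render_images: bool = False
    image_size: int = 64

    def __post_init__(self):
        if self.kin_noise < 0 or self.visual_noise < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 < self.pull_rate <= 1:
            raise ValueError("pull rate must be in (0, 1]")
        # gestures must be distinguishable in the JOINT emission space even
        # when the complementarity knob shares prototypes within one modality
        joint = np.concatenate(
            [self.visual_prototypes, self.kin_targets_left, self.kin_targets_right],
            axis=1,
        )
        d = np.linalg.norm(joint[:, None] - joint[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0:
            raise ValueError("two gestures have identical joint emission parameters")


def _segment_progress(labels: np.ndarray) -> np.ndarray:
    """Within-segment progress in (0,1): (i + 0.5)/len for frame i of a run."""
    prog = np.empty(len(labels), dtype=float)
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            n = t - start
            prog[start:t] = (np.arange(n) + 0.5) / n
            start = t
    return prog


def _render_frames(kin_l: np.ndarray, kin_r: np.ndarray, size: int) -> np.ndarray:
    """Render two Gaussian instrument glyphs whose centers follow the first
    two kinematic channels of each arm."""
    yy, xx = np.mgrid[0:size, 0:size]
    frames = np.zeros((len(kin_l), size, size), dtype=np.uint8)

    def center(v):
        return (np.tanh(v) * 0.4 + 0.5) * (size - 1)

    for t in range(len(kin_l)):
        img = np.zeros((size, size))
        for kin, sigma in ((kin_l[t], size / 12), (kin_r[t], size / 16)):
            cx, cy = center(kin[0]), center(kin[1])
            img += np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
        frames[t] = np.clip(img * 255, 0, 255).astype(np.uint8)
    return frames


def emit_observations(
    labels: dict[str, np.ndarray],
    emission: EmissionModel,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (visual, kin_left, kin_right) streams for a label sequence."""
    g = labels["gesture"]
    T = len(g)
    K = emission.kin_targets_left.shape[1]
    kin_l = np.empty((T, K))
    kin_r = np.empty((T, K))
    prev_l = np.zeros(K)
    prev_r = np.zeros(K)
    sd_k = emission.kin_noise * noise_scale
    for t in range(T):
        tgt_l = emission.kin_targets_left[g[t]]
        tgt_r = emission.kin_targets_right[g[t]]
        prev_l = prev_l + emission.pull_rate * (tgt_l - prev_l)
        prev_r = prev_r + emission.pull_rate * (tgt_r - prev_r)
        kin_l[t] = prev_l + rng.normal(0, sd_k, K) if sd_k > 0 else prev_l
        kin_r[t] = prev_r + rng.normal(0, sd_k, K) if sd_k > 0 else prev_r
    prog = _segment_progress(g)
    visual = (
        emission.visual_prototypes[g]
        + prog[:, None] * emission.visual_drift[g]
    )
    sd_v = emission.visual_noise * noise_scale
    if sd_v > 0:
        visual = visual + rng.normal(0, sd_v, visual.shape)
    if emission.render_images:
        visual = _render_frames(kin_l, kin_r, emission.image_size)
    return visual, kin_l, kin_r


def random_emission_model(
    n_gestures: int,
    rng: np.random.Generator,
    kin_dim: int = 8,
    feature_dim: int = 32,
    pull_rate: float = 0.35,
    kin_noise: float = 0.3,
    visual_noise: float = 0.6,
    drift_norm: float = 2.0,
    visual_confusable_pairs: tuple[tuple[int, int], ...] = (),
    kinematic_confusable_pairs: tuple[tuple[int, int], ...] = (),
    render_images: bool = False,
) -> EmissionModel:
    """Draw per-gesture targets and prototypes; optionally make gesture pairs
    indistinguishable in one modality (the complementarity knob)."""
    kin_l = rng.normal(0, 1, (n_gestures, kin_dim))
    kin_r = rng.normal(0, 1, (n_gestures, kin_dim))
    proto = rng.normal(0, 1, (n_gestures, feature_dim))
    drift = rng.normal(0, 1, (n_gestures, feature_dim))
    drift *= drift_norm / np.linalg.norm(drift, axis=1, keepdims=True)
    for a, b in visual_confusable_pairs:
        proto[b] = proto[a]
        drift[b] = drift[a]
    for a, b in kinematic_confusable_pairs:
        kin_l[b] = kin_l[a]
        kin_r[b] = kin_r[a]
    return EmissionModel(
        kin_targets_left=kin_l,
        kin_targets_right=kin_r,
        pull_rate=pull_rate,
        kin_noise=kin_noise,
        visual_prototypes=proto,
        visual_drift=drift,
        visual_noise=visual_noise,
        render_images=render_images,
    )


@dataclass
class BenchmarkConfig:
    """Default desk-scale benchmark: 8 users x 3 trials, 6 gestures in 3
    steps in 2 phases, ~300 frames (10 s at 30 Hz) per demonstration.

    One visually confusable gesture pair and one kinematically confusable
    pair are built in so the modalities carry complementary information.
    """

    n_users: int = 8
    trials_per_user: int = 3
    n_phases: int = 2
    n_steps: int = 3
    n_gestures: int = 6
    fps: float = 30.0
    t_target: int = 300
    mean_duration: float = 50.0
    min_duration: float = 25.0
    skip_prob: float = 0.0
    kin_dim: int = 8
    feature_dim: int = 32
    pull_rate: float = 0.35
    kin_noise: float = 0.3
    visual_noise: float = 0.6
    drift_norm: float = 2.0
    visual_confusable_pairs: tuple = ((4, 5),)
    kinematic_confusable_pairs: tuple = ((2, 3),)
    skill_duration_range: tuple = (0.85, 1.2)
    skill_noise_range: tuple = (0.9, 1.3)
    render_images: bool = False


def make_benchmark(
    config: BenchmarkConfig | None = None,
    seed: int = 0,
    n_demos: int | None = None,
    out_dir=None,
) -> tuple[list[Demonstration], DatasetIndex]:
    """Generate the benchmark: demonstrations + index (optionally on disk).

    Deterministic under a fixed seed.  ``n_demos`` truncates the user x trial
    grid (0 gives an empty index).
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    hierarchy = left_to_right_hierarchy(
        config.n_phases,
        config.n_steps,
        config.n_gestures,
        config.mean_duration,
        config.min_duration,
        config.skip_prob,
    )
    emission = random_emission_model(
        config.n_gestures,
        rng,
        kin_dim=config.kin_dim,
        feature_dim=config.feature_dim,
        pull_rate=config.pull_rate,
        kin_noise=config.kin_noise,
        visual_noise=config.visual_noise,
        drift_norm=config.drift_norm,
        visual_confusable_pairs=config.visual_confusable_pairs,
        kinematic_confusable_pairs=config.kinematic_confusable_pairs,
        render_images=config.render_images,
    )
    demos: list[Demonstration] = []
    records: list[DemoRecord] = []
    total = config.n_users * config.trials_per_user if n_demos is None else n_demos
    count = 0
    for u in range(config.n_users):
        skill_d = rng.uniform(*config.skill_duration_range)
        skill_n = rng.uniform(*config.skill_noise_range)
        for trial in range(config.trials_per_user):
            if count >= total:
                break
            user_id = f"U{u}"
            demo_id = f"U{u}T{trial}"
            t_target = int(round(config.t_target * skill_d))
            scaled = WorkflowHierarchy(
                gesture_to_step=hierarchy.gesture_to_step,
                step_to_phase=hierarchy.step_to_phase,
                min_duration=np.maximum(1, hierarchy.min_duration * skill_d),
                mean_duration=np.maximum(1, hierarchy.mean_duration * skill_d),
                transition=hierarchy.transition,
                initial=hierarchy.initial,
            )
            t_target = max(t_target, int(np.ceil(scaled.min_path_duration())))
            labels = sample_workflow(scaled, t_target, rng)
            visual, kin_l, kin_r = emit_observations(labels, emission, rng, skill_n)
            demos.append(
                Demonstration(
                    demo_id=demo_id,
                    user_id=user_id,
                    trial_id=trial,
                    fps=config.fps,
                    visual=visual,
                    kin_left=kin_l,
                    kin_right=kin_r,
                    labels=labels,
                    visual_mode="images" if config.render_images else "features",
                )
            )
            records.append(DemoRecord(demo_id, user_id, trial))
            count += 1
    index = DatasetIndex(records, hierarchy.vocabularies())
    if out_dir is not None:
        write_dataset(demos, index, out_dir)
    return demos, index
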