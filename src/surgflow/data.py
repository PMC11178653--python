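"""Dataset model and I/O for synchronized surgical demonstrations.

A *demonstration* is one recorded trial: a visual stream (image stack or
precomputed per-frame feature vectors), kinematic streams for the left and
right patient-side manipulators, and frame-wise workflow labels at one or
more granularity levels (phase / step / gesture).  Files follow the JIGSAWS
conventions: whitespace-delimited kinematics with one row per frame, and
transcripts of ``start_frame end_frame label`` lines with inclusive 0-based
frame intervals; frames outside every segment are unlabeled (-1).

Also here: per-channel z-scoring of kinematics fitted on training folds only,
frame-rate decimation, and the two JIGSAWS cross-validation schemes
(leave-one-supertrial-out and leave-one-user-out).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Demonstration",
    "DemoRecord",
    "DatasetIndex",
    "CVSplit",
    "NormalizationStats",
    "read_kinematics",
    "read_transcript",
    "write_transcript",
    "fit_normalization",
    "apply_normalization",
    "resample",
    "make_splits",
    "save_array",
    "load_array",
    "write_dataset",
    "read_dataset",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class Demonstration:
    """One synchronized multimodal recording with per-frame labels.

    ``visual`` is either a (T, F) float feature matrix (``visual_mode ==
    "features"``) or a (T, H, W[, C]) uint8 image stack (``"images"``).
    ``labels`` maps granularity name to an int vector of length T with -1
    marking unlabeled frames.
    """

    demo_id: str
    user_id: str
    trial_id: int
    fps: float
    visual: np.ndarray
    kin_left: np.ndarray
    kin_right: np.ndarray
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    visual_mode: str = "features"

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        T = self.n_frames
        if T < 1:
            raise ValueError("demonstration must have at least one frame")
        for name, arr in (("kin_left", self.kin_left), ("kin_right", self.kin_right)):
            if arr.shape[0] != T:
                raise ValueError(f"{name} length {arr.shape[0]} != visual length {T}")
        for g, lab in self.labels.items():
            if len(lab) != T:
                raise ValueError(f"labels[{g}] length {len(lab)} != {T}")

    @property
    def n_frames(self) -> int:
        return self.visual.shape[0]

    def modality(self, name: str) -> np.ndarray:
        if name == "visual":
            return self.visual
        if name == "kin_left":
            return self.kin_left
        if name == "kin_right":
            return self.kin_right
        raise KeyError(f"unknown modality {name!r}")


@dataclass
class DemoRecord:
    """Lightweight descriptor of a demonstration inside a DatasetIndex."""

    demo_id: str
    user_id: str
    trial_id: int
    paths: dict[str, str] = field(default_factory=dict)


@dataclass
class DatasetIndex:
    """Catalog of demonstrations plus the label vocabularies per granularity."""

    demos: list[DemoRecord]
    granularities: dict[str, list[str]]  # ordered coarse -> fine

    def __post_init__(self):
        ids = [d.demo_id for d in self.demos]
        if len(set(ids)) != len(ids):
            raise ValueError("demo_ids must be unique")

    @property
    def users(self) -> list[str]:
        return sorted({d.user_id for d in self.demos})

    @property
    def trials_per_user(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for d in self.demos:
            out.setdefault(d.user_id, []).append(d.trial_id)
        return {u: sorted(v) for u, v in out.items()}


@dataclass
class CVSplit:
    scheme: str  # LOSO | LOUO | HOLDOUT
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def read_kinematics(path: str | Path, columns: slice | list[int] | None = None) -> np.ndarray:
    """Read a whitespace-delimited kinematics file into a (T, K) matrix.

    ``columns`` selects channels (slice or index list); None keeps all.
    Raises :class:`FormatError` naming the offending line on ragged rows.
    """
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected {width}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
    if not rows:
        raise FormatError(f"{path}: empty kinematics file")
    mat = np.asarray(rows, dtype=float)
    if columns is not None:
        idx = columns if isinstance(columns, slice) else list(columns)
        if not isinstance(idx, slice):
            if max(idx) >= mat.shape[1] or min(idx) < 0:
                raise FormatError(
                    f"{path}: column selection {idx} out of range for width {mat.shape[1]}"
                )
            mat = mat[:, idx]
        else:
            if idx.stop is not None and idx.stop > mat.shape[1]:
                raise FormatError(
                    f"{path}: column slice stop {idx.stop} exceeds width {mat.shape[1]}"
                )
            mat = mat[:, idx]
    return mat


def read_transcript(
    path: str | Path, total_frames: int, vocabulary: list[str]
) -> np.ndarray:
    """Expand a ``start end label`` transcript into a frame-wise label vector.

    Intervals are inclusive on both ends in 0-based frame indices; frames not
    covered by any segment get -1.  Overlapping segments and labels outside
    ``vocabulary`` are errors.
    """
    vocab_idx = {name: i for i, name in enumerate(vocabulary)}
    labels = np.full(total_frames, -1, dtype=int)
    covered = np.zeros(total_frames, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 'start end label'")
            start, end, name = int(parts[0]), int(parts[1]), parts[2]
            if name not in vocab_idx:
                raise FormatError(f"{path}: line {lineno}: unknown label {name!r}")
            if start < 0 or end < start:
                raise FormatError(f"{path}: line {lineno}: bad interval {start}..{end}")
            end_c = min(end, total_frames - 1)
            if start > end_c:
                continue  # segment entirely past the frame range
            if covered[start : end_c + 1].any():
                raise FormatError(f"{path}: line {lineno}: overlapping segment")
            covered[start : end_c + 1] = True
            labels[start : end_c + 1] = vocab_idx[name]
    return labels


def write_transcript(path: str | Path, labels: np.ndarray, vocabulary: list[str]) -> None:
    """Write maximal constant runs of a label vector as transcript lines.

    Unlabeled (-1) runs are omitted, producing gaps on re-read.
    """
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        start = 0
        for t in range(1, len(labels) + 1):
            if t == len(labels) or labels[t] != labels[start]:
                if labels[start] >= 0:
                    fh.write(f"{start} {t - 1} {vocabulary[labels[start]]}\n")
                start = t


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationStats:
    """Per-channel mean/std of each kinematic stream, fitted on training data.

    Channels with zero variance are flagged; they are mean-centered but not
    scaled when applied.
    """

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    constant: dict[str, np.ndarray]  # bool per channel


def fit_normalization(demos: list[Demonstration]) -> NormalizationStats:
    """Pool all frames of the given (training) demos per kinematic channel."""
    if not demos:
        raise ValueError("need at least one training demonstration")
    mean, std, const = {}, {}, {}
    for stream in ("kin_left", "kin_right"):
        pooled = np.concatenate([d.modality(stream) for d in demos], axis=0)
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)  # population std: re-applying gives exactly unit var
        flag = sd == 0
        mean[stream], std[stream], const[stream] = mu, sd, flag
    return NormalizationStats(mean, std, const)


def apply_normalization(demo: Demonstration, stats: NormalizationStats) -> Demonstration:
    """Return a copy of ``demo`` with z-scored kinematics (constant channels
    are only centered)."""
    new = {}
    for stream in ("kin_left", "kin_right"):
        x = demo.modality(stream) - stats.mean[stream]
        sd = np.where(stats.constant[stream], 1.0, stats.std[stream])
        new[stream] = x / sd
    return Demonstration(
        demo_id=demo.demo_id,
        user_id=demo.user_id,
        trial_id=demo.trial_id,
        fps=demo.fps,
        visual=demo.visual,
        kin_left=new["kin_left"],
        kin_right=new["kin_right"],
        labels=demo.labels,
        visual_mode=demo.visual_mode,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample(demo: Demonstration, target_fps: float) -> Demonstration:
    """Decimate all streams (and labels) to ``target_fps`` by striding.

    Only integer decimation is supported (the training rates 3 and 5 FPS are
    integer strides of 30 Hz source data); output frame j maps to source
    frame j * stride.
    """
    ratio = demo.fps / target_fps
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        candidates = [demo.fps / k for k in (1, 2, 3, 5, 6, 10, 15, 30) if demo.fps % k == 0]
        raise ValueError(
            f"cannot decimate {demo.fps} Hz to {target_fps} Hz by an integer stride; "
            f"nearest valid rates: {sorted(set(candidates), reverse=True)}"
        )
    if stride == 1:
        return demo
    sel = slice(None, None, stride)
    return Demonstration(
        demo_id=demo.demo_id,
        user_id=demo.user_id,
        trial_id=demo.trial_id,
        fps=target_fps,
        visual=demo.visual[sel],
        kin_left=demo.kin_left[sel],
        kin_right=demo.kin_right[sel],
        labels={g: lab[sel] for g, lab in demo.labels.items()},
        visual_mode=demo.visual_mode,
    )


# ---------------------------------------------------------------------------
# cross-validation splits
# ---------------------------------------------------------------------------


def make_splits(index: DatasetIndex, scheme: str) -> list[CVSplit]:
    """Generate LOSO or LOUO folds.

    LOUO holds out all trials of one user per fold.  LOSO ("supertrial")
    holds out trial i of every user in fold i, requiring equal trial counts
    across users.
    """
    scheme = scheme.upper()
    all_ids = [d.demo_id for d in index.demos]
    if scheme == "LOUO":
        users = index.users
        if len(users) < 2:
            raise ValueError("LOUO requires at least 2 users")
        splits = []
        for k, user in enumerate(users):
            test = [d.demo_id for d in index.demos if d.user_id == user]
            train = [i for i in all_ids if i not in set(test)]
            splits.append(CVSplit("LOUO", k, train, test))
        return splits
    if scheme == "LOSO":
        tpu = index.trials_per_user
        counts = {len(v) for v in tpu.values()}
        if len(counts) != 1:
            raise ValueError("LOSO requires every user to have the same trial count")
        trial_lists = {u: v for u, v in tpu.items()}
        n_trials = counts.pop()
        splits = []
        for k in range(n_trials):
            test = [
                d.demo_id
                for d in index.demos
                if d.trial_id == trial_lists[d.user_id][k]
            ]
            train = [i for i in all_ids if i not in set(test)]
            splits.append(CVSplit("LOSO", k, train, test))
        return splits
    raise ValueError(f"unknown scheme {scheme!r} (use LOSO or LOUO)")


# ---------------------------------------------------------------------------
# array + dataset persistence
# ---------------------------------------------------------------------------


def save_array(path: str | Path, arr: np.ndarray, meta: dict | None = None) -> None:
    """Save an array as .npy with a JSON sidecar recording fps/demo_id/dims."""
    path = Path(path)
    np.save(path, arr)
    if meta is not None:
        sidecar = path.with_suffix(".json")
        meta = dict(meta, shape=list(arr.shape))
        sidecar.write_text(json.dumps(meta, indent=1))


def load_array(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.load(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def write_dataset(demos: list[Demonstration], index: DatasetIndex, out_dir: str | Path) -> Path:
    """Write demonstrations in the on-disk layout + a YAML manifest.

    Layout: kinematics/<id>_{left,right}.txt, transcripts/<granularity>/<id>.txt,
    visual/<id>.npy (features) and manifest.yaml tying it together.
    """
    out = Path(out_dir)
    (out / "kinematics").mkdir(parents=True, exist_ok=True)
    (out / "visual").mkdir(exist_ok=True)
    for g in index.granularities:
        (out / "transcripts" / g).mkdir(parents=True, exist_ok=True)
    records = []
    for demo in demos:
        kl = out / "kinematics" / f"{demo.demo_id}_left.txt"
        kr = out / "kinematics" / f"{demo.demo_id}_right.txt"
        np.savetxt(kl, demo.kin_left, fmt="%.6f")
        np.savetxt(kr, demo.kin_right, fmt="%.6f")
        vis = out / "visual" / f"{demo.demo_id}.npy"
        save_array(
            vis,
            demo.visual,
            meta={"demo_id": demo.demo_id, "fps": demo.fps, "mode": demo.visual_mode},
        )
        paths = {"kin_left": str(kl), "kin_right": str(kr), "visual": str(vis)}
        for g, lab in demo.labels.items():
            tp = out / "transcripts" / g / f"{demo.demo_id}.txt"
            write_transcript(tp, lab, index.granularities[g])
            paths[f"transcript_{g}"] = str(tp)
        records.append(
            {
                "demo_id": demo.demo_id,
                "user_id": demo.user_id,
                "trial_id": demo.trial_id,
                "fps": demo.fps,
                "n_frames": demo.n_frames,
                "visual_mode": demo.visual_mode,
                "paths": paths,
            }
        )
    manifest = {
        "granularities": {g: list(v) for g, v in index.granularities.items()},
        "demonstrations": records,
    }
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def read_dataset(manifest_path: str | Path) -> tuple[list[Demonstration], DatasetIndex]:
    """Load a dataset written by :func:`write_dataset`."""
    manifest = yaml.safe_load(Path(manifest_path).read_text())
    gran = {g: list(v) for g, v in manifest["granularities"].items()}
    demos, records = [], []
    for rec in manifest["demonstrations"]:
        visual, _ = load_array(rec["paths"]["visual"])
        kin_l = read_kinematics(rec["paths"]["kin_left"])
        kin_r = read_kinematics(rec["paths"]["kin_right"])
        T = rec["n_frames"]
        labels = {}
        for g, vocab in gran.items():
            key = f"transcript_{g}"
            if key in rec["paths"]:
                labels[g] = read_transcript(rec["paths"][key], T, vocab)
        demos.append(
            Demonstration(
                demo_id=rec["demo_id"],
                user_id=rec["user_id"],
                trial_id=rec["trial_id"],
                fps=rec["fps"],
                visual=visual,
                kin_left=kin_l,
                kin_right=kin_r,
                labels=labels,
                visual_mode=rec.get("visual_mode", "features"),
            )
        )
        records.append(
            DemoRecord(rec["demo_id"], rec["user_id"], rec["trial_id"], rec["paths"])
        )
    index = DatasetIndex(records, gran)
    return demos, index
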