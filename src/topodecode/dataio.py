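"""Trial containers, class balancing, and stratified 80/20 splits.

Two container layouts are supported, in either HDF5 (``.h5``/``.hdf5``)
or NumPy ``.npz`` form:

* raw EEG:    ``data`` (n_trials x channels x samples, float32),
              ``labels``, ``subjects``, ``channel_names``, ``rate``
* sequences:  ``frames`` (n_trials x n_frames x H x W x 3, float32),
              ``labels``, ``subjects``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topomap import TopomapSequence, TrialRecording

__all__ = [
    "TrialSet",
    "SplitSpec",
    "DatasetSplit",
    "load_trials",
    "save_trials",
    "balance_classes",
    "make_split",
    "round_half_up",
]

RAW_FIELDS = ("data", "labels", "subjects", "channel_names", "rate")
SEQ_FIELDS = ("frames", "labels", "subjects")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from the floor (0.5 -> up)."""
    f = 10.0 ** decimals
    return float(np.floor(x * f + 0.5) / f)


@dataclass
class TrialSet:
    """An ordered collection of trials (raw or image-sequence) with its classes."""

    trials: list  # TrialRecording or TopomapSequence
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.classes:
            seen: dict[str, None] = {}
            for t in self.trials:
                seen.setdefault(t.label, None)
            self.classes = tuple(seen)
        self.classes = tuple(self.classes)
        for t in self.trials:
            if t.label not in self.classes:
                raise ValueError(f"trial label {t.label!r} not in classes")

    def __len__(self) -> int:
        return len(self.trials)

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def subjects(self) -> list[str]:
        return [t.subject for t in self.trials]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for t in self.trials:
            counts[t.label] += 1
        return counts

    def subset(self, indices) -> "TrialSet":
        return TrialSet([self.trials[i] for i in indices], classes=self.classes)

    def filter_classes(self, classes) -> "TrialSet":
        classes = tuple(classes)
        return TrialSet(
            [t for t in self.trials if t.label in classes], classes=classes
        )

    def split_by_subject(self) -> dict[str, "TrialSet"]:
        groups: dict[str, list] = {}
        for t in self.trials:
            groups.setdefault(t.subject, []).append(t)
        return {s: TrialSet(ts, classes=self.classes) for s, ts in groups.items()}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class DatasetSplit:
    train: TrialSet
    test: TrialSet
    spec: SplitSpec = field(default_factory=SplitSpec)


def _decode(arr) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in np.asarray(arr)]


def _read_container(path: Path) -> dict:
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                out[k] = f[k][()]
        return out
    with np.load(path, allow_pickle=False) as z:
        return {k: z[k] for k in z.files}


def load_trials(path) -> TrialSet:
    """Load a raw-EEG or image-sequence container into a TrialSet.

    Raises ``ValueError`` naming the first missing/invalid field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = _read_container(path)
    kind = RAW_FIELDS if "data" in raw or "frames" not in raw else SEQ_FIELDS
    for name in kind:
        if name not in raw:
            raise ValueError(f"missing field: {name}")
    labels = _decode(raw["labels"])
    subjects = _decode(raw["subjects"])
    trials: list = []
    if kind is RAW_FIELDS:
        data = np.asarray(raw["data"])
        if data.ndim != 3:
            raise ValueError("invalid field: data must be 3-dimensional")
        if not (len(labels) == len(subjects) == data.shape[0]):
            raise ValueError("invalid field: labels/subjects length mismatch")
        channel_names = tuple(_decode(raw["channel_names"]))
        rate = float(np.asarray(raw["rate"]).reshape(()))
        for i in range(data.shape[0]):
            trials.append(
                TrialRecording(
                    data=data[i],
                    rate=rate,
                    label=labels[i],
                    subject=subjects[i],
                    channel_names=channel_names,
                )
            )
    else:
        frames = np.asarray(raw["frames"])
        if frames.ndim != 5:
            raise ValueError("invalid field: frames must be 5-dimensional")
        if not (len(labels) == len(subjects) == frames.shape[0]):
            raise ValueError("invalid field: labels/subjects length mismatch")
        for i in range(frames.shape[0]):
            trials.append(
                TopomapSequence(frames=frames[i], label=labels[i], subject=subjects[i])
            )
    return TrialSet(trials)


def save_trials(path, trial_set: TrialSet) -> None:
    """Write a TrialSet to a container (format chosen by extension)."""
    path = Path(path)
    first = trial_set.trials[0]
    if isinstance(first, TrialRecording):
        payload = {
            "data": np.stack([t.data for t in trial_set.trials]).astype(np.float32),
            "labels": np.asarray(trial_set.labels()),
            "subjects": np.asarray(trial_set.subjects()),
            "channel_names": np.asarray(list(first.channel_names)),
            "rate": np.asarray(first.rate),
        }
    else:
        payload = {
            "frames": np.stack([t.frames for t in trial_set.trials]).astype(np.float32),
            "labels": np.asarray(trial_set.labels()),
            "subjects": np.asarray(trial_set.subjects()),
        }
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for k, v in payload.items():
                if v.dtype.kind in ("U", "S"):
                    f.create_dataset(
                        k, data=np.char.encode(v.astype(str), "utf-8")
                    )
                else:
                    f.create_dataset(k, data=v)
    else:
        np.savez_compressed(path, **payload)


def balance_classes(trial_set: TrialSet, seed: int = 0) -> TrialSet:
    """Downsample each class uniformly at random to the minimum class count."""
    counts = trial_set.class_counts()
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"empty class: {c!r}")
    m = min(counts.values())
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    by_class: dict[str, list[int]] = {c: [] for c in trial_set.classes}
    for i, t in enumerate(trial_set.trials):
        by_class[t.label].append(i)
    for c in trial_set.classes:
        idx = np.asarray(by_class[c])
        chosen = rng.choice(idx, size=m, replace=False)
        keep.extend(chosen.tolist())
    keep.sort()  # preserve original trial order
    return trial_set.subset(keep)


def make_split(trial_set: TrialSet, spec: SplitSpec | None = None) -> DatasetSplit:
    """Seeded stratified partition; per-class train count = round(f * n)."""
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[int]] = {c: [] for c in trial_set.classes}
    for i, t in enumerate(trial_set.trials):
        by_class[t.label].append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        groups = [by_class[c] for c in trial_set.classes]
    else:
        groups = [list(range(len(trial_set)))]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError("each class needs at least 2 trials to split")
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(spec.train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        arr = np.asarray(idx)
        train_idx.extend(arr[perm[:n_train]].tolist())
        test_idx.extend(arr[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return DatasetSplit(
        train=trial_set.subset(train_idx),
        test=trial_set.subset(test_idx),
        spec=spec,
    )
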