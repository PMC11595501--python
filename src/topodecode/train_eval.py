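"""Subject-dependent training/evaluation with accuracy aggregation.

Each subject's trials are balanced, split 80/20 stratified by class,
transformed to scalp-map sequences, and used to train one model per
architecture variant.  Per-subject test accuracies (percent) are
averaged across subjects for the final score; tables print one row per
subject plus an ``Average`` row, values rounded half-up to one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import montage as _montage
from .dataio import (
    DatasetSplit,
    SplitSpec,
    TrialSet,
    balance_classes,
    make_split,
    round_half_up,
)
from .models import ModelGraph, build_model
from .models.graph import Adam
from .topomap import (
    FrameSchedule,
    TopomapSequence,
    quantize_roundtrip,
    trial_to_sequence,
)

__all__ = [
    "TrainConfig",
    "ExperimentTask",
    "EvalResult",
    "TrainingHistory",
    "train",
    "accuracy",
    "average_accuracy",
    "run_experiment",
    "transform_trialset",
    "sequences_to_arrays",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    early_stop_patience: int = 10
    target_loss: float | None = None
    loss: str = "categorical_crossentropy"
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "categorical_crossentropy":
            raise ValueError("only categorical cross-entropy is supported")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.loss)


@dataclass
class EvalResult:
    """Per-subject accuracies (percent) and their cross-subject average."""

    per_subject: dict[str, float]
    n_correct: dict[str, int]
    n_total: dict[str, int]

    @property
    def N(self) -> int:
        return len(self.per_subject)

    @property
    def average(self) -> float:
        return average_accuracy(list(self.per_subject.values()))


def sequences_to_arrays(
    trial_set: TrialSet, classes: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a TrialSet of TopomapSequence into (X, y) arrays."""
    classes = tuple(classes or trial_set.classes)
    x = np.stack([t.frames for t in trial_set.trials]).astype(np.float32)
    y = np.array([classes.index(t.label) for t in trial_set.trials], dtype=np.int64)
    return x, y


def transform_trialset(
    trial_set: TrialSet,
    montage2d=None,
    schedule: FrameSchedule | None = None,
    grid_size: int = 64,
    quantize: bool = True,
) -> TrialSet:
    """Raw trials -> scalp-map sequences (optionally 8-bit quantized).

    Quantization is on by default to mirror on-disk image storage, where
    pixels are bytes rescaled back to [0, 1] by dividing by 255.
    """
    if montage2d is None:
        first = trial_set.trials[0]
        montage2d = _montage.project_to_disk(
            _montage.standard_1020_positions(list(first.channel_names))
        )
    sequences = []
    for t in trial_set.trials:
        seq = trial_to_sequence(t, montage2d, schedule, grid_size=grid_size)
        if quantize:
            seq = quantize_roundtrip(seq)
        sequences.append(seq)
    return TrialSet(sequences, classes=trial_set.classes)


def train(
    model: ModelGraph,
    split: DatasetSplit,
    config: TrainConfig | None = None,
) -> TrainingHistory:
    """Minimize cross-entropy with Adam on the split's training set.

    Early stopping monitors the per-epoch mean training loss (there is
    no validation split) with the configured patience; an optional
    ``target_loss`` stops as soon as the epoch loss falls below it.
    """
    config = config or TrainConfig()
    if len(split.train) == 0:
        raise ValueError("training set is empty")
    x, y = sequences_to_arrays(split.train)
    if x.shape[1:] != model.input_shape:
        raise ValueError(
            f"sequence shape {x.shape[1:]} does not match model input "
            f"{model.input_shape}"
        )
    optimizer = Adam(model, learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    model.reset_dropout_rng(config.seed + 1)
    history = TrainingHistory()
    best = np.inf
    since_best = 0
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        sizes = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            loss = model.loss_and_grads(x[idx], y[idx])
            optimizer.step()
            losses.append(loss)
            sizes.append(len(idx))
        epoch_loss = float(np.average(losses, weights=sizes))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        history.loss.append(epoch_loss)
        if epoch_loss < best - 1e-12:
            best = epoch_loss
            since_best = 0
        else:
            since_best += 1
        if config.target_loss is not None and epoch_loss <= config.target_loss:
            history.stopped_epoch = epoch
            break
        if since_best >= config.early_stop_patience:
            history.stopped_epoch = epoch
            break
    return history


def accuracy(predictions, truth) -> float:
    """Percent of predictions matching the truth labels."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of zero predictions")
    return 100.0 * float((predictions == truth).mean())


def average_accuracy(per_subject) -> float:
    """Arithmetic mean of per-subject accuracies (percent)."""
    per_subject = list(per_subject)
    if not per_subject:
        raise ValueError("need at least one subject accuracy")
    return float(np.mean(per_subject))


@dataclass(frozen=True)
class ExperimentTask:
    """One experiment: which words, which architectures, how to split/train."""

    classes: tuple[str, ...]
    variants: tuple[str, ...] = ("lstm", "stack_lstm", "bilstm")
    schedule: FrameSchedule = field(default_factory=FrameSchedule)
    split: SplitSpec = field(default_factory=SplitSpec)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    grid_size: int = 64
    quantize: bool = True
    model_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "variants", tuple(self.variants))


def run_experiment(
    task: ExperimentTask, data: TrialSet
) -> tuple[dict[str, EvalResult], pd.DataFrame]:
    """Run the subject-dependent protocol over every subject in ``data``.

    Returns per-variant EvalResults and a results table (rows =
    subjects + Average, columns = variants).  Subjects missing one of
    the task's classes are skipped with a warning and excluded from the
    average.
    """
    per_subject_sets = data.filter_classes(task.classes).split_by_subject()
    results: dict[str, EvalResult] = {
        v: EvalResult({}, {}, {}) for v in task.variants
    }
    for subject in sorted(per_subject_sets):
        subject_set = per_subject_sets[subject]
        counts = subject_set.class_counts()
        if any(counts[c] < 2 for c in task.classes):
            logger.warning(
                "skipping subject %s: missing or underpopulated class "
                "(counts %s)", subject, counts,
            )
            continue
        balanced = balance_classes(subject_set, seed=task.split.seed)
        split = make_split(balanced, task.split)
        already_images = isinstance(split.train.trials[0], TopomapSequence)
        if already_images:
            train_seqs, test_seqs = split.train, split.test
        else:
            train_seqs = transform_trialset(
                split.train, schedule=task.schedule,
                grid_size=task.grid_size, quantize=task.quantize,
            )
            test_seqs = transform_trialset(
                split.test, schedule=task.schedule,
                grid_size=task.grid_size, quantize=task.quantize,
            )
        x_test, y_test = sequences_to_arrays(test_seqs, task.classes)
        input_shape = train_seqs.trials[0].frames.shape
        for variant in task.variants:
            model = build_model(
                variant,
                n_classes=len(task.classes),
                input_shape=tuple(input_shape),
                seed=task.model_seed,
            )
            train(
                model,
                DatasetSplit(train=train_seqs, test=test_seqs, spec=split.spec),
                task.train_config,
            )
            pred = model.predict(x_test)
            acc = accuracy(pred, y_test)
            results[variant].per_subject[subject] = acc
            results[variant].n_correct[subject] = int((pred == y_test).sum())
            results[variant].n_total[subject] = int(y_test.size)
            logger.info("subject %s variant %s: %.2f%%", subject, variant, acc)
    table = results_table(results)
    return results, table


def results_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Subjects x variants accuracy table with a final Average row."""
    subjects = sorted({s for r in results.values() for s in r.per_subject})
    rows = {}
    for s in subjects:
        rows[s] = {
            v: round_half_up(r.per_subject[s], 2) if s in r.per_subject else np.nan
            for v, r in results.items()
        }
    rows["Average"] = {
        v: round_half_up(r.average, 1) if r.per_subject else np.nan
        for v, r in results.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "Subject"
    return table
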