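"""Synthetic imagined-speech-like EEG with known class structure.

Each class c is a rank-1 spatiotemporal source: a fixed unit-norm
spatial pattern over channels times a smooth Hann envelope centered at a
class-specific latency, plus white Gaussian noise scaled to a requested
signal-to-noise ratio.  No physiological fidelity is claimed; the point
is a controllable, fully offline stand-in that exercises the whole
pipeline (spatial structure for the scalp maps, temporal structure for
the recurrent head).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import montage
from .dataio import TrialSet
from .topomap import TrialRecording

__all__ = ["SyntheticSpec", "class_pattern", "generate_trials"]

#: maximum |pearson correlation| allowed between class spatial patterns
_MAX_PATTERN_CORR = 0.7

#: peak signal amplitude in microvolts
_AMPLITUDE_UV = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    classes: tuple[str, ...] = ("word_a", "word_b")
    n_trials_per_class: int = 70
    rate: float = 256.0
    duration_s: float = 2.0
    snr: float = 5.0
    seed: int = 0
    subject: str = "S01"
    channel_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(montage.frontal_subset())
    )

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration_s))


def _pattern_sequence(n_classes: int, n_channels: int, seed: int) -> np.ndarray:
    """Draw unit-norm spatial patterns for classes 0..n_classes-1.

    Patterns are drawn sequentially from one seeded stream; a candidate
    is resampled until its correlation with every accepted pattern stays
    below the threshold, so the sequence is deterministic in (seed, index).
    """
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for _ in range(n_classes):
        while True:
            v = rng.standard_normal(n_channels)
            v /= np.linalg.norm(v)
            if n_channels == 1 or all(
                abs(_corr(v, u)) < _MAX_PATTERN_CORR for u in accepted
            ):
                accepted.append(v)
                break
    return np.stack(accepted)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def class_pattern(class_index: int, n_channels: int, seed: int = 0) -> np.ndarray:
    """Deterministic unit-norm spatial weight vector for one class index."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    return _pattern_sequence(class_index + 1, n_channels, seed)[class_index]


def _envelope(class_index: int, n_classes: int, n_samples: int) -> np.ndarray:
    """Hann bump of half the trial, centered at a class-specific latency."""
    width = n_samples // 2
    if n_classes > 1:
        center = (0.3 + 0.4 * class_index / (n_classes - 1)) * n_samples
    else:
        center = 0.5 * n_samples
    t = np.arange(n_samples)
    u = (t - (center - width / 2)) / width
    env = np.where((u >= 0) & (u <= 1), 0.5 - 0.5 * np.cos(2 * math.pi * u), 0.0)
    return env


def generate_trials(spec: SyntheticSpec) -> TrialSet:
    """Generate a balanced, labeled TrialSet per the spec.

    The additive white-noise variance is set from the mean signal power
    so that signal_power / noise_power equals ``spec.snr`` exactly in
    expectation (``snr = inf`` yields noiseless trials).
    """
    rng = np.random.default_rng(spec.seed)
    n_ch = len(spec.channel_names)
    n_s = spec.n_samples
    patterns = _pattern_sequence(len(spec.classes), n_ch, spec.seed)
    trials: list[TrialRecording] = []
    for ci, cls in enumerate(spec.classes):
        env = _envelope(ci, len(spec.classes), n_s)
        signal = _AMPLITUDE_UV * np.outer(patterns[ci], env)  # (ch, samples)
        p_sig = float((signal ** 2).mean())
        sigma = 0.0 if math.isinf(spec.snr) else math.sqrt(p_sig / spec.snr)
        for t in range(spec.n_trials_per_class):
            noise = sigma * rng.standard_normal((n_ch, n_s)) if sigma else 0.0
            trials.append(
                TrialRecording(
                    data=signal + noise,
                    rate=spec.rate,
                    label=cls,
                    subject=spec.subject,
                    channel_names=spec.channel_names,
                )
            )
    return TrialSet(trials, classes=spec.classes)
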