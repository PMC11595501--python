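"""Trial -> sequence of normalized 64x64 RGB scalp-map frames.

A 2 s, 256 Hz trial is cut into 16 windows of 125 ms starting 4 ms after
trial onset.  Per window, the mean voltage of each channel is
interpolated (inverse-distance weighting, exponent 2) onto a raster
spanning the projected head disk and rendered through a fixed
piecewise-linear colormap with a symmetric per-trial color scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage2D

__all__ = [
    "TrialRecording",
    "FrameSchedule",
    "ScalarField",
    "TopomapSequence",
    "extract_frame_values",
    "interpolate_scalp",
    "render_rgb",
    "trial_to_sequence",
    "quantize_roundtrip",
    "save_sequence",
    "load_sequence",
    "export_png",
]


@dataclass
class TrialRecording:
    """One trial: channels x samples voltage matrix plus metadata."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate: float  # Hz
    label: str
    subject: str
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a non-empty channels x samples matrix")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def is_paper_conformant(self) -> bool:
        """True for the reference geometry: 2 s at 256 Hz (512 samples)."""
        return self.rate == 256 and self.n_samples == 512


@dataclass(frozen=True)
class FrameSchedule:
    """Windowing rule: n_frames windows of window_ms starting at offset_ms."""

    window_ms: float = 125.0
    offset_ms: float = 4.0
    n_frames: int = 16

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.offset_ms < 0:
            raise ValueError("offset_ms must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def offset_samples(self, rate: float) -> int:
        return int(round(self.offset_ms * rate / 1000.0))


@dataclass
class ScalarField:
    """Interpolated voltage raster plus head-disk membership mask."""

    grid: np.ndarray  # (gs, gs) float
    mask: np.ndarray  # (gs, gs) bool


@dataclass
class TopomapSequence:
    """n_frames x H x W x 3 image tensor in [0, 1] with trial metadata."""

    frames: np.ndarray
    label: str
    subject: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n_frames, H, W, 3)")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def extract_frame_values(
    trial: TrialRecording, k: int, schedule: FrameSchedule | None = None
) -> np.ndarray:
    """Mean voltage per channel over the k-th schedule window.

    Window ``k`` covers samples ``[offset + k*W, offset + (k+1)*W)`` with
    ``W = round(window_ms * rate / 1000)`` and
    ``offset = round(offset_ms * rate / 1000)``; a window extending past
    the trial end is clipped (it must keep at least one sample).
    """
    schedule = schedule or FrameSchedule()
    if not 0 <= k < schedule.n_frames:
        raise IndexError(f"frame index {k} outside [0, {schedule.n_frames})")
    w = schedule.window_samples(trial.rate)
    start = schedule.offset_samples(trial.rate) + k * w
    stop = min(start + w, trial.n_samples)
    if start >= trial.n_samples:
        raise ValueError(f"frame out of range: window starts at sample {start}")
    return trial.data[:, start:stop].mean(axis=1)


def _grid_coords(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates of the raster spanning [-1, 1]^2.

    ``x`` varies along axis 1 (columns) and ``y``, increasing toward the
    nose, along axis 0 (rows); row 0 is the back of the head.
    """
    c = -1.0 + (2.0 * np.arange(grid_size) + 1.0) / grid_size
    x, y = np.meshgrid(c, c)
    return x, y


def idw_weights(
    montage2d: Montage2D, grid_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the (pixels x electrodes) IDW weight matrix and disk mask.

    The weights depend only on geometry, so one matrix serves every
    frame of every trial on the same montage.  Rows sum to 1; a pixel
    whose center lies within 1e-9 of an electrode gets a one-hot row.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8")
    pos = montage2d.positions2d
    d2 = ((pos[None, :, :] - pos[:, None, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 1e-18:
        raise ValueError("duplicate electrode coordinates in montage")
    x, y = _grid_coords(grid_size)
    mask = x ** 2 + y ** 2 <= 1.0
    pts = np.stack([x[mask], y[mask]], axis=1)  # (m, 2)
    dist2 = ((pts[:, None, :] - pos[None, :, :]) ** 2).sum(-1)  # (m, e)
    exact = dist2 <= 1e-18  # within 1e-9 of an electrode
    with np.errstate(divide="ignore"):
        w = 1.0 / dist2
    hit = exact.any(axis=1)
    w[hit] = exact[hit].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    return w, mask


def interpolate_scalp(
    values: np.ndarray, montage2d: Montage2D, grid_size: int = 64
) -> ScalarField:
    """Inverse-distance-weighted (exponent 2) scalp field on a raster.

    Pixels outside the unit disk are masked and set to 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage2d.labels),):
        raise ValueError(
            f"{values.size} values for {len(montage2d.labels)} electrodes"
        )
    w, mask = idw_weights(montage2d, grid_size)
    grid = np.zeros(mask.shape, dtype=float)
    grid[mask] = w @ values
    return ScalarField(grid=grid, mask=mask)


def render_rgb(field: ScalarField, vmax: float) -> np.ndarray:
    """Map a scalar field to a [0, 1] RGB frame.

    Values are normalized symmetrically about zero,
    ``u = clamp((v + vmax) / (2 vmax), 0, 1)``, then pushed through a
    fixed piecewise-linear blue->red colormap.  Pixels outside the head
    disk are white.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    u = np.clip((field.grid + vmax) / (2.0 * vmax), 0.0, 1.0)
    r = np.clip(1.5 - np.abs(4.0 * u - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * u - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * u - 1.0), 0.0, 1.0)
    rgb = np.stack([r, g, b], axis=-1)
    rgb[~field.mask] = 1.0
    return rgb.astype(np.float32)


def trial_to_sequence(
    trial: TrialRecording,
    montage2d: Montage2D,
    schedule: FrameSchedule | None = None,
    grid_size: int = 64,
) -> TopomapSequence:
    """Full trial -> frame-sequence transform.

    The color scale is symmetric with a per-trial ``vmax`` equal to the
    largest absolute windowed value across all frames, so relative
    amplitude between frames is preserved (an all-zero trial falls back
    to ``vmax = 1``).
    """
    schedule = schedule or FrameSchedule()
    if tuple(trial.channel_names) != tuple(montage2d.labels):
        raise ValueError("trial channel names do not match montage labels")
    values = np.stack(
        [extract_frame_values(trial, k, schedule) for k in range(schedule.n_frames)]
    )  # (n_frames, n_channels)
    vmax = float(np.abs(values).max())
    if vmax == 0.0:
        vmax = 1.0
    w, mask = idw_weights(montage2d, grid_size)
    fields = values @ w.T  # (n_frames, n_masked_pixels)
    frames = np.empty((schedule.n_frames, grid_size, grid_size, 3), dtype=np.float32)
    for k in range(schedule.n_frames):
        grid = np.zeros(mask.shape, dtype=float)
        grid[mask] = fields[k]
        frames[k] = render_rgb(ScalarField(grid=grid, mask=mask), vmax)
    return TopomapSequence(frames=frames, label=trial.label, subject=trial.subject)


def quantize_roundtrip(sequence: TopomapSequence) -> TopomapSequence:
    """Emulate 8-bit image storage: byte = round-half-up(v*255), back via /255."""
    bytes_ = np.floor(sequence.frames * 255.0 + 0.5)
    frames = (bytes_ / 255.0).astype(np.float32)
    return TopomapSequence(frames=frames, label=sequence.label, subject=sequence.subject)


def save_sequence(path, sequence: TopomapSequence) -> None:
    """Write one sequence to a compressed .npz container."""
    np.savez_compressed(
        path,
        frames=sequence.frames.astype(np.float32),
        label=np.asarray(sequence.label),
        subject=np.asarray(sequence.subject),
    )


def load_sequence(path) -> TopomapSequence:
    with np.load(path, allow_pickle=False) as z:
        return TopomapSequence(
            frames=z["frames"],
            label=str(z["label"]),
            subject=str(z["subject"]),
        )


def export_png(sequence: TopomapSequence, out_dir) -> list:
    """Write each frame as an 8-bit RGB PNG (frame_00.png, ...) for inspection."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(sequence.n_frames):
        img = np.floor(sequence.frames[k] * 255.0 + 0.5).astype(np.uint8)
        p = out / f"frame_{k:02d}.png"
        Image.fromarray(img, mode="RGB").save(p)
        paths.append(p)
    return paths
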