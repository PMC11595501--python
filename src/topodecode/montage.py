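"""Standard 10-20/10-10 electrode positions and 2D head projection.

Positions come from an idealized spherical layout shipped with the
package (``data/montage1020.txt``): each electrode is given by its
inclination from the vertex and its azimuth from the nose direction.
The 2D projection used for rasterizing scalp maps is azimuthal
equidistant, with the ear-level circle mapped to the unit circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ElectrodeMontage",
    "Montage2D",
    "standard_1020_positions",
    "project_to_disk",
    "frontal_subset",
]

#: The 15 frontal-lobe channels used for scalp-map generation, in the
#: fixed order every downstream array follows.
FRONTAL_15 = (
    "Fp1", "AF3", "Fp2", "AF4", "AF7", "AF8",
    "F1", "Fz", "F2", "F7", "F5", "F3", "F4", "F6", "F8",
)


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels with unit-sphere 3D positions (head-centered)."""

    labels: tuple[str, ...]
    positions3d: np.ndarray  # (n, 3), unit norm rows

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions3d, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions3d shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every 3D position must have unit norm")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        object.__setattr__(self, "positions3d", pos)


@dataclass(frozen=True)
class Montage2D:
    """Electrode labels with 2D positions inside the closed unit disk."""

    labels: tuple[str, ...]
    positions2d: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions2d, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError(
                f"positions2d shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        r2 = (pos ** 2).sum(axis=1)
        if np.any(r2 > 1.0 + 1e-9):
            raise ValueError("2D positions must lie inside the unit disk")
        object.__setattr__(self, "positions2d", pos)


def _load_table() -> dict[str, tuple[str, float, float]]:
    """Parse the shipped position table, keyed by lower-case label.

    Values are (canonical label, inclination_deg, azimuth_deg).
    """
    table: dict[str, tuple[str, float, float]] = {}
    text = (
        resources.files("topodecode.data")
        .joinpath("montage1020.txt")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, incl, az = line.split()
        table[label.lower()] = (label, float(incl), float(az))
    return table


_TABLE = _load_table()


def _sph_to_cart(incl_deg: float, az_deg: float) -> tuple[float, float, float]:
    incl = math.radians(incl_deg)
    az = math.radians(az_deg)
    x = math.sin(incl) * math.sin(az)
    y = math.sin(incl) * math.cos(az)
    z = math.cos(incl)
    # snap exact zeros so midline/vertex electrodes are bit-clean
    if abs(x) < 1e-15:
        x = 0.0
    if abs(y) < 1e-15:
        y = 0.0
    if abs(z) < 1e-15:
        z = 0.0
    n = math.sqrt(x * x + y * y + z * z)
    return x / n, y / n, z / n


def standard_1020_positions(labels: list[str] | tuple[str, ...]) -> ElectrodeMontage:
    """Look up unit-sphere positions for 10-20/10-10 channel names.

    Matching is case-insensitive; output labels use the canonical
    capitalization of the shipped table and preserve input order.

    Raises
    ------
    KeyError
        If a label is not in the 10-20/10-10 table (the message names
        the offending label).
    """
    canon: list[str] = []
    pos: list[tuple[float, float, float]] = []
    for lab in labels:
        entry = _TABLE.get(str(lab).lower())
        if entry is None:
            raise KeyError(f"unknown 10-20 electrode label: {lab!r}")
        canon.append(entry[0])
        pos.append(_sph_to_cart(entry[1], entry[2]))
    return ElectrodeMontage(tuple(canon), np.array(pos, dtype=float))


def project_to_disk(montage: ElectrodeMontage) -> Montage2D:
    """Azimuthal-equidistant projection of a montage onto the unit disk.

    A point at polar angle ``theta`` from the vertex maps to radius
    ``theta / (pi/2)`` (ear level -> radius 1) at the same azimuth; the
    vertex maps to the origin.
    """
    pos = montage.positions3d
    z = np.clip(pos[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    r = theta / (math.pi / 2.0)
    rho = np.hypot(pos[:, 0], pos[:, 1])  # sin(theta), >= 0
    scale = np.where(rho > 1e-12, r / np.where(rho > 1e-12, rho, 1.0), 0.0)
    xy = pos[:, :2] * scale[:, None]
    return Montage2D(montage.labels, xy)


def frontal_subset() -> list[str]:
    """The fixed, ordered 15-channel frontal subset used for scalp maps."""
    return list(FRONTAL_15)
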