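"""Sensor layout handling for the 128-channel BioSemi montage.

The decoder's spatial input representation, the simulator's source
patterns and the ERP cluster statistics all need 2-D scalp coordinates
for each sensor.  Positions come from the standard ``biosemi128``
montage shipped with MNE and are flattened with an azimuthal-equidistant
projection about the vertex, the conventional projection for EEG
topographic maps: the projected radius of a sensor is proportional to
its angular distance from the vertex, so distances on the scalp are
approximately preserved.

Coordinate convention: ``x`` increases toward the subject's right,
``y`` toward the front of the head (anterior).  Units are radians of
arc from the vertex ("layout units" elsewhere in the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorLayout", "biosemi128_layout"]

#: |x| below which a sensor counts as lying on the front-back midline.
MIDLINE_TOL = 0.05


@dataclass(frozen=True)
class SensorLayout:
    """Named sensors with 2-D scalp-projected positions.

    Attributes
    ----------
    names : tuple of str
        Montage labels (for BioSemi: ``A1``–``D32``).
    positions : ndarray, shape (n, 2)
        Azimuthal-equidistant projected coordinates (x right, y anterior).
    """

    names: tuple[str, ...]
    positions: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("sensor names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 2):
            raise ValueError("positions must have shape (n_sensors, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown sensor {name!r}") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def hemisphere(self, name: str) -> str:
        """``'left'``, ``'right'`` or ``'midline'`` for one sensor."""
        x = self.position(name)[0]
        if abs(x) <= MIDLINE_TOL:
            return "midline"
        return "right" if x > 0 else "left"

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(self.hemisphere(n) for n in self.names)

    @property
    def midline(self) -> np.ndarray:
        """Boolean midline flag per sensor."""
        return np.abs(self.positions[:, 0]) <= MIDLINE_TOL

    def mirror(self, name: str) -> str:
        """Sensor closest to the left-right mirror image of ``name``."""
        x, y = self.position(name)
        d = np.hypot(self.positions[:, 0] + x, self.positions[:, 1] - y)
        return self.names[int(np.argmin(d))]

    def frontal(self, fraction: float = 0.12) -> tuple[str, ...]:
        """The most anterior ``fraction`` of sensors (blink-sensitive set)."""
        k = max(1, int(round(fraction * len(self))))
        order = np.argsort(-self.positions[:, 1])
        return tuple(self.names[i] for i in order[:k])


def _project_azimuthal(points3d: np.ndarray) -> np.ndarray:
    """Project 3-D head-surface points to the plane about the vertex."""
    c = points3d.mean(axis=0)
    c[2] = (points3d[:, 2].min() + points3d[:, 2].max()) / 2.0
    v = points3d - c
    r = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r, -1.0, 1.0))
    rho = np.hypot(v[:, 0], v[:, 1])
    rho[rho == 0] = 1e-12
    return np.column_stack([theta * v[:, 0] / rho, theta * v[:, 1] / rho])


def biosemi128_layout() -> SensorLayout:
    """Standard 128-sensor BioSemi layout projected to 2-D.

    Uses the ``biosemi128`` montage shipped with MNE (labels A1–D32).
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi128")
    ch_pos = montage.get_positions()["ch_pos"]
    names = tuple(ch_pos)
    pts = np.array([ch_pos[n] for n in names])
    return SensorLayout(names=names, positions=_project_azimuthal(pts))
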