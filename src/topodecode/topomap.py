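"""Topography-preserving mapping of 128 sensors onto a 13x9 grid.

A convolutional decoder can only exploit spatial structure if scalp
neighbours are adjacent in its input array.  This module arranges 117
of the 128 BioSemi sensors on a 13 (anterior->posterior) x 9
(left->right) grid: sensors are sorted front-to-back and split into 13
latitude bands, each band is ordered left-to-right, and the laterally
outermost sensors of over-full bands are dropped until every band holds
exactly 9.  Eleven peripheral sensors are removed this way
(128 = 13*9 + 11).  The default assignment is shipped as an editable
CSV asset and re-validated on load; the identity of the dropped set is
approximate (derived from the standard montage geometry, not from a
published table).

Epoched trials rearranged through the mapping become dense
``(13, 9, T)`` arrays (`TopoTensorSet`), the decoder's input space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import SensorLayout, biosemi128_layout

__all__ = [
    "GridMapping",
    "TopoTensorSet",
    "MappingError",
    "default_biosemi128_mapping",
    "derive_grid_mapping",
    "apply_mapping",
    "inverse_mapping",
    "adjacency",
    "grid_adjacency",
]

N_ROWS = 13
N_COLS = 9


class MappingError(ValueError):
    """Raised when a sensor-to-grid assignment violates the grid contract."""


@dataclass(frozen=True)
class GridMapping:
    """Assignment of sensors to cells of a 13x9 spatial grid.

    Attributes
    ----------
    cells : dict
        ``sensor name -> (row, col)`` for the 117 mapped sensors.
    dropped : tuple of str
        The 11 peripheral sensors excluded from the grid.
    """

    cells: dict[str, tuple[int, int]]
    dropped: tuple[str, ...]
    n_rows: int = N_ROWS
    n_cols: int = N_COLS

    def __post_init__(self) -> None:
        validate_mapping(self)

    @property
    def mapped(self) -> tuple[str, ...]:
        """Mapped sensor names in row-major grid order."""
        return tuple(
            sorted(self.cells, key=lambda s: self.cells[s])
        )

    def sensor_at(self, row: int, col: int) -> str:
        for name, (r, c) in self.cells.items():
            if (r, c) == (row, col):
                return name
        raise KeyError(f"no sensor at cell ({row}, {col})")

    def grid_of_names(self) -> np.ndarray:
        out = np.empty((self.n_rows, self.n_cols), dtype=object)
        for name, (r, c) in self.cells.items():
            out[r, c] = name
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sensor": s, "row": r, "col": c, "dropped": 0}
            for s, (r, c) in self.cells.items()
        ]
        rows += [
            {"sensor": s, "row": -1, "col": -1, "dropped": 1}
            for s in self.dropped
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["dropped", "row", "col"])
            .reset_index(drop=True)
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "GridMapping":
        kept = table[table["dropped"] == 0]
        cells = {
            str(r.sensor): (int(r.row), int(r.col))
            for r in kept.itertuples()
        }
        dropped = tuple(str(s) for s in table.loc[table["dropped"] == 1, "sensor"])
        return cls(cells=cells, dropped=dropped)

    @classmethod
    def load(cls, path: str | Path) -> "GridMapping":
        return cls.from_frame(pd.read_csv(path))


def validate_mapping(mapping: GridMapping) -> None:
    """Enforce the structural contract of the 13x9 grid assignment."""
    cells = mapping.cells
    if len(cells) != mapping.n_rows * mapping.n_cols:
        raise MappingError(
            f"expected {mapping.n_rows * mapping.n_cols} mapped sensors, "
            f"got {len(cells)}"
        )
    if len(cells) + len(mapping.dropped) != 128:
        raise MappingError("mapped + dropped sensors must cover all 128")
    if set(cells) & set(mapping.dropped):
        raise MappingError("a sensor cannot be both mapped and dropped")
    seen = set()
    for name, (r, c) in cells.items():
        if not (0 <= r < mapping.n_rows and 0 <= c < mapping.n_cols):
            raise MappingError(f"sensor {name} assigned out-of-grid cell {(r, c)}")
        if (r, c) in seen:
            raise MappingError(f"cell {(r, c)} assigned twice")
        seen.add((r, c))


def derive_grid_mapping(layout: SensorLayout) -> GridMapping:
    """Construct the 13x9 assignment from layout geometry.

    Sensors are sorted anterior->posterior into 13 bands (two size-9
    bands at the frontal and occipital extremes, eleven size-10 bands in
    between); within a band they are ordered left->right, and the
    laterally outermost sensor of each size-10 band is dropped as
    peripheral.  This is the procedure that generated the shipped asset.
    """
    if len(layout) != 128:
        raise MappingError(f"need a 128-sensor layout, got {len(layout)}")
    x, y = layout.positions[:, 0], layout.positions[:, 1]
    order = list(np.argsort(-y))
    sizes = [9] + [10] * 11 + [9]
    cells: dict[str, tuple[int, int]] = {}
    dropped: list[str] = []
    start = 0
    for row, size in enumerate(sizes):
        band = sorted(order[start : start + size], key=lambda i: x[i])
        start += size
        while len(band) > N_COLS:
            if abs(x[band[0]]) >= abs(x[band[-1]]):
                dropped.append(layout.names[band.pop(0)])
            else:
                dropped.append(layout.names[band.pop(-1)])
        for col, i in enumerate(band):
            cells[layout.names[i]] = (row, col)
    return GridMapping(cells=cells, dropped=tuple(dropped))


def default_biosemi128_mapping(layout: SensorLayout | None = None) -> GridMapping:
    """Load (and validate) the shipped BioSemi-128 grid asset."""
    if layout is not None and len(layout) != 128:
        raise MappingError(f"need a 128-sensor layout, got {len(layout)}")
    with resources.files("topodecode").joinpath(
        "data/biosemi128_grid.csv"
    ).open("r") as fh:
        mapping = GridMapping.from_frame(pd.read_csv(fh))
    if layout is not None:
        unknown = (set(mapping.cells) | set(mapping.dropped)) - set(layout.names)
        if unknown:
            raise MappingError(f"asset names absent from layout: {sorted(unknown)}")
    return mapping


# ---------------------------------------------------------------------------
# tensors


@dataclass
class TopoTensorSet:
    """Trials as (n, 13, 9, T) topography-preserving arrays."""

    data: np.ndarray
    labels: np.ndarray
    mapping: GridMapping
    sampling_rate: float
    class_names: tuple[str, ...] = ()
    subject_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 4 or self.data.shape[1:3] != (
            self.mapping.n_rows,
            self.mapping.n_cols,
        ):
            raise ValueError(
                f"data must be (n, {self.mapping.n_rows}, "
                f"{self.mapping.n_cols}, T); got {self.data.shape}"
            )
        if self.data.shape[3] < 1:
            raise ValueError("need at least one time sample")
        if len(self.labels) != len(self.data):
            raise ValueError("labels and trials disagree in length")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_times(self) -> int:
        return self.data.shape[3]

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.labels.max()) + 1


def apply_mapping(epochs, mapping: GridMapping) -> TopoTensorSet:
    """Rearrange a `LabelledEpochSet` into grid tensors.

    Cell ``(r, c)`` of every trial carries the unmodified time series of
    the sensor assigned there; dropped sensors are discarded.
    """
    ch_index = {name: i for i, name in enumerate(epochs.channel_names)}
    missing = [s for s in mapping.cells if s not in ch_index]
    if missing:
        raise MappingError(f"epochs lack mapped sensors: {missing[:5]}")
    n, _, t = epochs.trials.shape
    data = np.empty((n, mapping.n_rows, mapping.n_cols, t), dtype=epochs.trials.dtype)
    for name, (r, c) in mapping.cells.items():
        data[:, r, c, :] = epochs.trials[:, ch_index[name], :]
    return TopoTensorSet(
        data=data,
        labels=np.array(epochs.labels),
        mapping=mapping,
        sampling_rate=epochs.sampling_rate,
        class_names=tuple(epochs.class_names),
        subject_id=epochs.subject_id,
        task=epochs.task,
    )


def inverse_mapping(tensors: TopoTensorSet) -> tuple[np.ndarray, tuple[str, ...]]:
    """Recover the (n, 117, T) channel series and their names."""
    names = tensors.mapping.mapped
    n, _, _, t = tensors.data.shape
    out = np.empty((n, len(names), t), dtype=tensors.data.dtype)
    for i, name in enumerate(names):
        r, c = tensors.mapping.cells[name]
        out[:, i, :] = tensors.data[:, r, c, :]
    return out, names


# ---------------------------------------------------------------------------
# adjacency


def adjacency(layout: SensorLayout, max_dist: float = 0.45) -> np.ndarray:
    """Sensor adjacency from layout distance.

    Two sensors are neighbours when their projected distance is at most
    ``max_dist`` layout units (radians of arc from the vertex; 0.45 is
    roughly 1.5x the typical inter-sensor spacing of the 128-channel
    montage, so every sensor keeps at least one neighbour).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= max_dist
    np.fill_diagonal(adj, False)
    return adj


def grid_adjacency(mapping: GridMapping) -> np.ndarray:
    """8-neighbourhood adjacency between mapped sensors on the grid.

    Rows/columns are ordered as ``mapping.mapped`` (row-major grid order).
    """
    names = mapping.mapped
    rc = np.array([mapping.cells[n] for n in names])
    dr = np.abs(rc[:, None, 0] - rc[None, :, 0])
    dc = np.abs(rc[:, None, 1] - rc[None, :, 1])
    adj = (np.maximum(dr, dc) == 1)
    return adj
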