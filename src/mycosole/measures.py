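"""Virtual-electrode read-outs: potentials, activity, coverage, snapshots.

An electrode at node ``x`` reports the sum of ``u - v`` over the integer
nodes ``y`` with ``|x - y| < 2`` (Euclidean), i.e. the 3x3 Moore
neighbourhood of the centre; only conductive nodes contribute (they are the
only nodes with non-zero fields).  Total activity counts nodes with
``u > 0.1``; coverage counts, per node, the iterations on which ``u``
exceeded that threshold; snapshots binarise the field at ``u > 0.04``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

from .engine import FieldState
from .templates import ConductiveTemplate

__all__ = [
    "ElectrodeLayout",
    "CoverageMap",
    "sample_potential",
    "total_activity",
    "render_snapshot",
    "PotentialRecorder",
    "ActivityRecorder",
    "CoverageRecorder",
    "SnapshotRecorder",
    "ACTIVITY_THRESHOLD",
    "DISPLAY_THRESHOLD",
]

ACTIVITY_THRESHOLD = 0.1
DISPLAY_THRESHOLD = 0.04

# integer offsets with Euclidean distance < 2 from the centre: the 3x3
# Moore neighbourhood (orthogonal distance-2 nodes are excluded by the
# strict inequality)
_NEIGHBOURHOOD = [
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if di * di + dj * dj < 4
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Ordered electrode identifiers and their grid coordinates."""

    names: tuple[str, ...]
    coords: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.coords):
            raise ValueError("one coordinate per electrode required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode identifiers must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def coord(self, name: str) -> tuple[int, int]:
        return self.coords[self.names.index(name)]

    @classmethod
    def default(
        cls, mask: np.ndarray, k: int = 16, snap_to: np.ndarray | None = None
    ) -> "ElectrodeLayout":
        """``k`` electrodes along the medial axis of an insole mask.

        ``E1`` sits in the toe lobe (high ``j``) and ``E2`` in the heel
        lobe (low ``j``), mirroring the two canonical stimulation loci;
        ``E3`` .. ``Ek`` fill the axis from toe to heel.  When ``snap_to``
        (a conductive grid) is given, each electrode is moved to its
        nearest conductive node — electrodes contact the mycelium, not
        bare substrate.
        """
        mask = np.asarray(mask, dtype=bool)
        cols = np.flatnonzero(mask.any(axis=0))
        lo, hi = cols[0], cols[-1]
        span = hi - lo
        # inset the endpoints so electrode neighbourhoods stay inside the lobes
        positions = np.linspace(hi - 0.08 * span, lo + 0.08 * span, k)
        occupied = set(cols.tolist())
        coords = []
        for jp in positions:
            j = int(round(jp))
            # snap to the nearest column that contains mask nodes (relevant
            # when the layout is derived from a sparse network grid)
            j = min(occupied, key=lambda c: abs(c - j))
            rows = np.flatnonzero(mask[:, j])
            coords.append((int(round(rows.mean())), j))
        if snap_to is not None:
            nodes = np.argwhere(np.asarray(snap_to, dtype=bool))
            if len(nodes) == 0:
                raise ValueError("snap_to grid has no conductive nodes")
            snapped = []
            for i, j in coords:
                d2 = (nodes[:, 0] - i) ** 2 + (nodes[:, 1] - j) ** 2
                snapped.append(tuple(int(x) for x in nodes[np.argmin(d2)]))
            coords = snapped
        names = tuple(f"E{i + 1}" for i in range(k))
        # E1 = toe end, E2 = heel end, E3.. fill in between (toe -> heel)
        coords = [coords[0], coords[-1], *coords[1:-1]]
        return cls(names=names, coords=tuple(coords))


def sample_potential(
    state: FieldState,
    template: ConductiveTemplate,
    layout: ElectrodeLayout,
    electrode: str,
    summand: Literal["neighbour", "centre"] = "neighbour",
) -> float:
    """Electrode potential: sum of ``u - v`` over the Moore neighbourhood.

    ``summand="neighbour"`` (default) sums the field at each contributing
    node; ``summand="centre"`` reproduces a literal centre-field reading in
    which every conductive neighbour contributes ``u_x - v_x`` of the
    electrode node itself.
    """
    ci, cj = layout.coord(electrode)
    n_i, n_j = template.shape
    if not (0 <= ci < n_i and 0 <= cj < n_j):
        raise ValueError(f"electrode {electrode} at {(ci, cj)} is off-grid")
    total = 0.0
    centre_val = state.u[ci, cj] - state.v[ci, cj]
    for di, dj in _NEIGHBOURHOOD:
        i, j = ci + di, cj + dj
        if 0 <= i < n_i and 0 <= j < n_j and template.grid[i, j]:
            total += (state.u[i, j] - state.v[i, j]) if summand == "neighbour" else centre_val
    return float(total)


def total_activity(
    state: FieldState, template: ConductiveTemplate, threshold: float = ACTIVITY_THRESHOLD
) -> int:
    """Number of conductive nodes with ``u`` strictly above ``threshold``."""
    return int(np.count_nonzero(state.u[template.grid] > threshold))


def render_snapshot(
    state: FieldState, template: ConductiveTemplate, display_threshold: float = DISPLAY_THRESHOLD
) -> np.ndarray:
    """Binary frame: foreground = conductive nodes with ``u > threshold``."""
    return (state.u > display_threshold) & template.grid


@dataclass
class CoverageMap:
    """Per-node count of iterations on which ``u`` exceeded the threshold."""

    raw: np.ndarray
    threshold: float = ACTIVITY_THRESHOLD

    @classmethod
    def zeros(cls, shape: tuple[int, int], threshold: float = ACTIVITY_THRESHOLD) -> "CoverageMap":
        return cls(np.zeros(shape, dtype=np.int64), threshold)

    def accumulate(self, state: FieldState) -> None:
        if state.u.shape != self.raw.shape:
            raise ValueError("field shape differs from coverage shape")
        self.raw += state.u > self.threshold

    def normalized(self) -> np.ndarray:
        """Raw counts divided by the grid-wide maximum; all-zero stays all-zero."""
        m = self.raw.max()
        if m == 0:
            return np.zeros(self.raw.shape, dtype=float)
        return self.raw / float(m)

    def save_png(self, path) -> None:
        """16-bit greyscale: 0 = never covered, 65535 = maximum coverage."""
        img = (self.normalized() * 65535).astype(np.uint16)
        Image.fromarray(img).save(path)

    def to_text(self) -> str:
        return "\n".join(" ".join(str(int(c)) for c in row) for row in self.raw)


# ---------------------------------------------------------------------------
# recorders pluggable into engine.simulate
# ---------------------------------------------------------------------------


@dataclass
class PotentialRecorder:
    """Per-electrode potential time series at a fixed recording stride."""

    template: ConductiveTemplate
    layout: ElectrodeLayout
    stride: int = 1
    summand: Literal["neighbour", "centre"] = "neighbour"
    times: list = field(default_factory=list)
    values: list = field(default_factory=list)

    def record(self, t: int, state: FieldState) -> None:
        self.times.append(t)
        self.values.append(
            [
                sample_potential(state, self.template, self.layout, name, self.summand)
                for name in self.layout.names
            ]
        )

    def as_frame(self) -> pd.DataFrame:
        """Column 1 = iteration, then one column per electrode."""
        df = pd.DataFrame(self.values, columns=list(self.layout.names))
        df.insert(0, "iteration", self.times)
        return df


@dataclass
class ActivityRecorder:
    """Excited-node counts (``u > threshold``) over time."""

    template: ConductiveTemplate
    threshold: float = ACTIVITY_THRESHOLD
    stride: int = 1
    times: list = field(default_factory=list)
    counts: list = field(default_factory=list)

    def record(self, t: int, state: FieldState) -> None:
        self.times.append(t)
        self.counts.append(total_activity(state, self.template, self.threshold))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": self.times, "active_nodes": self.counts})


@dataclass
class CoverageRecorder:
    """Accumulates a :class:`CoverageMap` at the recording stride."""

    template: ConductiveTemplate
    threshold: float = ACTIVITY_THRESHOLD
    stride: int = 1
    coverage: CoverageMap = None

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = CoverageMap.zeros(self.template.shape, self.threshold)

    def record(self, t: int, state: FieldState) -> None:
        self.coverage.accumulate(state)


@dataclass
class SnapshotRecorder:
    """Binary display frames (``u > 0.04``) every ``stride`` iterations."""

    template: ConductiveTemplate
    display_threshold: float = DISPLAY_THRESHOLD
    stride: int = 100
    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)

    def record(self, t: int, state: FieldState) -> None:
        self.times.append(t)
        self.frames.append(render_snapshot(state, self.template, self.display_threshold))

    def save_frames(self, directory) -> None:
        """Numbered PNGs suitable for external video assembly."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t, frame in zip(self.times, self.frames):
            Image.fromarray((frame * 255).astype(np.uint8)).save(directory / f"frame_{t:07d}.png")
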