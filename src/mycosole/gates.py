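"""Spike detection and Boolean-gate extraction from potential traces.

Spikes are local maxima whose topographic prominence (height above the
higher of the two flanking minima, window-unbounded) clears a threshold.
Gate extraction compares spike trains recorded under the three stimulation
scenarios ``(x, y) in {(0,1), (1,0), (1,1)}`` -- ``x`` true meaning initial
excitation around electrode E1, ``y`` around E2.  Spikes pooled across
scenarios are grouped into events; the presence/absence triple of each
event is the truth table of a Boolean function restricted to the three
tested input pairs, which names the gate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeDetectionParams",
    "SpikeTrain",
    "GateTimingParams",
    "GateCensus",
    "detect_spikes",
    "interspike_intervals",
    "align_events",
    "classify_gate",
    "census_gates",
    "GATE_LOOKUP",
    "SCENARIOS",
]

SCENARIOS = ("01", "10", "11")

#: presence triple (s01, s10, s11) -> gate label.  Each triple is the truth
#: table of a Boolean function of (x, y) restricted to the tested inputs
#: (0,1), (1,0), (1,1); e.g. (0,1,1) matches f(x,y)=x, hence SELECT-x.
GATE_LOOKUP = {
    (0, 0, 0): "CONST-FALSE",
    (0, 0, 1): "AND",
    (0, 1, 0): "x-AND-NOT-y",
    (0, 1, 1): "SELECT-x",
    (1, 0, 0): "NOT-x-AND-y",
    (1, 0, 1): "SELECT-y",
    (1, 1, 0): "XOR",
    (1, 1, 1): "OR",
}


@dataclass(frozen=True)
class SpikeDetectionParams:
    """Prominence threshold (trace units) and optional filters.

    ``prominence`` defaults to 0.03, the detection threshold used for
    millivolt-scale electrode recordings.  ``amplitude_cap`` optionally
    discards spikes whose prominence exceeds a ceiling (e.g. 0.1 mV to
    keep only small spikes); ``min_separation`` enforces a minimum sample
    distance between accepted peaks.
    """

    prominence: float = 0.03
    min_separation: int | None = None
    amplitude_cap: float | None = None

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("prominence threshold must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike apex times with per-spike prominence and amplitude."""

    times: np.ndarray
    prominences: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "prominences", np.asarray(self.prominences, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls) -> "SpikeTrain":
        return cls(np.array([]), np.array([]), np.array([]))


@dataclass(frozen=True)
class GateTimingParams:
    """Timing constants for event grouping (in trace time units).

    Spikes from different scenarios closer than ``simultaneity_window``
    count as one simultaneous response; spikes more than
    ``separation_gap`` apart belong to distinct events.
    """

    simultaneity_window: float = 2e2
    separation_gap: float = 1e3

    def __post_init__(self) -> None:
        if not self.separation_gap > self.simultaneity_window > 0:
            raise ValueError("require separation_gap > simultaneity_window > 0")


def detect_spikes(
    trace: np.ndarray,
    params: SpikeDetectionParams = SpikeDetectionParams(),
    times: np.ndarray | None = None,
) -> SpikeTrain:
    """Find peaks with topographic prominence >= the threshold.

    ``times`` maps sample indices to time stamps (defaults to the indices
    themselves).  Spike times are reported at the maximum sample.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 3:
        raise ValueError("trace must be 1-D with at least 3 samples")
    idx, props = find_peaks(
        trace, prominence=params.prominence, distance=params.min_separation
    )
    prom = props["prominences"]
    if params.amplitude_cap is not None:
        keep = prom <= params.amplitude_cap
        idx, prom = idx[keep], prom[keep]
    t = idx.astype(float) if times is None else np.asarray(times, dtype=float)[idx]
    return SpikeTrain(times=t, prominences=prom, amplitudes=trace[idx])


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """Successive differences of spike times; empty for < 2 spikes."""
    if len(train) < 2:
        return np.array([])
    return np.diff(train.times)


def align_events(
    trains: dict[str, SpikeTrain],
    timing: GateTimingParams = GateTimingParams(),
) -> list[tuple[int, int, int]]:
    """Group pooled spikes into events and return their presence triples.

    Spikes from the three scenario trains are pooled and partitioned by
    single-linkage chaining: a gap larger than ``separation_gap`` starts a
    new event.  Within-event gaps larger than the simultaneity window but
    not large enough to separate events are ambiguous; they are resolved
    into the earlier event and logged.  Every spike lands in exactly one
    event.  Each event's triple ``(s01, s10, s11)`` records which
    scenarios contributed at least one spike.
    """
    unknown = set(trains) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenario labels: {sorted(unknown)}")
    pooled = sorted(
        (t, scen) for scen in SCENARIOS for t in trains.get(scen, SpikeTrain.empty()).times
    )
    patterns: list[tuple[int, int, int]] = []
    current: list[tuple[float, str]] = []

    def flush():
        if current:
            present = {scen for _, scen in current}
            patterns.append(tuple(int(s in present) for s in SCENARIOS))

    prev_t = None
    for t, scen in pooled:
        if prev_t is not None and t - prev_t > timing.separation_gap:
            flush()
            current = []
        elif prev_t is not None and t - prev_t > timing.simultaneity_window:
            logger.info(
                "spike at t=%s is %s after its predecessor: beyond the "
                "simultaneity window but within the separation gap; "
                "assigned to the earlier event",
                t,
                t - prev_t,
            )
        current.append((t, scen))
        prev_t = t
    flush()
    return patterns


def classify_gate(pattern: tuple[int, int, int]) -> str:
    """Name the Boolean gate whose truth table matches a presence triple."""
    key = tuple(int(bool(p)) for p in pattern)
    if len(key) != 3:
        raise ValueError("pattern must be a triple (s01, s10, s11)")
    return GATE_LOOKUP[key]


@dataclass
class GateCensus:
    """Per-electrode gate labels and aggregate counts per gate type."""

    per_electrode: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> Counter:
        c = Counter()
        for labels in self.per_electrode.values():
            c.update(labels)
        return c

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.per_electrode.values())

    def as_frame(self) -> pd.DataFrame:
        """Electrode x gate-type count table."""
        gates = sorted({g for v in self.per_electrode.values() for g in v})
        rows = {
            e: {g: labels.count(g) for g in gates}
            for e, labels in self.per_electrode.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def census_gates(
    traces: dict[str, pd.DataFrame],
    detect: SpikeDetectionParams,
    timing: GateTimingParams = GateTimingParams(),
) -> GateCensus:
    """Classify gates on every electrode from three scenario recordings.

    ``traces`` maps scenario label ("01", "10", "11") to a potentials
    table with an ``iteration`` column and one column per electrode, all
    three recorded with the same stride over the same horizon.
    """
    if set(traces) != set(SCENARIOS):
        raise ValueError(f"need exactly the scenarios {SCENARIOS}")
    iters = [np.asarray(df["iteration"]) for df in traces.values()]
    if not all(len(x) == len(iters[0]) and np.array_equal(x, iters[0]) for x in iters[1:]):
        raise ValueError("scenario recordings differ in stride or horizon")
    electrodes = [c for c in traces["01"].columns if c != "iteration"]
    census = GateCensus()
    for e in electrodes:
        trains = {
            scen: detect_spikes(np.asarray(df[e]), detect, times=np.asarray(df["iteration"]))
            for scen, df in traces.items()
        }
        patterns = align_events(trains, timing)
        census.per_electrode[e] = [classify_gate(p) for p in patterns]
    return census
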