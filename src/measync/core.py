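"""Core domain types for multi-electrode array (MEA) recordings.

A recording is organised as a *well*: a small grid of extracellular
electrodes (by default 4 x 4 at 350 um pitch) that each yield a train of
spike timestamps.  All times are in seconds, all distances in micrometres;
unit conversions happen only at I/O boundaries.

Time windows are half-open ``[t0, t1)`` throughout, so that adjacent
windows never double-count a spike.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElectrodeGeometry",
    "SpikeTrain",
    "Epoch",
    "WellRecording",
    "electrode_distance",
    "enumerate_pairs",
    "slice_window",
]

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Rectangular electrode grid with labelled positions.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the default 4 x 4 gives 16 electrodes per well.
    pitch
        Centre-to-centre electrode spacing in micrometres (default 350).
    electrode_ids
        Ordered unique labels, row-major.  When omitted, labels
        ``E01 .. E16`` (zero-padded) are generated.
    """

    n_rows: int = 4
    n_cols: int = 4
    pitch: float = 350.0
    electrode_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        n = self.n_rows * self.n_cols
        ids = self.electrode_ids
        if not ids:
            width = max(2, len(str(n)))
            ids = tuple(f"E{k + 1:0{width}d}" for k in range(n))
            object.__setattr__(self, "electrode_ids", ids)
        if len(ids) != n:
            raise ValueError(f"expected {n} electrode ids, got {len(ids)}")
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        object.__setattr__(
            self, "_index", {eid: k for k, eid in enumerate(ids)}
        )

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def position(self, electrode_id: str) -> tuple[int, int]:
        """0-based (row, col) grid coordinates of an electrode."""
        try:
            k = self._index[electrode_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown electrode id: {electrode_id!r}") from None
        return divmod(k, self.n_cols)


def electrode_distance(
    id_i: str, id_j: str, geometry: ElectrodeGeometry
) -> float:
    """Euclidean distance between two electrodes in micrometres."""
    ri, ci = geometry.position(id_i)
    rj, cj = geometry.position(id_j)
    return math.hypot(ri - rj, ci - cj) * geometry.pitch


def enumerate_pairs(geometry: ElectrodeGeometry) -> list[tuple[str, str]]:
    """All C(n, 2) unordered electrode pairs, lexicographic by id."""
    return list(itertools.combinations(sorted(geometry.electrode_ids), 2))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps for one electrode over a recording interval."""

    electrode_id: str
    timestamps: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        object.__setattr__(self, "timestamps", ts)
        if not self.t_start <= self.t_stop:
            raise ValueError("t_start must not exceed t_stop")
        if ts.size:
            if not np.all(np.diff(ts) > 0):
                raise ValueError("timestamps must be strictly increasing")
            if ts[0] < self.t_start - _TIME_TOL or ts[-1] > self.t_stop + _TIME_TOL:
                raise ValueError("timestamps outside [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def isis(self) -> np.ndarray:
        """Interspike intervals (length ``n_spikes - 1``)."""
        return np.diff(self.timestamps)

    def rate(self) -> float:
        """Mean firing rate in Hz (0 for a zero-length interval)."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


def slice_window(train: SpikeTrain, t0: float, t1: float) -> SpikeTrain:
    """Restrict a train to the half-open window ``[t0, t1)``.

    The returned train has bounds ``t0, t1``; the input is untouched.
    """
    if not t0 < t1:
        raise ValueError("window requires t0 < t1")
    ts = train.timestamps
    i0 = np.searchsorted(ts, t0, side="left")
    i1 = np.searchsorted(ts, t1, side="left")
    return SpikeTrain(train.electrode_id, ts[i0:i1].copy(), t0, t1)


@dataclass(frozen=True)
class Epoch:
    """A labelled protocol interval (condition) in seconds."""

    label: str
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError("epoch requires t0 < t1")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class WellRecording:
    """One well: a spike train per electrode plus the protocol epochs."""

    geometry: ElectrodeGeometry
    trains: tuple[SpikeTrain, ...]
    epochs: tuple[Epoch, ...] = ()

    def __post_init__(self) -> None:
        self.trains = tuple(self.trains)
        self.epochs = tuple(self.epochs)
        ids = [tr.electrode_id for tr in self.trains]
        if sorted(ids) != sorted(self.geometry.electrode_ids):
            raise ValueError("trains must match geometry electrodes exactly")
        bounds = {(tr.t_start, tr.t_stop) for tr in self.trains}
        if len(bounds) > 1:
            raise ValueError("all trains must share identical bounds")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.t0 < a.t1 - _TIME_TOL:
                raise ValueError("epochs must be ordered and non-overlapping")
        self._by_id = {tr.electrode_id: tr for tr in self.trains}

    @property
    def t_start(self) -> float:
        return self.trains[0].t_start

    @property
    def t_stop(self) -> float:
        return self.trains[0].t_stop

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def train(self, electrode_id: str) -> SpikeTrain:
        try:
            return self._by_id[electrode_id]
        except KeyError:
            raise KeyError(f"unknown electrode id: {electrode_id!r}") from None

    def total_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)

    def slice(self, t0: float, t1: float) -> "WellRecording":
        """Restrict every train to ``[t0, t1)``; epochs are clipped."""
        trains = tuple(slice_window(tr, t0, t1) for tr in self.trains)
        epochs = tuple(
            Epoch(ep.label, max(ep.t0, t0), min(ep.t1, t1))
            for ep in self.epochs
            if ep.t1 > t0 and ep.t0 < t1
        )
        return WellRecording(self.geometry, trains, epochs)
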