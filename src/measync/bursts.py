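"""Synchronized-burst-firing (SBF) detection and firing-rate summaries.

An SBF is an array-wide event in which many electrodes fire densely within
a short interval.  Detection follows a four-step procedure on the
array-wide spike histogram:

1. bin all spikes across electrodes (100 ms bins by default);
2. mark candidate bins whose total count and number of active electrodes
   both exceed thresholds;
3. merge candidate runs separated by less than a maximum gap;
4. discard merged events that are too short or too sparse.

All thresholds are exposed in :class:`SBFParams`.  Spikes are then
classified as *burst* (inside a closed event interval) or *sporadic*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain, WellRecording, slice_window

__all__ = [
    "RateHistogram",
    "SBFEvent",
    "SBFParams",
    "SpikeClassification",
    "RateSummary",
    "array_spike_histogram",
    "detect_sbf",
    "classify_spikes",
    "count_sbf",
    "active_channels",
    "rate_summary",
]


@dataclass(frozen=True)
class RateHistogram:
    """Array-wide spike histogram with per-bin active-electrode counts."""

    bin_edges: np.ndarray
    counts: np.ndarray  # total spikes per bin, summed over electrodes
    active_counts: np.ndarray  # electrodes with >= 1 spike per bin

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class SBFEvent:
    """A detected synchronized burst firing."""

    t_start: float
    t_end: float
    n_spikes: int
    participating_electrodes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("event requires t_start < t_end")
        if self.n_spikes < 1:
            raise ValueError("event must contain at least one spike")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SBFParams:
    """Thresholds of the four-step SBF detector.

    ``min_total_count_per_bin=None`` selects an adaptive default of four
    times the *median* per-bin count (floored at 10 spikes/bin): the median
    tracks the sporadic background and, unlike the mean, is not inflated by
    the bursts themselves or by epoch-varying burst intensity.
    ``edge_pad`` widens each detected event at both ends to absorb the
    sub-threshold flanks of a burst (stragglers there would otherwise
    contaminate the sporadic class); it is clamped below half the merge
    gap so padded events can never overlap.
    """

    bin_width: float = 0.1
    min_total_count_per_bin: float | None = None
    min_electrodes_per_bin: int = 4
    max_merge_gap: float = 0.3
    min_duration: float = 0.2
    min_event_spikes: int = 40
    edge_pad: float = 0.1

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if self.min_total_count_per_bin is not None and not self.min_total_count_per_bin > 0:
            raise ValueError("min_total_count_per_bin must be positive")
        if self.min_electrodes_per_bin < 1:
            raise ValueError("min_electrodes_per_bin must be >= 1")
        for name in ("max_merge_gap", "min_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.min_event_spikes < 1:
            raise ValueError("min_event_spikes must be >= 1")
        if self.edge_pad < 0:
            raise ValueError("edge_pad must be non-negative")


def _bin_index(ts: np.ndarray, t0: float, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor((ts - t0) / bin_width).astype(np.int64)
    # a spike exactly at t_stop belongs to the last bin so counts conserve
    return np.clip(idx, 0, n_bins - 1)


def array_spike_histogram(well: WellRecording, bin_width: float = 0.1) -> RateHistogram:
    """Total spike count per half-open bin, summed over all electrodes."""
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil((well.duration - 1e-12) / bin_width))) if well.duration > 0 else 1
    edges = well.t_start + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    active = np.zeros(n_bins, dtype=np.int64)
    for tr in well.trains:
        if not tr.n_spikes:
            continue
        c = np.bincount(
            _bin_index(tr.timestamps, well.t_start, bin_width, n_bins),
            minlength=n_bins,
        )
        counts += c
        active += c > 0
    return RateHistogram(edges, counts, active)


def detect_sbf(well: WellRecording, params: SBFParams = SBFParams()) -> list[SBFEvent]:
    """Detect SBFs with the four-step histogram method (see module docs)."""
    hist = array_spike_histogram(well, params.bin_width)
    threshold = params.min_total_count_per_bin
    if threshold is None:
        threshold = max(4.0 * float(np.median(hist.counts)), 10.0)
    candidate = (hist.counts >= threshold) & (
        hist.active_counts >= params.min_electrodes_per_bin
    )
    idx = np.flatnonzero(candidate)
    if not idx.size:
        return []
    # runs of consecutive candidate bins
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_start = idx[np.concatenate(([0], breaks + 1))]
    run_stop = idx[np.concatenate((breaks, [idx.size - 1]))] + 1  # exclusive
    # merge runs separated by a silent gap shorter than max_merge_gap
    merged: list[list[int]] = [[int(run_start[0]), int(run_stop[0])]]
    for s, e in zip(run_start[1:], run_stop[1:]):
        gap = (s - merged[-1][1]) * params.bin_width
        if gap < params.max_merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    pad = min(params.edge_pad, 0.499 * params.max_merge_gap)
    events = []
    for s, e in merged:
        core_start = float(hist.bin_edges[s])
        core_end = float(hist.bin_edges[e])
        n_spikes = int(hist.counts[s:e].sum())
        if core_end - core_start < params.min_duration or n_spikes < params.min_event_spikes:
            continue
        t_start = max(core_start - pad, well.t_start)
        t_end = min(core_end + pad, float(hist.bin_edges[-1]))
        participants = frozenset(
            tr.electrode_id
            for tr in well.trains
            if slice_window(tr, t_start, min(t_end, well.t_stop) + 1e-12).n_spikes
        )
        events.append(SBFEvent(t_start, t_end, n_spikes, participants))
    return events


@dataclass
class SpikeClassification:
    """Per-spike burst/sporadic partition for a well.

    ``burst_masks`` maps electrode id to a boolean array aligned with the
    train's timestamps (True = inside an SBF, closed interval).
    """

    events: tuple[SBFEvent, ...]
    burst_masks: dict[str, np.ndarray]

    def subtrain(self, train: SpikeTrain, spike_class: str) -> SpikeTrain:
        """The burst-only or sporadic-only restriction of a train."""
        mask = self.burst_masks[train.electrode_id]
        if mask.size != train.n_spikes:
            raise ValueError("classification does not match this train")
        if spike_class == "burst":
            keep = mask
        elif spike_class == "sporadic":
            keep = ~mask
        else:
            raise ValueError(f"unknown spike class: {spike_class!r}")
        return SpikeTrain(
            train.electrode_id, train.timestamps[keep], train.t_start, train.t_stop
        )

    def n_burst(self, electrode_id: str) -> int:
        return int(self.burst_masks[electrode_id].sum())

    def n_sporadic(self, electrode_id: str) -> int:
        m = self.burst_masks[electrode_id]
        return int((~m).sum())


def classify_spikes(
    well: WellRecording, events: list[SBFEvent]
) -> SpikeClassification:
    """Label each spike *burst* iff it lies inside a closed event interval."""
    ev = sorted(events, key=lambda e: e.t_start)
    for a, b in zip(ev, ev[1:]):
        if b.t_start < a.t_end:
            raise ValueError("events must be non-overlapping")
    starts = np.array([e.t_start for e in ev])
    ends = np.array([e.t_end for e in ev])
    masks = {}
    for tr in well.trains:
        ts = tr.timestamps
        if not ev:
            masks[tr.electrode_id] = np.zeros(ts.size, dtype=bool)
            continue
        k = np.searchsorted(starts, ts, side="right") - 1
        inside = (k >= 0) & (ts <= ends[np.clip(k, 0, len(ev) - 1)])
        masks[tr.electrode_id] = inside
    return SpikeClassification(tuple(ev), masks)


def count_sbf(events: list[SBFEvent], t0: float, t1: float) -> int:
    """Number of events starting in the half-open window ``[t0, t1)``."""
    if not t0 < t1:
        raise ValueError("window requires t0 < t1")
    return sum(1 for e in events if t0 <= e.t_start < t1)


def active_channels(
    well: WellRecording,
    classification: SpikeClassification,
    min_rate: float = 1.0,
    window: tuple[float, float] | None = None,
) -> set[str]:
    """Electrodes whose sporadic-spike rate is at least ``min_rate`` Hz."""
    t0, t1 = window if window is not None else (well.t_start, well.t_stop)
    if not t1 > t0:
        raise ValueError("analysis window must have positive length")
    out = set()
    for tr in well.trains:
        sub = slice_window(classification.subtrain(tr, "sporadic"), t0, t1)
        if sub.n_spikes / (t1 - t0) >= min_rate:
            out.add(tr.electrode_id)
    return out


@dataclass(frozen=True)
class RateSummary:
    """Per-electrode firing rates and their across-electrode summary."""

    per_electrode: pd.DataFrame  # columns: sporadic_rate, total_rate, active
    sporadic_mean: float  # mean over active channels
    sporadic_sem: float
    total_mean: float  # mean over all electrodes
    total_sem: float


def rate_summary(
    well: WellRecording,
    classification: SpikeClassification,
    min_rate: float = 1.0,
    window: tuple[float, float] | None = None,
) -> RateSummary:
    """Sporadic and total firing rates, mean +/- SE across electrodes.

    The sporadic mean is taken over *active channels* (sporadic rate of at
    least ``min_rate`` Hz); the total mean over all electrodes.
    """
    t0, t1 = window if window is not None else (well.t_start, well.t_stop)
    if not t1 - t0 >= 1.0:
        raise ValueError("analysis window must be at least 1 s")
    rows = []
    for tr in well.trains:
        total = slice_window(tr, t0, t1).n_spikes / (t1 - t0)
        spor = (
            slice_window(classification.subtrain(tr, "sporadic"), t0, t1).n_spikes
            / (t1 - t0)
        )
        rows.append((tr.electrode_id, spor, total, spor >= min_rate))
    df = pd.DataFrame(
        rows, columns=["electrode_id", "sporadic_rate", "total_rate", "active"]
    ).set_index("electrode_id")

    def _mean_sem(x: np.ndarray) -> tuple[float, float]:
        if x.size == 0:
            return 0.0, 0.0
        sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return float(x.mean()), sem

    spor_mean, spor_sem = _mean_sem(
        df.loc[df["active"], "sporadic_rate"].to_numpy()
    )
    tot_mean, tot_sem = _mean_sem(df["total_rate"].to_numpy())
    return RateSummary(df, spor_mean, spor_sem, tot_mean, tot_sem)
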