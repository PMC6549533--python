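"""Pairwise connection strength via surrogate-normalized synchrony Z-scores.

Two spikes on different electrodes are *synchronized* when they fall within
a coincidence window of each other (100 ms by default).  The raw count
N_real depends on firing rates, so it is standardized against a null in
which each electrode's interspike intervals (ISIs) are randomly permuted:
100 surrogate train pairs are drawn, the count recomputed for each, and

    Z = (N_real - Ave_surrogate) / SD_surrogate .

ISI shuffling preserves each train's spike count, first and last spike
time and ISI multiset while destroying cross-electrode timing, so Z
measures synchrony beyond what the firing statistics alone produce.
A pair whose surrogate counts have zero spread (e.g. single-spike trains)
has no defined Z and is flagged and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .core import (
    ElectrodeGeometry,
    SpikeTrain,
    WellRecording,
    electrode_distance,
    enumerate_pairs,
    slice_window,
)
from .bursts import SpikeClassification

__all__ = [
    "SurrogateParams",
    "SynchronyStat",
    "PairChange",
    "ReductionRate",
    "Z_CRIT_P01",
    "count_synchronized_spikes",
    "shuffle_isi_surrogate",
    "z_score_pair",
    "well_synchrony",
    "stats_frame",
    "z_by_distance",
    "pair_changes",
    "reduction_rate",
    "significant_pairs",
]

#: Two-sided standard-normal critical value at alpha = 0.01, to the printed
#: precision used when calling a pair's connection significant.
Z_CRIT_P01 = 2.58


@dataclass(frozen=True)
class SurrogateParams:
    """Surrogate-null settings: window (s), number of surrogates, seed."""

    n_surrogates: int = 100
    window: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 2:
            raise ValueError("need at least 2 surrogates")
        if not self.window > 0:
            raise ValueError("window must be positive")


@dataclass(frozen=True)
class SynchronyStat:
    """One pair's synchronized-spike count and surrogate-null Z-score."""

    pair: tuple[str, str]
    n_real: int
    ave_surrogate: float
    sd_surrogate: float
    z: float  # nan when not defined
    defined: bool


@dataclass(frozen=True)
class PairChange:
    """Z-score of one pair before and after an intervention."""

    pair: tuple[str, str]
    z_before: float
    z_after: float

    @property
    def delta(self) -> float:
        return self.z_after - self.z_before


class ReductionRate(NamedTuple):
    """Share of band pairs whose Z decreased, as a percentage."""

    pct: float
    n_decreased: int
    n_band: int


def _count_within(a: np.ndarray, b: np.ndarray, window: float) -> int:
    """Unordered cross pairs with |t_a - t_b| strictly below ``window``."""
    if not a.size or not b.size:
        return 0
    hi = np.searchsorted(b, a + window, side="left")
    lo = np.searchsorted(b, a - window, side="right")
    return int((hi - lo).sum())


def count_synchronized_spikes(
    train_i: SpikeTrain, train_j: SpikeTrain, window: float = 0.1
) -> int:
    """Number of synchronized spike pairs between two electrodes.

    Counts unordered pairs (one spike from each train) whose times differ
    by strictly less than ``window`` seconds; symmetric in its arguments.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    if (train_i.t_start, train_i.t_stop) != (train_j.t_start, train_j.t_stop):
        raise ValueError("trains must share identical bounds")
    return _count_within(train_i.timestamps, train_j.timestamps, window)


def _batch_surrogates(ts: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` ISI-shuffled copies of a sorted timestamp vector, as rows."""
    if ts.size < 3:  # 0, 1 or 2 spikes: permutation is the identity
        return np.tile(ts, (n, 1))
    isi = np.diff(ts)
    mat = np.tile(isi, (n, 1))
    rng.permuted(mat, axis=1, out=mat)
    out = np.empty((n, ts.size))
    out[:, 0] = ts[0]
    np.cumsum(mat, axis=1, out=mat)
    out[:, 1:] = ts[0] + mat
    return out


def shuffle_isi_surrogate(
    train: SpikeTrain, rng: np.random.Generator
) -> SpikeTrain:
    """One ISI-shuffled surrogate of a train.

    The first spike time is kept and the remaining times are rebuilt from
    a uniformly random permutation of the original ISI sequence, so the
    spike count, the ISI multiset and the first and last spike times are
    all preserved.  Trains with fewer than two ISIs are returned unchanged.
    """
    ts = _batch_surrogates(train.timestamps, 1, rng)[0]
    return SpikeTrain(train.electrode_id, ts, train.t_start, train.t_stop)


def z_score_pair(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    params: SurrogateParams = SurrogateParams(),
    rng: np.random.Generator | None = None,
) -> SynchronyStat:
    """Surrogate-null Z-score of one electrode pair.

    Both trains are independently ISI-shuffled in every surrogate draw,
    keeping the null exchangeable between the two electrodes.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_real = count_synchronized_spikes(train_i, train_j, params.window)
    si = _batch_surrogates(train_i.timestamps, params.n_surrogates, rng)
    sj = _batch_surrogates(train_j.timestamps, params.n_surrogates, rng)
    counts = np.array(
        [
            _count_within(si[s], sj[s], params.window)
            for s in range(params.n_surrogates)
        ],
        dtype=float,
    )
    ave = float(counts.mean())
    sd = float(counts.std(ddof=1))
    defined = sd > 0
    z = (n_real - ave) / sd if defined else float("nan")
    return SynchronyStat(
        (train_i.electrode_id, train_j.electrode_id), n_real, ave, sd, z, defined
    )


def well_synchrony(
    well: WellRecording,
    params: SurrogateParams = SurrogateParams(),
    spike_class: str = "all",
    window_t: tuple[float, float] | None = None,
    classification: SpikeClassification | None = None,
    rng: np.random.Generator | None = None,
) -> list[SynchronyStat]:
    """Z-score every electrode pair of a well (120 stats for 16 electrodes).

    ``spike_class`` restricts the analysis to ``"sporadic"`` or ``"burst"``
    spikes (a classification is then required) and ``window_t`` to a
    half-open analysis window, e.g. the 15 min before stimulation.
    """
    if spike_class not in ("all", "sporadic", "burst"):
        raise ValueError(f"unknown spike class: {spike_class!r}")
    if spike_class != "all" and classification is None:
        raise ValueError("a SpikeClassification is required for class filtering")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    trains = {}
    for tr in well.trains:
        if spike_class != "all":
            tr = classification.subtrain(tr, spike_class)  # type: ignore[union-attr]
        if window_t is not None:
            tr = slice_window(tr, *window_t)
        trains[tr.electrode_id] = tr
    return [
        z_score_pair(trains[a], trains[b], params, rng)
        for a, b in enumerate_pairs(well.geometry)
    ]


def stats_frame(
    stats: Iterable[SynchronyStat], geometry: ElectrodeGeometry | None = None
) -> pd.DataFrame:
    """Tidy per-pair table of synchrony stats (with distances if given)."""
    rows = []
    for s in stats:
        row = {
            "electrode_i": s.pair[0],
            "electrode_j": s.pair[1],
            "n_real": s.n_real,
            "ave_surrogate": s.ave_surrogate,
            "sd_surrogate": s.sd_surrogate,
            "z": s.z,
            "defined": s.defined,
        }
        if geometry is not None:
            row["distance_um"] = electrode_distance(*s.pair, geometry)
        rows.append(row)
    return pd.DataFrame(rows)


def z_by_distance(
    stats: Iterable[SynchronyStat], geometry: ElectrodeGeometry
) -> pd.DataFrame:
    """Mean Z per exact electrode distance (undefined pairs excluded).

    The grid lattice yields discrete distances (350, 350*sqrt(2), 700, ...
    um for the default geometry), so pairs are grouped by exact distance
    rather than binned.
    """
    df = stats_frame(stats, geometry)
    df = df[df["defined"]]
    df["distance_um"] = df["distance_um"].round(6)
    out = (
        df.groupby("distance_um")["z"]
        .agg(mean_z="mean", n_pairs="size")
        .reset_index()
        .sort_values("distance_um", ignore_index=True)
    )
    return out


def pair_changes(
    before: list[SynchronyStat], after: list[SynchronyStat]
) -> list[PairChange]:
    """Match before/after stats positionally into PairChange records."""
    if len(before) != len(after):
        raise ValueError("before/after stats must have equal length")
    out = []
    for b, a in zip(before, after):
        if b.pair != a.pair:
            raise ValueError(f"pair mismatch: {b.pair} vs {a.pair}")
        out.append(PairChange(b.pair, b.z, a.z))
    return out


def reduction_rate(
    before: list[SynchronyStat],
    after: list[SynchronyStat],
    z_band: str = "above",
    z_crit: float = Z_CRIT_P01,
) -> ReductionRate:
    """Percentage of band pairs whose Z decreased after an intervention.

    The band holds pairs with defined Z_before strictly above (``"above"``)
    or below (``"below"``) ``z_crit``; pairs with undefined Z on either
    side are excluded.  Returns ``100 * n_decreased / n_band``.
    """
    if z_band not in ("above", "below"):
        raise ValueError(f"unknown z_band: {z_band!r}")
    changes = pair_changes(before, after)
    defined = [
        c
        for c, b, a in zip(changes, before, after)
        if b.defined and a.defined
    ]
    if z_band == "above":
        band = [c for c in defined if c.z_before > z_crit]
    else:
        band = [c for c in defined if c.z_before < z_crit]
    if not band:
        raise ValueError("no pairs in the requested Z band")
    n_dec = sum(1 for c in band if c.z_after < c.z_before)
    return ReductionRate(100.0 * n_dec / len(band), n_dec, len(band))


def significant_pairs(
    stats: Iterable[SynchronyStat], z_crit: float = Z_CRIT_P01
) -> list[SynchronyStat]:
    """Pairs with defined Z strictly above the critical value."""
    if not z_crit > 0:
        raise ValueError("z_crit must be positive")
    return [s for s in stats if s.defined and s.z > z_crit]
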