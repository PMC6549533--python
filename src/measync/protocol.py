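"""Dose-response and time-course statistics for well-level protocols.

Metrics (spike counts, SBF counts) are binned over time, normalized to a
reference window set to 100%, and compared across conditions with the
tests used throughout this literature: one-way ANOVA with many-to-one
Dunnett post hoc comparisons, step-down Holm adjustment, and the paired
two-tailed t-test.  Wells are the experimental unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .bursts import SBFEvent, array_spike_histogram, count_sbf
from .core import WellRecording

__all__ = [
    "TimeBinnedMetric",
    "AnovaDunnettResult",
    "PairedTResult",
    "percent_of_reference",
    "bin_timecourse",
    "anova_dunnett",
    "holm_adjust",
    "paired_t",
    "dose_response_table",
]

_ALIGN_TOL = 1e-6


def percent_of_reference(x: float, ref: float) -> float:
    """``100 * x / ref``; the reference must be positive."""
    if not ref > 0:
        raise ValueError("reference value must be positive")
    return 100.0 * x / ref


@dataclass(frozen=True)
class TimeBinnedMetric:
    """A binned, reference-normalized time course of one metric.

    ``masked`` flags bins excluded from analysis (e.g. the 15 min during
    electrical stimulation); their normalized values are NaN but the bins
    are kept so indices stay aligned with wall-clock time.
    """

    metric: str
    bin_edges: np.ndarray
    values: np.ndarray
    masked: np.ndarray
    reference_window: tuple[float, float]
    reference_value: float
    normalized: np.ndarray  # percent of reference, NaN where masked

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    def bin_starting_at(self, t: float) -> int:
        """Index of the bin whose left edge is ``t`` (within tolerance)."""
        k = int(np.argmin(np.abs(self.bin_edges[:-1] - t)))
        if abs(self.bin_edges[k] - t) > _ALIGN_TOL:
            raise ValueError(f"no bin starts at t = {t}")
        return k


def bin_timecourse(
    well: WellRecording,
    events: Sequence[SBFEvent] | None,
    metric: str,
    bin_width: float,
    reference_window: tuple[float, float],
    mask_windows: Sequence[tuple[float, float]] = (),
) -> TimeBinnedMetric:
    """Bin a metric over time and normalize it to a reference window.

    ``metric`` is ``"spikes"`` (total spikes per bin across electrodes) or
    ``"sbf"`` (SBF count per bin; ``events`` required).  The reference
    window must align with bin edges; the reference value is the mean
    per-bin metric over its bins and must be positive.
    """
    if metric not in ("spikes", "sbf"):
        raise ValueError(f"unknown metric: {metric!r}")
    if metric == "sbf" and events is None:
        raise ValueError("SBF events are required for the sbf metric")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(well.duration / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    edges = well.t_start + np.arange(n_bins + 1) * bin_width

    if metric == "spikes":
        hist = array_spike_histogram(well.slice(well.t_start, float(edges[-1])), bin_width)
        values = hist.counts[:n_bins].astype(float)
    else:
        values = np.array(
            [count_sbf(list(events), edges[k], edges[k + 1]) for k in range(n_bins)],
            dtype=float,
        )

    r0, r1 = reference_window
    offs0 = (r0 - well.t_start) / bin_width
    offs1 = (r1 - well.t_start) / bin_width
    if abs(offs0 - round(offs0)) > _ALIGN_TOL or abs(offs1 - round(offs1)) > _ALIGN_TOL:
        raise ValueError("reference window must align with bin edges")
    k0, k1 = int(round(offs0)), int(round(offs1))
    if not 0 <= k0 < k1 <= n_bins:
        raise ValueError("reference window outside the binned range")
    ref = float(values[k0:k1].mean())
    if not ref > 0:
        raise ValueError("reference metric is zero; cannot normalize")

    masked = np.zeros(n_bins, dtype=bool)
    for m0, m1 in mask_windows:
        overlap = (edges[:-1] < m1 - _ALIGN_TOL) & (edges[1:] > m0 + _ALIGN_TOL)
        masked |= overlap
    normalized = 100.0 * values / ref
    normalized[masked] = np.nan
    return TimeBinnedMetric(
        metric, edges, values, masked, (r0, r1), ref, normalized
    )


@dataclass(frozen=True)
class AnovaDunnettResult:
    """One-way ANOVA F/p plus Dunnett-adjusted p per treatment group."""

    f_stat: float
    p_anova: float
    pvalues: "pd.Series"  # indexed by treatment label
    method: str


def anova_dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    method: str = "dunnett",
    n_resamples: int = 10000,
    seed: int | None = None,
) -> AnovaDunnettResult:
    """One-way ANOVA with many-to-one comparisons against a control.

    ``method="dunnett"`` uses the multivariate-t Dunnett procedure;
    ``method="permutation"`` uses a max-|t| permutation null (pooled-SD
    t statistics, labels permuted jointly), which drops the equal-variance
    multivariate-t machinery for very small samples.
    """
    if control_label not in groups:
        raise KeyError(f"control group {control_label!r} not in groups")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    control = arrays[control_label]
    labels = [k for k in arrays if k != control_label]
    treatments = [arrays[k] for k in labels]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant reference groups are legal here
        f_stat, p_anova = sps.f_oneway(control, *treatments)
        if method == "dunnett":
            res = sps.dunnett(*treatments, control=control)
            pvals = np.asarray(res.pvalue, dtype=float)
        elif method == "permutation":
            pvals = _max_t_permutation(
                control, treatments, n_resamples, np.random.default_rng(seed)
            )
        else:
            raise ValueError(f"unknown method: {method!r}")
    return AnovaDunnettResult(
        float(f_stat), float(p_anova), pd.Series(pvals, index=labels), method
    )


def _pooled_t(control: np.ndarray, treatments: list[np.ndarray]) -> np.ndarray:
    all_groups = [control] + treatments
    n_tot = sum(g.size for g in all_groups)
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    df = n_tot - len(all_groups)
    s2 = ss / df if df > 0 else 0.0
    if s2 <= 0:
        return np.full(len(treatments), np.inf)
    return np.array(
        [
            (t.mean() - control.mean()) / np.sqrt(s2 * (1 / t.size + 1 / control.size))
            for t in treatments
        ]
    )


def _max_t_permutation(
    control: np.ndarray,
    treatments: list[np.ndarray],
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    t_obs = np.abs(_pooled_t(control, treatments))
    pooled = np.concatenate([control] + treatments)
    sizes = [control.size] + [t.size for t in treatments]
    cuts = np.cumsum(sizes)[:-1]
    exceed = np.zeros_like(t_obs)
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        parts = np.split(perm, cuts)
        t_null = np.abs(_pooled_t(parts[0], parts[1:])).max()
        exceed += t_null >= t_obs
    return (1.0 + exceed) / (n_resamples + 1.0)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm familywise adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class PairedTResult:
    """Two-tailed paired t-test summary."""

    mean_difference: float
    t_stat: float
    p_value: float
    n: int


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-tailed paired t-test on matched samples (``y - x``)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    if xa.size < 2:
        raise ValueError("need at least two pairs")
    d = ya - xa
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(ya, xa)
    return PairedTResult(float(d.mean()), float(t), float(p), int(xa.size))


def dose_response_table(
    pct_by_condition: Mapping[str, Sequence[float]],
    vehicle_label: str = "vehicle",
) -> pd.DataFrame:
    """Summarize per-well percent-of-vehicle values across doses.

    Returns mean, SE and Holm-adjusted two-sample t-test p-values of each
    dose against vehicle (the vehicle row normalizes to 100% and carries
    no p-value).
    """
    if vehicle_label not in pct_by_condition:
        raise KeyError(f"vehicle group {vehicle_label!r} missing")
    veh = np.asarray(pct_by_condition[vehicle_label], dtype=float)
    rows, raw_p, labels = [], [], []
    for label, vals in pct_by_condition.items():
        v = np.asarray(vals, dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append({"condition": label, "mean_pct": float(v.mean()), "sem_pct": sem})
        if label != vehicle_label:
            labels.append(label)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # vehicle column is constant 100
                raw_p.append(float(sps.ttest_ind(v, veh).pvalue))
    adj = dict(zip(labels, holm_adjust(raw_p))) if labels else {}
    df = pd.DataFrame(rows).set_index("condition")
    df["p_holm"] = pd.Series(adj)
    return df
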