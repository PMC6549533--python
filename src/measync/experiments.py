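"""End-to-end experiment pipelines on simulated wells.

Each function builds a protocol, simulates a set of wells (wells are the
experimental unit), runs the full analysis chain — SBF detection, spike
classification, binning/normalization, synchrony Z-scores — and returns
tidy tables ready for the statistical comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bursts import SBFParams, classify_spikes, count_sbf, detect_sbf
from .core import ElectrodeGeometry
from .protocol import TimeBinnedMetric, anova_dunnett, bin_timecourse
from .simulate import (
    EpochSpec,
    SimParams,
    dose_response_protocol,
    lfs_protocol,
    neuromodulator_cycle_protocol,
    simulate_well,
)
from .synchrony import SurrogateParams, SynchronyStat, well_synchrony

__all__ = [
    "LFSResult",
    "run_lfs_experiment",
    "run_dose_response",
    "run_cycle_experiment",
    "run_lfs_synchrony",
]

_MAX_SEED = 2**31 - 1


def _well_seeds(seed: int, n_wells: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, n_wells)


@dataclass
class LFSResult:
    """Normalized 15-min time courses of an LFS experiment.

    ``spikes_pct`` and ``sbf_pct`` are (wells x bins) DataFrames in percent
    of the reference bin; stimulation bins are NaN.  ``post_stim_bins``
    indexes the bin immediately after each stimulation set.
    """

    spikes_pct: pd.DataFrame
    sbf_pct: pd.DataFrame
    bin_edges: np.ndarray
    reference_bin: int
    post_stim_bins: list[int]
    stim_windows: list[tuple[float, float]]

    def dunnett(self, metric: str = "spikes", bins: list[int] | None = None):
        """Dunnett comparison of selected bins against the reference bin."""
        df = self.spikes_pct if metric == "spikes" else self.sbf_pct
        bins = bins if bins is not None else self.post_stim_bins
        groups = {"before": df.iloc[:, self.reference_bin].to_numpy()}
        for b in bins:
            groups[f"bin{b}"] = df.iloc[:, b].to_numpy()
        return anova_dunnett(groups, "before")


def run_lfs_experiment(
    params: SimParams = SimParams(),
    n_wells: int = 8,
    seed: int = 0,
    baseline_s: float = 3 * 3600.0,
    n_sets: int = 4,
    stim_s: float = 900.0,
    set_period_s: float = 5400.0,
    post_s: float = 3 * 3600.0,
    bin_width: float = 900.0,
    sbf_params: SBFParams = SBFParams(),
) -> LFSResult:
    """Simulate and analyse a low-frequency-stimulation experiment.

    Every well runs the same LFS protocol; spike and SBF counts are binned
    at 15 min, the stimulation bins are masked, and each well is
    normalized to its final pre-stimulation bin (100%).
    """
    protocol = lfs_protocol(
        params, baseline_s, n_sets, stim_s, set_period_s, post_s
    )
    stim_windows = [
        (ep.t0, ep.t1) for ep in protocol if ep.label.startswith("stim")
    ]
    ref_window = (baseline_s - bin_width, baseline_s)
    spikes_rows, sbf_rows = [], []
    edges = None
    for ws in _well_seeds(seed, n_wells):
        well, _ = simulate_well(protocol, params, seed=int(ws))
        events = detect_sbf(well, sbf_params)
        tb_sp = bin_timecourse(well, None, "spikes", bin_width, ref_window, stim_windows)
        tb_sb = bin_timecourse(well, events, "sbf", bin_width, ref_window, stim_windows)
        spikes_rows.append(tb_sp.normalized)
        sbf_rows.append(tb_sb.normalized)
        edges = tb_sp.bin_edges
    spikes_pct = pd.DataFrame(spikes_rows)
    sbf_pct = pd.DataFrame(sbf_rows)
    ref_bin = int(round((baseline_s - bin_width) / bin_width))
    post_bins = [int(round(t1 / bin_width)) for _, t1 in stim_windows]
    return LFSResult(
        spikes_pct, sbf_pct, edges, ref_bin, post_bins, stim_windows
    )


def run_dose_response(
    concentrations,
    params: SimParams = SimParams(),
    n_wells: int = 4,
    epoch_s: float = 600.0,
    seed: int = 0,
    sbf_params: SBFParams = SBFParams(),
    unit: str = "nM",
) -> pd.DataFrame:
    """Cumulative dosing: per-well SBF counts as percent of vehicle.

    Returns a (wells x conditions) DataFrame of SBF counts normalized to
    each well's vehicle epoch.
    """
    protocol = dose_response_protocol(concentrations, epoch_s, params, unit=unit)
    rows = []
    for ws in _well_seeds(seed, n_wells):
        well, _ = simulate_well(protocol, params, seed=int(ws))
        events = detect_sbf(well, sbf_params)
        counts = {
            ep.label: count_sbf(events, ep.t0, ep.t1) for ep in protocol
        }
        veh = counts["vehicle"]
        if veh == 0:
            raise ValueError("no vehicle SBFs detected; cannot normalize")
        rows.append({k: 100.0 * v / veh for k, v in counts.items()})
    return pd.DataFrame(rows)


def run_cycle_experiment(
    params: SimParams = SimParams(),
    n_wells: int = 3,
    seed: int = 0,
    concentration: float = 100.0,
    cycle_s: float = 12 * 3600.0,
    n_cycles: int = 2,
    bin_width: float = 3600.0,
    sbf_params: SBFParams = SBFParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alternating medium/neuromodulator cycles analysed hourly.

    Returns (spikes_pct, sbf_pct) DataFrames of hourly counts in percent
    of the hour immediately before the first dose.
    """
    protocol = neuromodulator_cycle_protocol(
        params, concentration, cycle_s, n_cycles
    )
    ref_window = (cycle_s - bin_width, cycle_s)
    spikes_rows, sbf_rows = [], []
    for ws in _well_seeds(seed, n_wells):
        well, _ = simulate_well(protocol, params, seed=int(ws))
        events = detect_sbf(well, sbf_params)
        spikes_rows.append(
            bin_timecourse(well, None, "spikes", bin_width, ref_window).normalized
        )
        sbf_rows.append(
            bin_timecourse(well, events, "sbf", bin_width, ref_window).normalized
        )
    return pd.DataFrame(spikes_rows), pd.DataFrame(sbf_rows)


def run_lfs_synchrony(
    params: SimParams,
    n_wells: int = 8,
    seed: int = 0,
    window_s: float = 900.0,
    surrogate: SurrogateParams = SurrogateParams(),
    spike_class: str = "sporadic",
    sbf_params: SBFParams = SBFParams(),
) -> tuple[list[SynchronyStat], list[SynchronyStat]]:
    """Pairwise Z-scores before vs immediately after one LFS set.

    Simulates, per well, a 15-min pre-stimulation window, the stimulation
    window, and the 15 min immediately after (with coupling and rates
    depressed per the generator parameters), then Z-scores every pair on
    the requested spike class in both analysis windows.  Stats are
    concatenated across wells in matched order.
    """
    protocol = [
        EpochSpec("before", 0.0, window_s),
        EpochSpec(
            "stim",
            window_s,
            2 * window_s,
            sporadic_mult=1 - params.lfs_depth_spike,
            sbf_mult=1 - params.lfs_depth_sbf,
            coupling_mult=1 - params.lfs_depth_coupling,
        ),
        EpochSpec(
            "after",
            2 * window_s,
            3 * window_s,
            sporadic_mult=1 - params.lfs_depth_spike,
            sbf_mult=1 - params.lfs_depth_sbf,
            coupling_mult=1 - params.lfs_depth_coupling,
        ),
    ]
    before_all: list[SynchronyStat] = []
    after_all: list[SynchronyStat] = []
    rng = np.random.default_rng(seed)
    for ws in _well_seeds(seed + 1, n_wells):
        well, _ = simulate_well(protocol, params, seed=int(ws))
        classification = None
        if spike_class != "all":
            classification = classify_spikes(well, detect_sbf(well, sbf_params))
        before_all.extend(
            well_synchrony(
                well, surrogate, spike_class, (0.0, window_s), classification, rng
            )
        )
        after_all.extend(
            well_synchrony(
                well,
                surrogate,
                spike_class,
                (2 * window_s, 3 * window_s),
                classification,
                rng,
            )
        )
    return before_all, after_all
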