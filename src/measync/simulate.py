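"""Generative model of MEA well recordings with known ground truth.

The generator reproduces the statistical structure the analysis assumes:

* sporadic firing as independent Poisson processes per electrode
  (~5 Hz by default, within the 1-10 Hz range typical of mature cultures);
* array-wide synchronized burst firings (SBFs) as a master Poisson process
  (default 0.06 Hz) in which each electrode participates with high
  probability, firing densely for about a second with a small onset jitter;
* tunable pairwise coupling as a common-parent process that injects
  near-coincident spikes into both electrodes of a pair;
* dose-dependent modulation of the SBF rate through a Hill (Emax) curve;
* stimulation-induced depression of firing with exponential recovery,
  with separate depths and recovery constants for sporadic spikes, SBFs
  and pair coupling.

Rate modulation is expressed as piecewise-constant per-epoch multipliers,
so every draw is an ordinary (conditionally homogeneous) Poisson count and
the expected numbers are available in closed form for tests.  Ground truth
(master burst intervals, per-spike labels, the coupling matrix actually
used) is returned alongside the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ElectrodeGeometry, Epoch, SpikeTrain, WellRecording
from .detect import RawTrace

__all__ = [
    "SimParams",
    "EpochSpec",
    "GroundTruth",
    "hill_multiplier",
    "depression_factor",
    "simulate_well",
    "render_raw_trace",
    "distance_coupling_matrix",
    "constant_protocol",
    "dose_response_protocol",
    "lfs_protocol",
    "neuromodulator_cycle_protocol",
]

#: SD of the per-electrode jitter applied to injected coincident spikes (s).
_COINCIDENT_JITTER = 0.005


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Rates are in Hz, durations and time constants in seconds, amplitudes
    in uV (``spike_amplitude`` is the negative-going peak).  ``coupling``
    is an optional symmetric zero-diagonal matrix in [0, 1) giving, for
    each electrode pair, the rate of injected coincident spikes as a
    fraction of the sporadic rate.
    """

    sporadic_rate: float = 5.0
    sbf_rate: float = 0.06
    sbf_duration: float = 1.0
    intra_burst_rate: float = 50.0
    participation_p: float = 0.9
    burst_latency_jitter: float = 0.02
    coupling: np.ndarray | None = None
    dose_Emax: float = 1.5
    dose_EC50: float = 30.0
    lfs_depth_spike: float = 0.2
    lfs_depth_sbf: float = 0.2
    lfs_depth_coupling: float = 0.4
    lfs_tau_spike: float = 4800.0
    lfs_tau_sbf: float = 600.0
    noise_sigma: float = 2.0
    spike_amplitude: float = -16.0
    sampling_rate: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sporadic_rate", "sbf_rate", "intra_burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.participation_p <= 1:
            raise ValueError("participation_p must be in [0, 1]")
        if not self.sbf_duration > 0:
            raise ValueError("sbf_duration must be positive")
        if self.burst_latency_jitter < 0:
            raise ValueError("burst_latency_jitter must be non-negative")
        for name in ("lfs_depth_spike", "lfs_depth_sbf", "lfs_depth_coupling"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("lfs_tau_spike", "lfs_tau_sbf"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError("coupling must be a square matrix")
            if not np.allclose(c, c.T):
                raise ValueError("coupling must be symmetric")
            if np.any(np.diag(c) != 0):
                raise ValueError("coupling diagonal must be zero")
            if np.any(c < 0) or np.any(c >= 1):
                raise ValueError("coupling entries must be in [0, 1)")
            object.__setattr__(self, "coupling", c)


@dataclass(frozen=True)
class EpochSpec(Epoch):
    """Protocol epoch with per-epoch rate multipliers.

    ``sporadic_mult`` scales the sporadic rate, ``sbf_mult`` the SBF rate,
    ``intra_burst_mult`` the within-burst firing rate and ``coupling_mult``
    the coincident-injection rate (connection strength) during the epoch.
    Dose protocols set ``intra_burst_mult = 1 / sbf_mult`` so that bursts
    become more frequent but not denser overall, reproducing the observed
    dissociation between SBF counts and total spike rates.
    """

    sporadic_mult: float = 1.0
    sbf_mult: float = 1.0
    intra_burst_mult: float = 1.0
    coupling_mult: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("sporadic_mult", "sbf_mult", "intra_burst_mult", "coupling_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_epoch(self) -> Epoch:
        return Epoch(self.label, self.t0, self.t1)


@dataclass
class GroundTruth:
    """Hidden truth emitted with a simulated well.

    ``spike_labels`` holds, per electrode, an array aligned with the
    emitted train's timestamps with values ``burst``, ``sporadic`` or
    ``coincident``; together they partition the emitted spikes.
    """

    sbf_times: np.ndarray  # (n_events, 2) scripted [start, end]
    spike_labels: dict[str, np.ndarray]
    coupling: np.ndarray
    protocol: tuple[EpochSpec, ...]


def hill_multiplier(C: float, Emax: float, EC50: float) -> float:
    """Hill (Emax) rate multiplier ``1 + Emax * C / (EC50 + C)``.

    Monotone non-decreasing in the concentration ``C``; equals 1 at
    ``C = 0`` and approaches ``1 + Emax`` at saturating dose.
    """
    if not EC50 > 0:
        raise ValueError("EC50 must be positive")
    if C < 0:
        raise ValueError("concentration must be non-negative")
    if Emax < 0:
        raise ValueError("Emax must be non-negative")
    return 1.0 + Emax * C / (EC50 + C)


def depression_factor(dt: float, depth: float, tau: float) -> float:
    """Post-stimulation rate multiplier ``1 - depth * exp(-dt / tau)``.

    ``dt`` is the time since the end of stimulation; the factor recovers
    exponentially from ``1 - depth`` towards 1.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not 0 <= depth < 1:
        raise ValueError("depth must be in [0, 1)")
    if not tau > 0:
        raise ValueError("tau must be positive")
    return 1.0 - depth * math.exp(-dt / tau)


def distance_coupling_matrix(
    geometry: ElectrodeGeometry, c0: float = 0.3, length_scale: float = 350.0
) -> np.ndarray:
    """Coupling matrix decaying exponentially with electrode distance.

    Nearest neighbours get ``c0 * exp(-1)`` at the default length scale of
    one pitch, emulating the distance profile of functional connectivity
    in cultured networks.
    """
    from .core import electrode_distance

    ids = geometry.electrode_ids
    n = len(ids)
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = electrode_distance(ids[i], ids[j], geometry)
            c[i, j] = c[j, i] = c0 * math.exp(-d / length_scale)
    return c


def _validate_protocol(protocol: tuple[EpochSpec, ...]) -> None:
    if not protocol:
        raise ValueError("protocol must contain at least one epoch")
    for a, b in zip(protocol, protocol[1:]):
        if abs(b.t0 - a.t1) > 1e-9:
            raise ValueError(
                "protocol epochs must be contiguous and ordered "
                f"(gap/overlap between {a.label!r} and {b.label!r})"
            )


def simulate_well(
    protocol,
    params: SimParams = SimParams(),
    seed: int | None = None,
    geometry: ElectrodeGeometry | None = None,
) -> tuple[WellRecording, GroundTruth]:
    """Simulate one well under a protocol of contiguous epochs.

    Identical ``(protocol, params, seed)`` yields identical output.
    Returns the recording and the ground truth used to generate it.
    """
    protocol = tuple(protocol)
    _validate_protocol(protocol)
    geometry = geometry or ElectrodeGeometry()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ids = geometry.electrode_ids
    n_el = len(ids)
    t0g, t1g = protocol[0].t0, protocol[-1].t1

    times = {eid: [] for eid in ids}
    labels = {eid: [] for eid in ids}

    # --- master SBF events -------------------------------------------------
    starts = []
    for ep in protocol:
        lam = params.sbf_rate * ep.sbf_mult * ep.duration
        k = rng.poisson(lam)
        starts.append(np.sort(rng.uniform(ep.t0, ep.t1, k)))
    sbf_starts = np.concatenate(starts) if starts else np.empty(0)
    sbf_starts.sort()
    epoch_t0 = np.array([ep.t0 for ep in protocol])
    burst_mults = np.array([ep.intra_burst_mult for ep in protocol])
    for s in sbf_starts:
        ep_idx = int(np.searchsorted(epoch_t0, s, side="right") - 1)
        joins = rng.random(n_el) < params.participation_p
        offsets = rng.normal(0.0, params.burst_latency_jitter, n_el)
        counts = rng.poisson(
            params.intra_burst_rate * burst_mults[ep_idx] * params.sbf_duration, n_el
        )
        counts[~joins] = 0
        total = int(counts.sum())
        u = rng.uniform(0.0, params.sbf_duration, total)
        onset = np.repeat(s + offsets, counts)
        tt = onset + u
        owner = np.repeat(np.arange(n_el), counts)
        ok = (tt >= t0g) & (tt < t1g)
        for e in np.unique(owner[ok]):
            sel = ok & (owner == e)
            times[ids[e]].append(tt[sel])
            labels[ids[e]].append(np.full(int(sel.sum()), "burst"))

    # --- sporadic spikes ---------------------------------------------------
    for e, eid in enumerate(ids):
        chunks = []
        for ep in protocol:
            lam = params.sporadic_rate * ep.sporadic_mult * ep.duration
            k = rng.poisson(lam)
            chunks.append(rng.uniform(ep.t0, ep.t1, k))
        tt = np.concatenate(chunks) if chunks else np.empty(0)
        times[eid].append(tt)
        labels[eid].append(np.full(tt.size, "sporadic"))

    # --- pairwise coincident injection -------------------------------------
    coupling = (
        params.coupling
        if params.coupling is not None
        else np.zeros((n_el, n_el))
    )
    if coupling.shape != (n_el, n_el):
        raise ValueError("coupling matrix shape must match the geometry")
    for i in range(n_el):
        for j in range(i + 1, n_el):
            c = coupling[i, j]
            if c <= 0:
                continue
            parents = []
            for ep in protocol:
                lam = (
                    c
                    * ep.coupling_mult
                    * params.sporadic_rate
                    * ep.sporadic_mult
                    * ep.duration
                )
                k = rng.poisson(lam)
                parents.append(rng.uniform(ep.t0, ep.t1, k))
            par = np.concatenate(parents) if parents else np.empty(0)
            if not par.size:
                continue
            for e in (i, j):
                tt = par + rng.normal(0.0, _COINCIDENT_JITTER, par.size)
                ok = (tt >= t0g) & (tt < t1g)
                times[ids[e]].append(tt[ok])
                labels[ids[e]].append(np.full(int(ok.sum()), "coincident"))

    # --- assemble trains ----------------------------------------------------
    trains = []
    out_labels: dict[str, np.ndarray] = {}
    for eid in ids:
        tt = np.concatenate(times[eid]) if times[eid] else np.empty(0)
        ll = (
            np.concatenate(labels[eid])
            if labels[eid]
            else np.empty(0, dtype="<U10")
        )
        order = np.argsort(tt, kind="stable")
        tt, ll = tt[order], ll[order]
        if tt.size:
            keep = np.concatenate(([True], np.diff(tt) > 0))  # drop exact ties
            tt, ll = tt[keep], ll[keep]
        trains.append(SpikeTrain(eid, tt, t0g, t1g))
        out_labels[eid] = ll

    well = WellRecording(
        geometry, tuple(trains), tuple(ep.to_epoch() for ep in protocol)
    )
    truth = GroundTruth(
        sbf_times=np.column_stack(
            (sbf_starts, np.minimum(sbf_starts + params.sbf_duration, t1g))
        )
        if sbf_starts.size
        else np.empty((0, 2)),
        spike_labels=out_labels,
        coupling=coupling,
        protocol=protocol,
    )
    return well, truth


def _spike_template(sampling_rate: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic ~1 ms waveform with dominant negative phase.

    Returns the template and the index of its (negative) peak.
    """
    n = max(4, int(round(sampling_rate * 0.001)))
    t = np.arange(n) / n
    shape = -np.sin(2 * np.pi * t)
    shape[t >= 0.5] *= 0.4  # smaller rebound phase
    shape /= np.abs(shape).max()
    template = shape * abs(amplitude)
    if amplitude > 0:
        template = -template
    return template, int(np.argmax(np.abs(template)))


def render_raw_trace(
    train: SpikeTrain,
    params: SimParams = SimParams(),
    rng: np.random.Generator | None = None,
) -> RawTrace:
    """Render a spike train as a noisy raw voltage trace.

    Gaussian noise of SD ``noise_sigma`` is sampled at ``sampling_rate``
    and a biphasic ~1 ms template with peak ``|spike_amplitude|`` is added
    with its extremum at each timestamp.
    """
    if not params.sampling_rate > 0:
        raise ValueError("sampling_rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(train.duration * fs))
    x = (
        rng.normal(0.0, params.noise_sigma, n)
        if params.noise_sigma > 0
        else np.zeros(n)
    )
    template, peak = _spike_template(fs, params.spike_amplitude)
    for ts in train.timestamps:
        k = int(round((ts - train.t_start) * fs)) - peak
        lo, hi = max(k, 0), min(k + template.size, n)
        if hi > lo:
            x[lo:hi] += template[lo - k : hi - k]
    return RawTrace(train.electrode_id, fs, x, train.t_start)


# --------------------------------------------------------------------------
# Protocol builders
# --------------------------------------------------------------------------


def constant_protocol(duration: float, label: str = "spontaneous") -> list[EpochSpec]:
    """A single unmodulated epoch of the given duration."""
    return [EpochSpec(label, 0.0, duration)]


def dose_response_protocol(
    concentrations,
    epoch_duration: float,
    params: SimParams = SimParams(),
    vehicle_label: str = "vehicle",
    unit: str = "nM",
) -> list[EpochSpec]:
    """Cumulative dosing: a vehicle epoch, then one epoch per dose.

    The SBF rate is scaled by the Hill multiplier at each concentration
    while the within-burst rate is scaled by its inverse, so SBF counts
    rise dose-dependently with no change in the total spike rate —
    the dissociation observed under neuromodulators.  Sporadic rates are
    untouched.
    """
    epochs = [EpochSpec(vehicle_label, 0.0, epoch_duration)]
    t = epoch_duration
    for c in concentrations:
        m = hill_multiplier(c, params.dose_Emax, params.dose_EC50)
        epochs.append(
            EpochSpec(
                f"dose_{c:g}{unit}",
                t,
                t + epoch_duration,
                sbf_mult=m,
                intra_burst_mult=1.0 / m,
            )
        )
        t += epoch_duration
    return epochs


def lfs_protocol(
    params: SimParams = SimParams(),
    baseline_s: float = 3 * 3600.0,
    n_sets: int = 4,
    stim_s: float = 900.0,
    set_period_s: float = 5400.0,
    post_s: float = 3 * 3600.0,
    step_s: float = 300.0,
) -> list[EpochSpec]:
    """Low-frequency-stimulation protocol with depression and recovery.

    Mirrors the 1 Hz LFS design: a spontaneous baseline, ``n_sets``
    stimulation sets (each ``stim_s`` of stimulation followed by
    spontaneous activity up to ``set_period_s``), then a post period.
    After each stimulation the sporadic rate, SBF rate and coupling are
    depressed by their respective depths and recover exponentially; the
    smooth recovery is discretised into ``step_s`` piecewise-constant
    epochs evaluated at the step midpoint.  Depression is re-triggered by
    each set (the most recent stimulation dominates).
    """
    epochs: list[EpochSpec] = [EpochSpec("baseline", 0.0, baseline_s)]
    t = baseline_s
    for k in range(n_sets):
        # during stimulation: activity fully depressed (analyses mask it)
        epochs.append(
            EpochSpec(
                f"stim{k + 1}",
                t,
                t + stim_s,
                sporadic_mult=1 - params.lfs_depth_spike,
                sbf_mult=1 - params.lfs_depth_sbf,
                coupling_mult=1 - params.lfs_depth_coupling,
            )
        )
        t += stim_s
        stim_end = t
        span = (set_period_s - stim_s) if k < n_sets - 1 else post_s
        n_steps = max(1, int(round(span / step_s)))
        for s in range(n_steps):
            a = stim_end + s * span / n_steps
            b = stim_end + (s + 1) * span / n_steps
            dt = (a + b) / 2 - stim_end
            epochs.append(
                EpochSpec(
                    f"recovery{k + 1}",
                    a,
                    b,
                    sporadic_mult=depression_factor(
                        dt, params.lfs_depth_spike, params.lfs_tau_spike
                    ),
                    sbf_mult=depression_factor(
                        dt, params.lfs_depth_sbf, params.lfs_tau_sbf
                    ),
                    coupling_mult=depression_factor(
                        dt, params.lfs_depth_coupling, params.lfs_tau_spike
                    ),
                )
            )
        t = stim_end + span
    return epochs


def neuromodulator_cycle_protocol(
    params: SimParams = SimParams(),
    concentration: float = 100.0,
    cycle_s: float = 12 * 3600.0,
    n_cycles: int = 2,
    effect_s: float = 5 * 3600.0,
    decay_tau_s: float = 2 * 3600.0,
    step_s: float = 3600.0,
) -> list[EpochSpec]:
    """Alternating medium / neuromodulator cycles.

    Odd cycles are plain medium; even cycles carry the dose, whose SBF-rate
    multiplier holds at the Hill value for ``effect_s`` and then decays
    exponentially back to 1, discretised at ``step_s`` (default hourly).
    """
    m_full = hill_multiplier(concentration, params.dose_Emax, params.dose_EC50)
    epochs: list[EpochSpec] = []
    t = 0.0
    for cyc in range(n_cycles):
        if cyc % 2 == 0:
            epochs.append(EpochSpec(f"medium{cyc // 2 + 1}", t, t + cycle_s))
            t += cycle_s
        else:
            n_steps = max(1, int(round(cycle_s / step_s)))
            for s in range(n_steps):
                a = t + s * cycle_s / n_steps
                b = t + (s + 1) * cycle_s / n_steps
                mid = (a + b) / 2 - t
                if mid <= effect_s:
                    m = m_full
                else:
                    m = 1 + (m_full - 1) * math.exp(-(mid - effect_s) / decay_tau_s)
                epochs.append(
                    EpochSpec(
                        f"dose{cyc // 2 + 1}",
                        a,
                        b,
                        sbf_mult=m,
                        intra_burst_mult=1.0 / m,
                    )
                )
            t += cycle_s
    return epochs
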