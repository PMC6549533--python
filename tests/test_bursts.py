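import numpy as np
import pytest

from measync import (
    SBFEvent,
    SBFParams,
    SimParams,
    SpikeTrain,
    WellRecording,
    active_channels,
    array_spike_histogram,
    classify_spikes,
    constant_protocol,
    count_sbf,
    detect_sbf,
    rate_summary,
    simulate_well,
)


def _uniform_well(geometry, times_per_electrode, t_stop=600.0):
    trains = tuple(
        SpikeTrain(eid, np.asarray(times_per_electrode.get(eid, []), float), 0.0, t_stop)
        for eid in geometry.electrode_ids
    )
    return WellRecording(geometry, trains)


class TestHistogram:
    def test_empty_well(self, geometry):
        well = _uniform_well(geometry, {})
        h = array_spike_histogram(well, 0.1)
        assert h.counts.sum() == 0
        assert h.active_counts.max() == 0

    def test_one_spike_per_electrode_first_bin(self, geometry):
        well = _uniform_well(geometry, {e: [0.05] for e in geometry.electrode_ids})
        h = array_spike_histogram(well, 0.1)
        assert h.counts[0] == 16
        assert h.active_counts[0] == 16
        assert h.counts[1:].sum() == 0

    @pytest.mark.parametrize("bin_width", [0.05, 0.1, 0.7, 1.0])
    def test_counts_conserved(self, default_well, bin_width):
        well, _ = default_well
        h = array_spike_histogram(well, bin_width)
        assert h.counts.sum() == well.total_spikes()


class TestDetectSBF:
    def test_pure_sporadic_yields_no_events(self, geometry):
        params = SimParams(sporadic_rate=1.0, sbf_rate=0.0)
        well, _ = simulate_well(constant_protocol(600.0), params, seed=10)
        assert detect_sbf(well) == []

    def test_scripted_bursts_recovered(self, default_well):
        well, truth = default_well
        events = detect_sbf(well)
        gt = truth.sbf_times
        recovered = sum(
            any(e.t_start <= g1 and e.t_end >= g0 for e in events) for g0, g1 in gt
        )
        spurious = sum(
            not any(e.t_start <= g1 and e.t_end >= g0 for g0, g1 in gt)
            for e in events
        )
        assert recovered / len(gt) >= 0.9
        assert spurious <= 0.1 * max(len(events), 1)

    def test_merge_rule_bridges_short_gap(self, geometry):
        # one burst split by a 0.2 s silent gap -> single event
        times = {}
        burst1 = np.arange(10.0, 10.4, 0.005)
        burst2 = np.arange(10.6, 11.0, 0.005)
        for eid in geometry.electrode_ids:
            times[eid] = np.concatenate([burst1, burst2]) + 1e-4 * hash(eid) % 0.001
        well = _uniform_well(geometry, times, t_stop=20.0)
        params = SBFParams(min_total_count_per_bin=50, max_merge_gap=0.3)
        events = detect_sbf(well, params)
        assert len(events) == 1

    def test_time_translation_invariance(self, geometry):
        rng = np.random.default_rng(0)
        base = {e: np.sort(rng.uniform(0, 60, 300)) for e in geometry.electrode_ids}
        burst = np.arange(30.0, 31.0, 0.01)
        times = {e: np.sort(np.concatenate([t, burst])) for e, t in base.items()}
        w1 = _uniform_well(geometry, times, t_stop=60.0)
        shifted = {
            e: t + 100.0 for e, t in times.items()
        }
        trains = tuple(
            SpikeTrain(e, shifted[e], 100.0, 160.0) for e in geometry.electrode_ids
        )
        w2 = WellRecording(geometry, trains)
        p = SBFParams(min_total_count_per_bin=100)
        e1, e2 = detect_sbf(w1, p), detect_sbf(w2, p)
        assert len(e1) == len(e2) == 1
        assert e2[0].t_start - e1[0].t_start == pytest.approx(100.0)


class TestClassifyAndCount:
    def test_no_events_all_sporadic(self, default_well):
        well, _ = default_well
        cls = classify_spikes(well, [])
        assert all((~m).all() for m in cls.burst_masks.values())

    def test_spike_at_event_start_is_burst(self, geometry):
        well = _uniform_well(geometry, {"E01": [5.0, 7.0]}, t_stop=10.0)
        ev = [SBFEvent(5.0, 6.0, 10, frozenset({"E01"}))]
        cls = classify_spikes(well, ev)
        assert cls.burst_masks["E01"].tolist() == [True, False]

    def test_partition_conserves_counts(self, default_well):
        well, _ = default_well
        events = detect_sbf(well)
        cls = classify_spikes(well, events)
        for tr in well.trains:
            assert cls.n_burst(tr.electrode_id) + cls.n_sporadic(tr.electrode_id) == tr.n_spikes

    def test_overlapping_events_rejected(self, default_well):
        well, _ = default_well
        ev = [
            SBFEvent(1.0, 2.0, 5, frozenset()),
            SBFEvent(1.5, 2.5, 5, frozenset()),
        ]
        with pytest.raises(ValueError):
            classify_spikes(well, ev)

    def test_count_sbf_half_open(self):
        events = [SBFEvent(t, t + 0.5, 10, frozenset()) for t in (0.0, 10.0, 20.0)]
        assert count_sbf(events, 0.0, 20.0) == 2  # start at t1 excluded
        assert count_sbf([], 0.0, 1.0) == 0
        assert count_sbf(events, 0.0, 30.0) == 3


class TestRates:
    def test_active_channel_boundary(self, geometry):
        times = {
            "E01": np.linspace(0.001, 599.999, 601),  # just above 1 Hz
            "E02": np.linspace(0.001, 599.999, 599),  # just below
        }
        well = _uniform_well(geometry, times)
        cls = classify_spikes(well, [])
        act = active_channels(well, cls, min_rate=1.0)
        assert "E01" in act and "E02" not in act

    def test_silent_well_empty(self, geometry):
        well = _uniform_well(geometry, {})
        cls = classify_spikes(well, [])
        assert active_channels(well, cls) == set()
        rs = rate_summary(well, cls)
        assert rs.total_mean == 0.0 and rs.sporadic_mean == 0.0

    def test_homogeneous_poisson_rate_recovered(self, poisson_well):
        cls = classify_spikes(poisson_well, [])
        rs = rate_summary(poisson_well, cls)
        # 5 Hz Poisson: mean within 3 SE of truth
        se = max(rs.sporadic_sem, 1e-6)
        assert abs(rs.sporadic_mean - 5.0) < 3 * se + 0.1

    def test_total_at_least_sporadic(self, default_well):
        well, _ = default_well
        cls = classify_spikes(well, detect_sbf(well))
        rs = rate_summary(well, cls)
        per = rs.per_electrode
        assert (per["total_rate"] >= per["sporadic_rate"] - 1e-12).all()
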