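import numpy as np
import pytest

from measync import (
    SimParams,
    anova_dunnett,
    bin_timecourse,
    constant_protocol,
    detect_sbf,
    dose_response_table,
    holm_adjust,
    paired_t,
    percent_of_reference,
    run_cycle_experiment,
    run_dose_response,
    simulate_well,
)


class TestPercentOfReference:
    def test_identity(self):
        assert percent_of_reference(5.0, 5.0) == 100.0

    def test_zero_numerator(self):
        assert percent_of_reference(0.0, 3.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_of_reference(1.0, 0.0)


class TestBinTimecourse:
    def test_constant_rate_near_100(self, poisson_well):
        tb = bin_timecourse(poisson_well, None, "spikes", 60.0, (0.0, 60.0))
        assert tb.n_bins == 15
        # Poisson with ~4800 spikes/bin: all bins within a few percent
        assert np.nanmax(np.abs(tb.normalized - 100.0)) < 10.0
        assert tb.normalized[0] == pytest.approx(100.0)

    def test_masked_bins_are_nan_but_kept(self, poisson_well):
        tb = bin_timecourse(
            poisson_well, None, "spikes", 60.0, (0.0, 60.0), mask_windows=[(120.0, 180.0)]
        )
        assert tb.masked[2]
        assert np.isnan(tb.normalized[2])
        assert tb.values[2] > 0  # raw value retained

    def test_misaligned_reference_rejected(self, poisson_well):
        with pytest.raises(ValueError):
            bin_timecourse(poisson_well, None, "spikes", 60.0, (10.0, 70.0))

    def test_sbf_metric_counts_events(self, default_well):
        well, _ = default_well
        events = detect_sbf(well)
        tb = bin_timecourse(well, events, "sbf", 100.0, (0.0, 100.0))
        assert tb.values.sum() == len(events)

    def test_zero_reference_rejected(self, geometry):
        well, _ = simulate_well(
            constant_protocol(120.0), SimParams(sporadic_rate=0.0, sbf_rate=0.0), seed=0
        )
        with pytest.raises(ValueError):
            bin_timecourse(well, None, "spikes", 60.0, (0.0, 60.0))


class TestAnovaDunnett:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 8)
        res = anova_dunnett({"c": base, "t1": base, "t2": base}, "c")
        assert res.f_stat == pytest.approx(0.0, abs=1e-10)
        assert (res.pvalues > 0.99).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        groups = {
            "c": rng.normal(0, 1, 6),
            "t1": rng.normal(0, 1, 6),
            "t2": rng.normal(5, 1, 6),  # 5 SD shift
        }
        res = anova_dunnett(groups, "c")
        assert res.pvalues["t2"] < 0.01
        assert res.pvalues["t1"] > 0.05

    def test_permutation_agrees_with_dunnett(self):
        rng = np.random.default_rng(2)
        groups = {
            "c": rng.normal(0, 1, 8),
            "t1": rng.normal(2.0, 1, 8),
            "t2": rng.normal(0.2, 1, 8),
        }
        d = anova_dunnett(groups, "c", method="dunnett")
        p = anova_dunnett(groups, "c", method="permutation", n_resamples=4000, seed=3)
        assert (d.pvalues["t1"] < 0.05) == (p.pvalues["t1"] < 0.05)
        assert abs(d.pvalues["t2"] - p.pvalues["t2"]) < 0.25

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett({"c": [1.0], "t": [1.0, 2.0]}, "c")


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_stepdown(self):
        out = holm_adjust([0.01, 0.04])
        assert out.tolist() == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_monotone_and_at_least_raw(self):
        raw = np.array([0.001, 0.2, 0.01, 0.04, 0.9])
        adj = holm_adjust(raw)
        assert (adj >= raw).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestPairedT:
    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.1, 8)
        res = paired_t(x, x + 3.0 + rng.normal(0, 0.1, 8))
        assert res.p_value < 0.01
        assert res.mean_difference == pytest.approx(3.0, abs=0.3)

    def test_antisymmetric(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.mean_difference == pytest.approx(-b.mean_difference)
        assert a.p_value == pytest.approx(b.p_value)


class TestDoseResponsePipeline:
    def test_sbf_increase_with_dose(self):
        # SBF counts rise with concentration while normalization keeps
        # vehicle at 100%
        params = SimParams(sporadic_rate=2.0, sbf_rate=0.06, seed=0)
        pct = run_dose_response([1.0, 10.0, 100.0, 1000.0], params, n_wells=4, epoch_s=1200.0, seed=6)
        means = pct.mean()
        assert means["vehicle"] == pytest.approx(100.0)
        assert means["dose_1000nM"] > means["dose_1nM"]
        assert means["dose_1000nM"] > 150.0
        table = dose_response_table({c: pct[c].to_numpy() for c in pct.columns})
        assert table.loc["dose_1000nM", "p_holm"] < 0.05


class TestCycleExperiment:
    def test_sbf_elevated_spikes_flat(self):
        # one medium + one dose cycle, hourly bins: SBF counts rise under
        # the neuromodulator while total spike counts do not
        params = SimParams(sporadic_rate=2.0, intra_burst_rate=25.0)
        spikes, sbf = run_cycle_experiment(
            params, n_wells=3, seed=8, cycle_s=6 * 3600.0, n_cycles=2
        )
        dose_bins = [6, 7, 8]  # first hours after administration
        sbf_groups = {"ref": sbf.iloc[:, 5].to_numpy()}
        spike_groups = {"ref": spikes.iloc[:, 5].to_numpy()}
        for b in dose_bins:
            sbf_groups[f"h{b}"] = sbf.iloc[:, b].to_numpy()
            spike_groups[f"h{b}"] = spikes.iloc[:, b].to_numpy()
        res_sbf = anova_dunnett(sbf_groups, "ref")
        res_spk = anova_dunnett(spike_groups, "ref")
        assert (res_sbf.pvalues < 0.05).all()
        assert (res_spk.pvalues > 0.05).all()
        assert sbf.iloc[:, dose_bins].mean().mean() > 150.0
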