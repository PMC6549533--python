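import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from measync import (
    SimParams,
    SurrogateParams,
    SynchronyStat,
    WellRecording,
    constant_protocol,
    count_synchronized_spikes,
    pair_changes,
    reduction_rate,
    shuffle_isi_surrogate,
    significant_pairs,
    simulate_well,
    stats_frame,
    well_synchrony,
    z_by_distance,
    z_score_pair,
)

from conftest import make_train


def brute_force_count(a, b, window):
    return int(sum(abs(x - y) < window for x in a for y in b))


class TestCountSynchronized:
    def test_empty_train(self):
        assert count_synchronized_spikes(make_train([]), make_train([1.0], eid="E02")) == 0

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0.00, 0.50], [0.05, 0.90], 1),
            ([0.00, 0.05], [0.04], 2),
            ([0.1], [0.2], 0),  # difference exactly at the window: excluded
        ],
    )
    def test_hand_counted_examples(self, a, b, expected):
        ta, tb = make_train(a), make_train(b, eid="E02")
        assert count_synchronized_spikes(ta, tb, 0.1) == expected
        assert count_synchronized_spikes(tb, ta, 0.1) == expected  # symmetric

    def test_mismatched_bounds_rejected(self):
        with pytest.raises(ValueError):
            count_synchronized_spikes(
                make_train([1.0]), make_train([1.0], t_stop=20.0, eid="E02")
            )

    @given(
        a=st.lists(st.floats(0, 10, allow_nan=False, width=32), unique=True, max_size=200),
        b=st.lists(st.floats(0, 10, allow_nan=False, width=32), unique=True, max_size=200),
        w=st.sampled_from([0.01, 0.1, 0.5]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, a, b, w):
        ta = make_train(sorted(a))
        tb = make_train(sorted(b), eid="E02")
        assert count_synchronized_spikes(ta, tb, w) == brute_force_count(a, b, w)


class TestSurrogate:
    def test_short_trains_unchanged(self, rng):
        for times in ([], [3.0], [1.0, 4.0]):
            tr = make_train(times)
            out = shuffle_isi_surrogate(tr, rng)
            assert np.array_equal(out.timestamps, tr.timestamps)

    def test_invariants_preserved(self, rng):
        tr = make_train(np.sort(rng.uniform(0, 10, 50)))
        for _ in range(100):
            out = shuffle_isi_surrogate(tr, rng)
            assert out.n_spikes == tr.n_spikes
            assert out.timestamps[0] == tr.timestamps[0]
            assert out.timestamps[-1] == pytest.approx(tr.timestamps[-1])
            assert np.allclose(np.sort(out.isis()), np.sort(tr.isis()))

    def test_permutation_uniformity(self, rng):
        # train [0, 1, 3]: only two distinct shuffles, equally likely
        tr = make_train([0.0, 1.0, 3.0])
        hits = {(0.0, 1.0, 3.0): 0, (0.0, 2.0, 3.0): 0}
        for _ in range(1000):
            out = tuple(shuffle_isi_surrogate(tr, rng).timestamps)
            hits[out] += 1
        chi = sps.chisquare(list(hits.values()))
        assert chi.pvalue > 1e-3


class TestZScore:
    def test_direct_formula(self):
        s = SynchronyStat(("a", "b"), 4, 2.0, 1.0, (4 - 2.0) / 1.0, True)
        assert s.z == 2.0  # N_real 4, surrogate mean 2, SD 1

    def test_single_spike_pair_undefined(self, rng):
        ti = make_train([5.0])
        tj = make_train([5.01], eid="E02")
        stat = z_score_pair(ti, tj, SurrogateParams(), rng)
        assert not stat.defined
        assert np.isnan(stat.z)

    def test_time_translation_invariance(self):
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 100, 200))
        b = np.sort(rng.uniform(0, 100, 200))
        s1 = z_score_pair(
            make_train(a, t_stop=100.0),
            make_train(b, t_stop=100.0, eid="E02"),
            SurrogateParams(seed=9),
        )
        s2 = z_score_pair(
            make_train(a + 50.0, t_start=50.0, t_stop=150.0),
            make_train(b + 50.0, t_start=50.0, t_stop=150.0, eid="E02"),
            SurrogateParams(seed=9),
        )
        assert s1.n_real == s2.n_real
        assert s1.z == pytest.approx(s2.z)


class TestWellSynchrony:
    def test_16_electrodes_give_120_stats(self, poisson_well):
        stats = well_synchrony(
            poisson_well, SurrogateParams(n_surrogates=5, seed=0), window_t=(0.0, 60.0)
        )
        assert len(stats) == 120

    def test_null_z_distribution(self, poisson_well):
        stats = well_synchrony(poisson_well, SurrogateParams(seed=1))
        z = np.array([s.z for s in stats if s.defined])
        assert abs(z.mean()) <= 0.15
        assert 0.6 <= z.std(ddof=1) <= 1.6

    def test_class_filter_monotone(self, default_well):
        from measync import classify_spikes, detect_sbf

        well, _ = default_well
        cls = classify_spikes(well, detect_sbf(well))
        p = SurrogateParams(n_surrogates=5, seed=2)
        all_stats = well_synchrony(well, p, "all", (0.0, 120.0))
        spor = well_synchrony(well, p, "sporadic", (0.0, 120.0), cls)
        for sa, ss in zip(all_stats, spor):
            assert sa.n_real >= ss.n_real


class TestDistanceProfile:
    def _stats_for_grid(self, geometry, z_value=1.0):
        from measync import enumerate_pairs

        return [
            SynchronyStat(p, 1, 0.5, 0.5, z_value, True)
            for p in enumerate_pairs(geometry)
        ]

    def test_nine_distances_on_4x4_grid(self, geometry):
        df = z_by_distance(self._stats_for_grid(geometry), geometry)
        assert len(df) == 9
        assert df["n_pairs"].sum() == 120

    def test_nearest_group_has_24_pairs(self, geometry):
        # 4x4 grid: 4 rows x 3 + 4 cols x 3 = 24 unordered adjacencies
        df = z_by_distance(self._stats_for_grid(geometry), geometry)
        assert df.iloc[0]["distance_um"] == pytest.approx(350.0)
        assert df.iloc[0]["n_pairs"] == 24

    def test_flat_profile_for_equal_z(self, geometry):
        df = z_by_distance(self._stats_for_grid(geometry, 2.5), geometry)
        assert np.allclose(df["mean_z"], 2.5)


class TestReductionRate:
    @staticmethod
    def _stat(pair, z, defined=True):
        return SynchronyStat(pair, 0, 0.0, 1.0, z, defined)

    def test_printed_worked_example(self):
        # 648 sub-threshold pairs of which 345 decreased -> 53.2%
        before, after = [], []
        for k in range(648):
            p = (f"a{k}", f"b{k}")
            before.append(self._stat(p, 1.0))
            after.append(self._stat(p, 0.5 if k < 345 else 1.5))
        rr = reduction_rate(before, after, "below", 2.58)
        assert rr.n_band == 648 and rr.n_decreased == 345
        assert round(rr.pct, 1) == 53.2

    def test_extremes(self):
        before = [self._stat(("a", "b"), 5.0)]
        assert reduction_rate(before, [self._stat(("a", "b"), 4.0)], "above").pct == 100.0
        assert reduction_rate(before, [self._stat(("a", "b"), 6.0)], "above").pct == 0.0

    def test_empty_band_errors(self):
        before = [self._stat(("a", "b"), 1.0)]
        after = [self._stat(("a", "b"), 0.5)]
        with pytest.raises(ValueError):
            reduction_rate(before, after, "above", 2.58)

    def test_undefined_pairs_excluded(self):
        before = [self._stat(("a", "b"), 5.0), self._stat(("c", "d"), np.nan, False)]
        after = [self._stat(("a", "b"), 4.0), self._stat(("c", "d"), np.nan, False)]
        rr = reduction_rate(before, after, "above")
        assert rr.n_band == 1


class TestSignificantPairs:
    def test_strict_threshold(self):
        s1 = SynchronyStat(("a", "b"), 0, 0, 1, 2.58, True)
        s2 = SynchronyStat(("a", "c"), 0, 0, 1, 2.59, True)
        s3 = SynchronyStat(("a", "d"), 0, 0, 1, np.nan, False)
        assert significant_pairs([s1, s2, s3]) == [s2]
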