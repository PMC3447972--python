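import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cenmisloc import (
    ProbeTrack,
    SpikeInSet,
    estimate_global_fold_change,
    ratio_track,
    running_average,
    scale_by_spike_ins,
)
from cenmisloc.normalize import spike_scale_factor


def track_with_spikes(chrom_values, spike_values, spike_refs, spacing=100):
    n_c, n_s = len(chrom_values), len(spike_values)
    chroms = np.concatenate(
        [np.full(n_c, "I", dtype=object), np.full(n_s, "spikein", dtype=object)]
    )
    positions = np.concatenate([np.arange(n_c) * spacing, np.arange(n_s) * spacing])
    values = np.concatenate([chrom_values, spike_values]).astype(float)
    track = ProbeTrack(chroms, positions, values, "linear", spacing)
    spikes = SpikeInSet(np.arange(n_c, n_c + n_s), np.asarray(spike_refs, float))
    return track, spikes


class TestSpikeScaling:
    def test_reference_matching_track_unchanged(self):
        track, spikes = track_with_spikes([1.0, 2.0], [1.0, 3.0], [1.0, 3.0])
        scaled = scale_by_spike_ins(track, spikes)
        np.testing.assert_allclose(scaled.values, track.values)

    def test_constant_multiple_exactly_inverted(self):
        base, spikes = track_with_spikes([1.0, 2.0, 4.0], [1.0, 3.0], [1.0, 3.0])
        tripled = base.with_values(base.values * 3.0)
        scaled = scale_by_spike_ins(tripled, spikes)
        np.testing.assert_allclose(scaled.values, base.values)

    def test_identical_spike_values_give_identical_factors(self):
        a, spikes = track_with_spikes([1.0, 5.0], [2.0, 2.0], [1.0, 1.0])
        b, _ = track_with_spikes([9.0, 0.5], [2.0, 2.0], [1.0, 1.0])
        assert spike_scale_factor(a, spikes) == spike_scale_factor(b, spikes)

    def test_idempotent(self):
        track, spikes = track_with_spikes([1.0, 2.0, 4.0], [5.0, 7.0], [1.0, 3.0])
        once = scale_by_spike_ins(track, spikes)
        twice = scale_by_spike_ins(once, spikes)
        np.testing.assert_allclose(once.values, twice.values)
        assert spike_scale_factor(once, spikes) == pytest.approx(1.0)

    def test_rank_order_preserved(self):
        track, spikes = track_with_spikes([3.0, 1.0, 2.0], [5.0], [1.0])
        scaled = scale_by_spike_ins(track, spikes)
        chrom = track.chromosomal_mask()
        assert list(np.argsort(scaled.values[chrom])) == list(
            np.argsort(track.values[chrom])
        )

    def test_empty_spikes_rejected(self, make_track):
        track = make_track([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            scale_by_spike_ins(track, SpikeInSet(np.array([]), np.array([])))


class TestRatioTrack:
    def test_self_ratio_is_unity(self, make_track):
        track = make_track([1.0, 2.0, 3.0])
        np.testing.assert_allclose(ratio_track(track, track, "linear").values, 1.0)
        np.testing.assert_allclose(ratio_track(track, track, "log2").values, 0.0)

    def test_constant_scaling(self, make_track):
        wt = make_track([1.0, 2.0, 3.0])
        mut = wt.with_values(wt.values * 2.0)
        np.testing.assert_allclose(ratio_track(mut, wt, "linear").values, 2.0)
        np.testing.assert_allclose(ratio_track(mut, wt, "log2").values, 1.0)

    def test_scale_round_trip(self, make_track):
        wt = make_track([1.0, 2.0, 4.0])
        mut = make_track([3.0, 2.0, 1.0])
        lin = ratio_track(mut, wt, "linear").values
        log = ratio_track(mut, wt, "log2").values
        np.testing.assert_allclose(log, np.log2(lin))

    def test_grid_mismatch_rejected(self, make_track):
        a = make_track([1.0, 2.0], spacing=100)
        b = make_track([1.0, 2.0], spacing=50)
        with pytest.raises(ValueError, match="grid"):
            ratio_track(a, b)

    def test_log2_inputs_accepted(self, make_track):
        wt = make_track([0.0, 1.0], scale="log2")
        mut = make_track([1.0, 1.0], scale="log2")
        np.testing.assert_allclose(
            ratio_track(mut, wt, "linear").values, [2.0, 1.0]
        )


class TestRunningAverage:
    def test_window_one_is_identity(self, make_track):
        track = make_track([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(running_average(track, 1).values, track.values)

    def test_constant_track_unchanged(self, make_track):
        track = make_track(np.full(50, 3.25))
        np.testing.assert_allclose(running_average(track, 7).values, 3.25)

    def test_unit_impulse_window_five(self, make_track):
        values = np.zeros(21)
        values[10] = 1.0
        track = make_track(values, scale="log2")
        smoothed = running_average(track, 5).values
        expected = np.convolve(values, np.ones(5) / 5, mode="same")
        np.testing.assert_allclose(smoothed, expected)
        np.testing.assert_allclose(smoothed[8:13], 0.2)

    def test_even_window_widened_to_odd(self, make_track):
        track = make_track(np.arange(1.0, 31.0))
        np.testing.assert_allclose(
            running_average(track, 4).values, running_average(track, 5).values
        )

    def test_edges_use_truncated_windows(self, make_track):
        track = make_track([1.0, 2.0, 3.0, 4.0, 5.0])
        out = running_average(track, 3).values
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_window_larger_than_chromosome_rejected(self, make_track):
        with pytest.raises(ValueError, match="window"):
            running_average(make_track([1.0, 2.0]), 5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=9, max_size=40),
        st.floats(-10, 10),
        st.integers(1, 4).map(lambda k: 2 * k + 1),
    )
    def test_commutes_with_adding_a_constant(self, values, const, window):
        base = _log_track(values)
        shifted = base.with_values(base.values + const)
        np.testing.assert_allclose(
            running_average(shifted, window).values,
            running_average(base, window).values + const,
            atol=1e-9,
        )

    def test_mean_preserved_up_to_edge_effects(self, make_track):
        rng = np.random.default_rng(0)
        values = rng.lognormal(0, 0.3, 500)
        track = make_track(values)
        window = 25
        smoothed = running_average(track, window).values
        assert abs(smoothed.mean() - values.mean()) <= (
            window / values.size
        ) * np.abs(values).max()


def _log_track(values):
    values = np.asarray(values, dtype=float)
    return ProbeTrack(
        np.full(values.size, "I", dtype=object),
        np.arange(values.size) * 10,
        values,
        "log2",
        10,
    )


class TestGlobalFoldChange:
    def test_identical_tracks_give_unity(self):
        track, spikes = track_with_spikes([1.0, 2.0, 3.0], [1.0, 2.0], [1.0, 2.0])
        assert estimate_global_fold_change(track, track, spikes) == pytest.approx(1.0)

    def test_noise_free_multiplier_recovered_exactly(self):
        wt, spikes = track_with_spikes([1.0, 2.0, 3.0, 4.0], [1.0, 2.0], [1.0, 2.0])
        mut_values = wt.values.copy()
        mut_values[wt.chromosomal_mask()] *= 1.7
        mut = wt.with_values(mut_values)
        assert estimate_global_fold_change(mut, wt, spikes) == pytest.approx(1.7)

    @pytest.mark.parametrize("c_mut,c_wt", [(3.0, 1.0), (1.0, 5.0), (0.25, 4.0)])
    def test_invariant_to_constant_premultiplication(self, c_mut, c_wt):
        wt, spikes = track_with_spikes(
            [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 4.0], [1.0, 2.0, 4.0]
        )
        mut_values = wt.values.copy()
        mut_values[wt.chromosomal_mask()] *= 1.7
        mut = wt.with_values(mut_values)
        baseline = estimate_global_fold_change(mut, wt, spikes)
        rescaled = estimate_global_fold_change(
            mut.with_values(mut.values * c_mut),
            wt.with_values(wt.values * c_wt),
            spikes,
        )
        assert rescaled == pytest.approx(baseline)
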