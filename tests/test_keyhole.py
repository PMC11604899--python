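import numpy as np
import pytest
from hypothesis import given, strategies as st

from xeosc.k0 import PeakSet
from xeosc.keyhole import (KeyholeImageStack, KeySchedule, assemble_keyhole,
                           bin_two_key, gaussian_window_kernel,
                           phase_to_delay_ms, sliding_window_keys, sw_maps,
                           two_key_map)


def peakset(maxima, minima, n_per_cycle=57, heart_rate=70.0):
    return PeakSet(maxima=np.asarray(maxima), minima=np.asarray(minima),
                   window=(0.3, 14.0), heart_rate=heart_rate,
                   n_per_cycle=n_per_cycle)


def sinusoid_peaks(n_spokes=934, period=57):
    maxima = np.arange(period, n_spokes - period, period)
    minima = maxima + period // 2
    return peakset(maxima, minima, n_per_cycle=period)


class TestBinTwoKey:
    def test_default_quota_is_twenty_percent(self):
        sched = bin_two_key(sinusoid_peaks(), 934)
        assert len(sched.keys[0]) == len(sched.keys[1]) == round(0.2 * 934)

    def test_single_maximum_symmetric_window(self):
        peaks = peakset([100], [250])
        sched = bin_two_key(peaks, 934, quota=5)
        assert set(sched.keys[0]) == {98, 99, 100, 101, 102}

    def test_keys_disjoint_and_interleaved(self):
        sched = bin_two_key(sinusoid_peaks(), 934)
        high, low = map(set, sched.keys)
        assert not (high & low)
        # between consecutive maxima windows there is a low window
        highs = np.sort(sched.keys[0])
        lows = np.sort(sched.keys[1])
        assert lows.min() > highs.min() and highs.max() > lows.min()

    def test_colliding_windows_shrink_with_warning(self):
        peaks = peakset([100], [103])
        with pytest.warns(UserWarning, match="collided|shrunk"):
            sched = bin_two_key(peaks, 110, quota=30)
        assert not (set(sched.keys[0]) & set(sched.keys[1]))

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError):
            bin_two_key(peakset([], [1]), 100)


class TestSlidingWindowKeys:
    def test_number_of_keys_is_spokes_per_cycle(self):
        sched = sliding_window_keys(sinusoid_peaks(period=57), 934)
        assert sched.n_keys == 57
        assert sched.j_pi == 30     # round-half-up(N/2) + 1

    def test_keys_step_forward_by_one_spoke(self):
        sched = sliding_window_keys(sinusoid_peaks(), 934)
        np.testing.assert_array_equal(sched.keys[2], sched.keys[0] + 2)

    def test_indices_past_last_spoke_truncated(self):
        peaks = sinusoid_peaks(n_spokes=934)
        sched = sliding_window_keys(peaks, 934)
        assert all(k.max() < 934 for k in sched.keys)
        assert len(sched.keys[-1]) <= len(sched.keys[0])

    def test_too_few_spokes_per_cycle_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_keys(sinusoid_peaks(period=3), 934)


class TestAssembleKeyhole:
    def test_point_count_formula(self):
        samples = np.zeros((934, 4, 13), complex)
        key = np.arange(187)
        hybrid, sp, pt = assemble_keyhole(samples, key, keyhole_radius=6)
        assert len(sp) == 934 * 7 + 187 * 6 == 7660

    def test_full_key_reproduces_all_samples(self):
        rng = np.random.default_rng(0)
        samples = rng.standard_normal((30, 4, 13)) + 0j
        hybrid, sp, pt = assemble_keyhole(samples, np.arange(30), 6)
        assert len(sp) == 30 * 13
        assert np.allclose(np.sort(hybrid.ravel().real),
                           np.sort(samples.transpose(0, 2, 1).reshape(-1, 4).ravel().real))

    def test_zero_radius_keeps_high_frequencies_only(self):
        samples = np.zeros((30, 4, 13), complex)
        hybrid, sp, pt = assemble_keyhole(samples, np.array([3]), 0)
        assert len(sp) == 30 * 13
        assert pt.min() == 0

    @given(st.integers(10, 60), st.integers(1, 9), st.integers(1, 10))
    def test_counting_oracle(self, n_spokes, radius, key_size):
        samples = np.zeros((n_spokes, 2, 10), complex)
        key = np.arange(min(key_size, n_spokes))
        _, sp, pt = assemble_keyhole(samples, key, radius)
        assert len(sp) == n_spokes * (10 - radius) + len(key) * radius

    def test_empty_key_rejected(self):
        with pytest.raises(ValueError):
            assemble_keyhole(np.zeros((10, 4, 13), complex), np.array([]), 6)


class TestTwoKeyMap:
    def test_arithmetic_of_definition(self):
        out = two_key_map(np.array([1.1]), np.array([0.9]))
        assert out[0] == pytest.approx(20.0)

    def test_equal_images_give_zero(self):
        s = np.random.default_rng(0).uniform(1, 2, (4, 4, 4))
        assert np.allclose(two_key_map(s, s), 0.0)

    def test_zero_mean_voxels_become_nan(self):
        out = two_key_map(np.zeros(3), np.zeros(3))
        assert np.all(np.isnan(out))


class TestSwMaps:
    def make_stack(self, phases, N=57, amp=0.1):
        j = np.arange(N)
        stack = 1 + amp * np.cos(2 * np.pi * j[:, None] / N - phases[None, :])
        return KeyholeImageStack(images=stack[:, :, None, None])

    def test_cosine_stack_recovers_amplitude_and_phase(self):
        stack = self.make_stack(np.zeros(1))
        maps = sw_maps(stack, KeySchedule(keys=[]),)
        # a pure harmonic through the circular smoothing kernel is attenuated
        # exactly by the kernel gain at the fundamental (~2.4% for win 10, s=2)
        kern = gaussian_window_kernel(10, 2.0)
        offs = np.arange(len(kern)) - len(kern) // 2
        gain = float(np.sum(kern * np.cos(2 * np.pi * offs / 57)))
        assert gain > 0.95
        # discrete minimum of the N=57 cosine sits half a key off the trough
        depth = 1.0 - np.cos(2 * np.pi * 28 / 57)
        assert maps.alpha_sw[0, 0, 0] == pytest.approx(100 * 0.1 * gain * depth, rel=1e-6)
        assert maps.j_max[0, 0, 0] == 1
        assert maps.phi[0, 0, 0] == 0.0

    @pytest.mark.parametrize("k", [5, 20, 29, 45])
    def test_shifted_peak_maps_to_phase(self, k):
        N = 57
        phase = 2 * np.pi * (k - 1) / N
        stack = self.make_stack(np.array([phase]), N=N)
        maps = sw_maps(stack, KeySchedule(keys=[]))
        assert maps.j_max[0, 0, 0] == k
        expected = phase if phase <= np.pi else phase - 2 * np.pi
        assert maps.phi[0, 0, 0] == pytest.approx(expected)

    def test_constant_stack_ties_break_to_first_key(self):
        stack = KeyholeImageStack(images=np.ones((57, 2, 2, 2)))
        maps = sw_maps(stack, KeySchedule(keys=[]))
        assert np.all(maps.alpha_sw == 0.0)
        assert np.all(maps.j_max == 1)

    def test_smoothing_preserves_per_voxel_mean(self):
        rng = np.random.default_rng(1)
        stack = KeyholeImageStack(images=rng.uniform(1, 2, (57, 3, 3, 3)))
        maps = sw_maps(stack, KeySchedule(keys=[]))
        raw_mean = stack.images.mean(axis=0)
        assert np.max(np.abs(maps.s_mean - raw_mean) / raw_mean) < 0.01

    def test_mask_applied(self):
        stack = self.make_stack(np.zeros(2))
        mask = np.array([[[True]], [[False]]])
        maps = sw_maps(stack, KeySchedule(keys=[]), mask=mask)
        assert np.isnan(maps.phi[1, 0, 0])
        assert not np.isnan(maps.phi[0, 0, 0])


def test_gaussian_window_kernel_symmetric_and_normalized():
    k10 = gaussian_window_kernel(10, 2.0)
    assert k10.sum() == pytest.approx(1.0)
    assert np.allclose(k10, k10[::-1])
    k11 = gaussian_window_kernel(11, 2.0)
    assert len(k11) % 2 == 1 and np.argmax(k11) == len(k11) // 2


def test_phase_to_delay_at_seventy_bpm():
    # pi of lag at 70 bpm is a touch under half the 857-ms cardiac period
    assert phase_to_delay_ms(np.pi, 70.0) == pytest.approx(428.6, abs=0.1)
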