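import numpy as np
import pytest

from xeosc.keyhole import OscillationMaps
from xeosc.phantom import sphere_mask, two_ellipsoid_lungs
from xeosc.regions import (RAYLEIGH_SD_FACTOR, estimate_background_sigma,
                           make_mask, region_partition, repeatability,
                           snr_gate, summarize_maps)


def noisy_magnitude(truth, sigma, seed=0):
    """Magnitude of truth plus complex noise with per-channel SD ``sigma``."""
    rng = np.random.default_rng(seed)
    return np.abs(truth + sigma * (rng.standard_normal(truth.shape)
                                   + 1j * rng.standard_normal(truth.shape)))


class TestMakeMask:
    def test_noiseless_mask_is_exact_support(self):
        lung = two_ellipsoid_lungs(32).astype(float)
        mask = make_mask(lung, noise_sigma=0.0)
        assert np.array_equal(mask, lung > 0)

    def test_dice_above_095_at_snr_ten(self):
        lung = two_ellipsoid_lungs(32).astype(float)
        sigma = 1.0 / 10.0
        img = noisy_magnitude(lung, sigma)
        mask = make_mask(img, noise_sigma=sigma)
        truth = lung > 0
        dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
        assert dice > 0.95

    def test_all_noise_image_raises(self):
        img = noisy_magnitude(np.zeros((16,) * 3), 1.0)
        with pytest.raises(ValueError, match="mask"):
            make_mask(img, noise_sigma=10.0)


class TestSnrGate:
    def make_image(self, snr, seed=0):
        grid = 24
        mask = sphere_mask(grid, (12, 12, 12), 6)
        sigma = 1.0
        truth = np.where(mask, snr * sigma, 0.0)
        return noisy_magnitude(truth, sigma, seed), mask

    def test_high_snr_included(self):
        img, mask = self.make_image(8.0)
        d = snr_gate(img, mask)
        assert d.include and not d.borderline
        assert d.snr == pytest.approx(8.0, rel=0.15)

    def test_low_snr_excluded(self):
        img, mask = self.make_image(3.0)
        assert not snr_gate(img, mask).include

    def test_borderline_flagged(self):
        img, mask = self.make_image(5.0)
        d = snr_gate(img, mask)
        assert d.include and d.borderline

    def test_rayleigh_correction_of_background(self):
        # recovers the per-channel Gaussian sigma from the Rayleigh magnitude SD
        rng = np.random.default_rng(3)
        mag = np.abs(rng.standard_normal((20,) * 3) + 1j * rng.standard_normal((20,) * 3))
        sigma = estimate_background_sigma(mag, mask=np.zeros((20,) * 3, bool))
        assert sigma == pytest.approx(1.0, rel=0.05)


class TestRegionPartition:
    def test_symmetric_lungs_split_evenly(self):
        mask = two_ellipsoid_lungs(32)
        regions = region_partition(mask)
        assert abs(regions.left.sum() - regions.right.sum()) < 0.05 * mask.sum()

    def test_region_pairs_partition_the_mask(self):
        mask = two_ellipsoid_lungs(32)
        r = region_partition(mask)
        for a, b in (("left", "right"), ("upper", "lower"),
                     ("anterior", "posterior"), ("central", "peripheral")):
            assert np.array_equal(r[a] | r[b], mask)
            assert not np.any(r[a] & r[b])

    def test_peripheral_matches_brute_force_erosion(self):
        """Erosion by 2 equals voxels whose cross-neighborhood (depth 2) fits."""
        grid = 20
        mask = sphere_mask(grid, (10, 10, 10), 8)
        r = region_partition(mask, erosion=2)
        interior = np.zeros_like(mask)
        offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) <= 1]
        for idx in np.argwhere(mask):
            ok = True
            for _ in range(1):
                pass
            # two cross-erosions == all voxels within city-block distance 2 in mask
            for dx in range(-2, 3):
                for dy in range(-2, 3):
                    for dz in range(-2, 3):
                        if abs(dx) + abs(dy) + abs(dz) > 2:
                            continue
                        p = idx + (dx, dy, dz)
                        if np.any(p < 0) or np.any(p >= grid) or not mask[tuple(p)]:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            interior[tuple(idx)] = ok
        assert np.array_equal(r.central, interior)
        assert r.peripheral.sum() == mask.sum() - interior.sum()

    def test_thin_mask_falls_back_with_warning(self):
        mask = np.zeros((16,) * 3, bool)
        mask[4:12, 4:12, 8] = True      # one-voxel-thick slab
        with pytest.warns(UserWarning, match="erosion"):
            region_partition(mask, erosion=2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_partition(np.zeros((8,) * 3, bool))


class TestSummaries:
    def make_maps(self, alpha_sw, alpha_2key=None, phi=None, mask=None):
        return OscillationMaps(alpha_sw=alpha_sw, alpha_2key=alpha_2key, phi=phi,
                               mask=mask)

    def test_constant_map_summaries(self):
        mask = two_ellipsoid_lungs(16)
        maps = self.make_maps(np.where(mask, 20.0, np.nan),
                              np.where(mask, 20.0, np.nan),
                              np.where(mask, 0.1, np.nan))
        df = summarize_maps(maps, region_partition(mask))
        assert np.allclose(df["alpha_sw_median"], 20.0)
        assert np.allclose(df["alpha_2key_mean"], 20.0)
        assert df.attrs["cv"]["cv_sw"] == pytest.approx(0.0, abs=1e-12)

    def test_half_and_half_map_statistics(self):
        mask = two_ellipsoid_lungs(16)
        vals = np.where(mask, 10.0, np.nan)
        x = np.arange(16)[:, None, None] * np.ones((1, 16, 16))
        vals[(x >= 8) & mask] = 30.0
        v = vals[mask]
        maps = self.make_maps(alpha_sw=vals, alpha_2key=vals)
        df = summarize_maps(maps, region_partition(mask))
        assert df.loc["whole", "alpha_2key_mean"] == pytest.approx(v.mean())
        assert df.attrs["cv"]["cv_2key"] == pytest.approx(v.std() / v.mean())

    def test_peripheral_phase_larger_than_central(self):
        mask = two_ellipsoid_lungs(16)
        regions = region_partition(mask)
        phi = np.where(mask, 0.1, np.nan)
        phi[regions.peripheral] = 0.5
        maps = self.make_maps(alpha_sw=None, phi=phi)
        df = summarize_maps(maps, regions)
        assert df.loc["peripheral", "phi_median"] > df.loc["central", "phi_median"]

    def test_wrapped_phase_cv_flagged(self):
        mask = two_ellipsoid_lungs(16)
        phi = np.where(mask, 3.0, np.nan)      # near the wrap point
        maps = self.make_maps(alpha_sw=None, phi=phi)
        with pytest.warns(UserWarning, match="wrap"):
            df = summarize_maps(maps, region_partition(mask))
        assert np.isnan(df.attrs["cv"]["cv_phi"])


class TestRepeatability:
    def test_identical_scans_are_perfectly_repeatable(self):
        rep = repeatability([[10.0, 10.0, 10.0]])
        assert rep.bias == 0 and rep.pct_diff == 0 and rep.cv3 == 0

    def test_pair_arithmetic(self):
        rep = repeatability([[10.0, 12.0]])
        assert rep.bias == pytest.approx(-2.0)
        assert rep.pct_diff == pytest.approx(100 * 2 / 11)

    def test_three_scan_cv(self):
        rep = repeatability([[10.0, 11.0, 12.0]])
        assert rep.cv3 == pytest.approx(1.0 / 11.0)

    def test_loa_contains_bias(self):
        rep = repeatability([[10, 12], [11, 10], [9, 13]])
        assert rep.loa[0] <= rep.bias <= rep.loa[1]

    def test_single_scan_rejected(self):
        with pytest.raises(ValueError):
            repeatability([[10.0]])
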