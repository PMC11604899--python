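import numpy as np
import pytest

from xeosc import SequenceParams
from xeosc.recon import (DcfSystem, Gridder, KaiserBesselKernel, compute_dcf,
                         grid_reconstruct, radial_trajectory)


class TestTrajectory:
    def test_spokes_are_center_out(self):
        traj = radial_trajectory(SequenceParams(n_spokes=50))
        assert np.all(traj.coords[:, 0, :] == 0)
        assert traj.radii[0] == 0
        assert np.all(np.diff(traj.radii) > 0)

    def test_k_max_with_readout_oversampling(self):
        seq = SequenceParams(nominal_matrix=20, readout_oversampling=1.3)
        traj = radial_trajectory(seq)
        assert np.max(np.linalg.norm(traj.points, axis=1)) == pytest.approx(13.0)

    def test_unit_spoke_directions(self):
        traj = radial_trajectory(SequenceParams(n_spokes=100))
        assert np.allclose(np.linalg.norm(traj.spoke_dirs, axis=1), 1.0)

    def test_golden_ordering_covers_every_spherical_cap(self):
        """Every 5%-solid-angle cap holds at least half its expected share."""
        traj = radial_trajectory(SequenceParams(n_spokes=934))
        dirs = traj.spoke_dirs
        rng = np.random.default_rng(0)
        centers = rng.standard_normal((200, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        cos_thresh = 1 - 2 * 0.05        # cap of 5% of the sphere's area
        counts = (dirs @ centers.T > cos_thresh).sum(axis=0)
        assert counts.min() >= 0.5 * 0.05 * 934

    def test_adjacent_spokes_angularly_dispersed(self):
        # keyhole keys need temporally contiguous spokes spread over the sphere
        traj = radial_trajectory(SequenceParams(n_spokes=934))
        d = traj.spoke_dirs
        adjacent = np.sum(d[:-1] * d[1:], axis=1)
        assert np.max(adjacent) < 0.9

    def test_unknown_ordering_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            radial_trajectory(SequenceParams(), ordering="spiral-out")

    def test_random_ordering_seeded(self):
        seq = SequenceParams(n_spokes=64)
        a = radial_trajectory(seq, ordering="random", seed=5)
        b = radial_trajectory(seq, ordering="random", seed=5)
        assert np.array_equal(a.coords, b.coords)


class TestDcf:
    def test_single_point_weight_is_inverse_kernel_peak(self):
        kern = KaiserBesselKernel()
        dcf = compute_dcf(np.zeros((1, 3)), kernel=kern)
        c0 = kern.autoconv(0.0)
        assert dcf.w[0] == pytest.approx(1.0 / c0, rel=1e-9)
        assert dcf.residual < 1e-12

    def test_coincident_points_share_the_weight(self):
        kern = KaiserBesselKernel()
        dcf = compute_dcf(np.zeros((2, 3)), kernel=kern)
        single = compute_dcf(np.zeros((1, 3)), kernel=kern)
        assert np.allclose(dcf.w, single.w[0] / 2)

    def test_uniform_ring_weights_equal(self):
        """64-point uniform 2D ring: symmetry forces equal weights."""
        theta = 2 * np.pi * np.arange(64) / 64
        pts = 3.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        dcf = compute_dcf(pts, max_iter=50, tol=1e-8)
        assert (dcf.w.max() - dcf.w.min()) / dcf.w.mean() < 1e-6

    def test_full_trajectory_converges_below_tolerance(self):
        traj = radial_trajectory(SequenceParams(n_spokes=300, nominal_matrix=10))
        dcf = compute_dcf(traj.points)
        assert dcf.residual < 0.05
        assert dcf.n_iter_used <= 25

    def test_subset_system_matches_direct_construction(self):
        traj = radial_trajectory(SequenceParams(n_spokes=120, nominal_matrix=10))
        pts = traj.points
        system = DcfSystem(pts)
        idx = np.arange(0, len(pts), 3)
        a = compute_dcf(system=system, subset=idx)
        b = compute_dcf(pts[idx])
        assert np.allclose(a.w, b.w, rtol=1e-9)


class TestGridding:
    def test_point_source_psf_peaks_at_center(self, small_seq):
        traj = radial_trajectory(small_seq)
        dcf = compute_dcf(traj.points)
        img = grid_reconstruct(np.ones(len(traj.points), complex), traj.points,
                               dcf, small_seq)
        mag = np.abs(img)
        assert np.unravel_index(mag.argmax(), mag.shape) == (8, 8, 8)

    def test_zero_samples_give_zero_image(self, small_seq):
        traj = radial_trajectory(small_seq)
        dcf = compute_dcf(traj.points)
        img = grid_reconstruct(np.zeros(len(traj.points), complex), traj.points,
                               dcf, small_seq)
        assert np.all(img == 0)

    def test_real_object_image_nearly_real(self, small_seq):
        """Conjugate-symmetric k-space of a real object grids to a ~real image."""
        from xeosc.phantom import make_phantom
        from xeosc.simulate import nudft3
        base = radial_trajectory(small_seq.replace(n_spokes=150))
        dirs = np.concatenate([base.spoke_dirs, -base.spoke_dirs])
        pts = (dirs[:, None, :] * base.radii[None, :, None]).reshape(-1, 3)
        ph = make_phantom(grid=16)
        xs = ph.voxel_coords(ph.lung_mask)
        samples = nudft3(ph.rho_m[ph.lung_mask], pts, xs)[0]
        dcf = compute_dcf(pts)
        img = grid_reconstruct(samples, pts, dcf, small_seq)
        assert np.max(np.abs(img.imag)) < 1e-3 * np.max(np.abs(img))

    def test_misaligned_inputs_rejected(self, small_seq):
        traj = radial_trajectory(small_seq)
        dcf = compute_dcf(traj.points)
        with pytest.raises(ValueError, match="align"):
            grid_reconstruct(np.ones(5, complex), traj.points, dcf, small_seq)

    def test_low_oversampling_warns(self, small_seq):
        traj = radial_trajectory(small_seq)
        with pytest.warns(UserWarning, match="aliasing"):
            Gridder(traj.points, small_seq, kernel=KaiserBesselKernel(os=1.2))


def test_kernel_autoconvolution_properties():
    kern = KaiserBesselKernel()
    assert kern.autoconv(0.0) > 0
    assert kern.autoconv(2.0) == pytest.approx(0.0, abs=1e-9)
    u = np.linspace(-1.9, 1.9, 41)
    assert np.allclose(kern.autoconv(u), kern.autoconv(-u))
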