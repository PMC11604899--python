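"""Forward model of the multi-echo 3D radial dissolved-phase acquisition.

Each spoke s excited at time t_s samples, at trajectory point k and echo e,

    y(s, e, p) = sum_c  A_c e^{i theta_c} E_c(t_e) D_c(t_s) F[rho_c,s](k_{s,p}) + noise,

where E_c(t_e) = exp((i 2 pi df_c - 1/T2*_c) t_e) is the chemical evolution
of compartment c at the echo time (intra-readout chemical evolution is
neglected, consistently with the k-space separation step), D_c is the global
biexponential decay of the dissolved compartments, and F is the exact
(direct) nonuniform discrete Fourier transform of the compartment's voxel
density.  The RBC density is modulated by the cardiac waveform:

    rho_rbc,s(r) = rho_rbc(r) [1 + alpha(r)/2 f(omega t_s - phi(r))].

The periodic waveform is expanded in a few harmonics so the time-varying
volume becomes a small set of static complex volumes with per-spoke scalar
coefficients; the transform of each static volume is computed once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomSpec
from .recon import Trajectory, radial_trajectory
from .sequence import SequenceParams
from .spectral import SpectralModel, default_spectral_model

__all__ = ["KSpaceAcquisition", "simulate_acquisition", "nudft3"]


@dataclass
class KSpaceAcquisition:
    """Multi-echo 3D radial k-space data with trajectory and timing."""

    samples: np.ndarray        # complex, (n_spokes, n_echoes, n_samples_per_echo)
    trajectory: Trajectory
    timestamps: np.ndarray     # absolute excitation time per spoke [s]
    seq: SequenceParams
    spectral_truth: SpectralModel | None = None

    def __post_init__(self):
        ns, ne, npt = self.samples.shape
        if (ns, npt) != (self.trajectory.n_spokes, self.trajectory.n_points):
            raise ValueError("samples and trajectory shapes disagree")
        if len(self.timestamps) != ns:
            raise ValueError("one timestamp per spoke required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_spokes(self) -> int:
        return self.samples.shape[0]

    def k0(self, echo: int = 0) -> np.ndarray:
        """Center-of-k-space sample of every spoke at one echo (complex)."""
        return self.samples[:, echo, 0]


def nudft3(volumes: np.ndarray, coords: np.ndarray, xs: np.ndarray,
           max_elems: float = 3e7) -> np.ndarray:
    """Direct (type-3) nonuniform DFT of one or more volumes.

    ``volumes``: (n_vol, n_vox) values at voxel coordinates ``xs`` (n_vox, 3)
    in FOV fractions; ``coords``: (n_pts, 3) k-space locations in cycles/FOV.
    Returns (n_vol, n_pts) with the convention sum_r rho(r) exp(-2 pi i k.x).
    Chunked over points to bound the phase-matrix memory.
    """
    volumes = np.atleast_2d(np.asarray(volumes, dtype=complex))
    coords = np.asarray(coords, dtype=float)
    xs = np.asarray(xs, dtype=float)
    out = np.empty((volumes.shape[0], coords.shape[0]), dtype=complex)
    step = max(1, int(max_elems / max(1, xs.shape[0])))
    for lo in range(0, coords.shape[0], step):
        hi = min(lo + step, coords.shape[0])
        phase = coords[lo:hi] @ xs.T          # (nc, n_vox)
        P = np.exp(-2j * np.pi * phase)
        out[:, lo:hi] = volumes @ P.T
    return out


def simulate_acquisition(
    phantom: PhantomSpec,
    seq: SequenceParams | None = None,
    spectral: SpectralModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    trajectory: Trajectory | None = None,
    ordering: str = "golden",
) -> KSpaceAcquisition:
    """Simulate the multi-echo radial acquisition of a phantom.

    Complex circular Gaussian noise of standard deviation ``noise_sd`` (per
    real/imaginary channel) is added to every sample; with ``noise_sd = 0``
    the output is deterministic.
    """
    seq = seq or SequenceParams()
    spectral = spectral or default_spectral_model()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if phantom.grid != seq.recon_matrix:
        raise ValueError(
            f"phantom grid {phantom.grid} incompatible with recon matrix {seq.recon_matrix}")
    f_heart = phantom.heart_rate / 60.0
    if f_heart > 0.5 / seq.tr:
        warnings.warn("heart frequency exceeds the spoke-rate Nyquist limit; "
                      "the k0 oscillation will alias", stacklevel=2)

    traj = trajectory or radial_trajectory(seq, ordering=ordering)
    t = seq.spoke_times
    omega = phantom.omega

    support = phantom.lung_mask
    xs = phantom.voxel_coords(support)
    rho_gas = phantom.rho_gas[support]
    rho_m = phantom.rho_m[support]
    rho_rbc = phantom.rho_rbc[support]
    half_amp = rho_rbc * phantom.alpha_map[support] / 2.0
    phi = phantom.phi_map[support]

    # Harmonic expansion of the waveform: f(wt - phi) = sum_h Re[g_h e^{ih(wt-phi)}]
    harm, gam = phantom.waveform.harmonics()
    vols = [rho_gas, rho_m, rho_rbc]
    for h, g in zip(harm, gam):
        v = half_amp * g * np.exp(-1j * h * phi)
        vols.append(v)            # paired with e^{+i h w t}/2
        vols.append(np.conj(v))   # paired with e^{-i h w t}/2
    F = nudft3(np.stack(vols), traj.points, xs)
    npts = traj.n_spokes * traj.n_points
    F_gas = F[0].reshape(traj.n_spokes, traj.n_points)
    F_m = F[1].reshape(traj.n_spokes, traj.n_points)
    F_rbc = F[2].reshape(traj.n_spokes, traj.n_points).copy()
    for idx, h in enumerate(harm):
        Fp = F[3 + 2 * idx].reshape(traj.n_spokes, traj.n_points)
        Fm = F[4 + 2 * idx].reshape(traj.n_spokes, traj.n_points)
        osc = np.exp(1j * h * omega * t)
        F_rbc = F_rbc + 0.5 * (osc[:, None] * Fp + np.conj(osc)[:, None] * Fm)

    decay = phantom.decay(t)[:, None]     # dissolved compartments only
    te = np.asarray(seq.echo_times)
    samples = np.empty((seq.n_spokes, seq.n_echoes, seq.n_samples_per_echo), dtype=complex)
    for e in range(seq.n_echoes):
        w_gas = spectral.gas.evolution(te[e]) * spectral.gas.amplitude * np.exp(1j * spectral.gas.phase)
        w_m = spectral.membrane.evolution(te[e]) * spectral.membrane.amplitude * np.exp(1j * spectral.membrane.phase)
        w_rbc = spectral.rbc.evolution(te[e]) * spectral.rbc.amplitude * np.exp(1j * spectral.rbc.phase)
        samples[:, e, :] = w_gas * F_gas + decay * (w_m * F_m + w_rbc * F_rbc)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + noise_sd * (rng.standard_normal(samples.shape)
                                        + 1j * rng.standard_normal(samples.shape))

    return KSpaceAcquisition(samples=samples, trajectory=traj, timestamps=t.copy(),
                             seq=seq, spectral_truth=spectral)


def add_noise(acq: KSpaceAcquisition, noise_sd: float, seed: int) -> KSpaceAcquisition:
    """Return a copy of a (noiseless) acquisition with fresh complex noise."""
    rng = np.random.default_rng(seed)
    noisy = acq.samples + noise_sd * (rng.standard_normal(acq.samples.shape)
                                      + 1j * rng.standard_normal(acq.samples.shape))
    return KSpaceAcquisition(samples=noisy, trajectory=acq.trajectory,
                             timestamps=acq.timestamps, seq=acq.seq,
                             spectral_truth=acq.spectral_truth)
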