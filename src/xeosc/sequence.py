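"""Acquisition parameters for the multi-echo 3D radial dissolved-phase sequence.

The defaults describe a four-echo flyback 3D radial spectroscopic acquisition
over a 14-s breath hold: 934 center-out spokes, 13 samples per echo with 30%
readout oversampling, TR 15 ms, flip 22 deg, 40-cm FOV reconstructed to a
32^3 matrix.  The nominal acquired resolution is 2 cm (nominal matrix 20), so
the maximum sampled radius is 1.3 x 10 = 13 cycles/FOV.

Also provides the periodic cardiac waveforms used to modulate the RBC signal
and the biexponential envelope emulating RF-induced depolarization and T1
relaxation of the dissolved-phase magnetization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SequenceParams",
    "DecayModel",
    "PeriodicWaveform",
    "sine_waveform",
    "systolic_waveform",
]

#: Echo times (s) of the four flyback echoes.  The true scanner values are not
#: published; these assume a 0.42-ms readout plus ~0.33-ms flyback rewinder.
DEFAULT_ECHO_TIMES = (0.45e-3, 1.20e-3, 1.95e-3, 2.70e-3)


@dataclass(frozen=True)
class SequenceParams:
    """Timing and geometry of the multi-echo 3D radial acquisition."""

    tr: float = 0.015                 # repetition time [s]
    flip: float = 22.0                # flip angle [deg]
    n_spokes: int = 934
    n_echoes: int = 4
    n_samples_per_echo: int = 13
    echo_times: tuple = DEFAULT_ECHO_TIMES   # [s], flyback
    bandwidth: float = 31250.0        # readout bandwidth [Hz]
    fov: float = 0.40                 # field of view [m]
    recon_matrix: int = 32            # reconstructed matrix size per dim
    nominal_matrix: int = 20          # acquired (Nyquist) matrix size per dim
    readout_oversampling: float = 1.3
    n_dummy: int = 20                 # discarded initial excitations

    def __post_init__(self):
        if self.n_spokes < 1:
            raise ValueError("n_spokes must be >= 1")
        te = np.asarray(self.echo_times, dtype=float)
        if len(te) != self.n_echoes:
            raise ValueError("echo_times must have n_echoes entries")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if self.readout_oversampling < 1:
            raise ValueError("readout_oversampling must be >= 1")
        if self.n_dummy < 0:
            raise ValueError("n_dummy must be >= 0")

    # ---- derived quantities -------------------------------------------------

    @property
    def dwell(self) -> float:
        """Sample dwell time [s]."""
        return 1.0 / self.bandwidth

    @property
    def k_max(self) -> float:
        """Maximum sampled k-space radius [cycles/FOV]."""
        return self.readout_oversampling * self.nominal_matrix / 2.0

    @property
    def breath_hold(self) -> float:
        """Total acquisition duration including dummy pulses [s]."""
        return (self.n_spokes + self.n_dummy) * self.tr

    @property
    def spoke_times(self) -> np.ndarray:
        """Absolute excitation time of each stored spoke [s].

        The dummy-pulse period precedes the first stored spoke, so spoke i is
        excited at (n_dummy + i) * TR after the start of the sequence.
        """
        return (self.n_dummy + np.arange(self.n_spokes)) * self.tr

    @property
    def spoke_rate(self) -> float:
        """k0 sampling rate, one sample per TR [Hz]."""
        return 1.0 / self.tr

    def replace(self, **kw) -> "SequenceParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DecayModel:
    """Biexponential envelope of the dissolved-phase signal.

    D(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2).  The defaults halve the
    dissolved k0 signal by roughly 7 s, the window in which oscillation
    analysis is performed.
    """

    a1: float = 0.5
    tau1: float = 3.0
    a2: float = 0.5
    tau2: float = 40.0

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a1 * np.exp(-t / self.tau1) + self.a2 * np.exp(-t / self.tau2)


class PeriodicWaveform:
    """Zero-mean, unit-amplitude periodic waveform f(theta).

    ``f`` is normalized so that its peak-to-peak range is exactly 2; a voxel
    with fractional amplitude alpha then oscillates with peak-to-peak range
    alpha about its mean via 1 + (alpha/2) f(omega t - phi).

    ``harmonics()`` returns complex coefficients gamma_h with
    f(theta) = sum_h Re[gamma_h exp(i h theta)], used by the forward model to
    express the modulation as a small set of static volumes.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], name: str = "custom",
                 n_grid: int = 4096, max_harmonics: int = 24, tol: float = 1e-9):
        theta = 2 * np.pi * np.arange(n_grid) / n_grid
        raw = np.asarray(fn(theta), dtype=float)
        mean = raw.mean()
        half_pp = (raw.max() - raw.min()) / 2.0
        if half_pp <= 0:
            raise ValueError("waveform must be non-constant")
        self._fn = fn
        self._mean = mean
        self._half_pp = half_pp
        self.name = name
        norm = (raw - mean) / half_pp
        ft = np.fft.rfft(norm) / n_grid
        gam = 2.0 * ft[1:max_harmonics + 1]
        keep = np.abs(gam) > tol
        self.harmonic_index = np.nonzero(keep)[0] + 1
        self.harmonic_coeffs = gam[keep]

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return (np.asarray(self._fn(theta), dtype=float) - self._mean) / self._half_pp

    def harmonics(self):
        """(harmonic numbers h, complex coefficients gamma_h)."""
        return self.harmonic_index, self.harmonic_coeffs


def sine_waveform() -> PeriodicWaveform:
    """Pure sinusoid; single harmonic."""
    return PeriodicWaveform(np.sin, name="sine")


def systolic_waveform(sharpness: float = 2.0, skew: float = 0.7) -> PeriodicWaveform:
    """Asymmetric cardiac-like waveform: fast systolic rise, slow decay.

    A von-Mises bump whose phase is warped by skew*(1 - cos theta), which
    steepens the rising edge relative to the falling edge for skew > 0.
    """
    def fn(theta):
        warped = theta - skew * (1.0 - np.cos(theta))
        return np.exp(sharpness * (np.cos(warped) - 1.0))
    return PeriodicWaveform(fn, name="systolic")
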