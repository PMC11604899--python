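"""Whole-lung k0 oscillation analysis.

The center-of-k-space sample of every radial spoke gives a 66.7-Hz time
series of the whole-lung signal.  The membrane k0 decays with RF-induced
depolarization and T1 relaxation of the gas reservoir; the RBC k0 carries
the same decay plus a cardiogenic modulation.  The pipeline:

1. normalize the membrane k0 by its mean and fit a biexponential decay;
2. normalize the RBC k0 by its mean and divide by the membrane fit
   (decay correction);
3. band-pass 0.5-2.5 Hz (zero-phase) to isolate the oscillation;
4. detect alternating maxima/minima, excluding the first second of
   transient behaviour (and optionally a noisy tail);
5. alpha_k0 = 100 x (mean of detrended maxima - mean of detrended minima)
   inside the high-SNR window (~first 7 s), and the heart rate from the
   maxima spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "K0Series",
    "PeakSet",
    "OscillationsNotDetected",
    "detrend_rbc",
    "bandpass",
    "detect_extrema",
    "alpha_k0",
]


class OscillationsNotDetected(RuntimeError):
    """Raised when cardiac oscillations are indistinguishable from noise."""


def _biexp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _monoexp(t, a, tau):
    return a * np.exp(-t / tau)


@dataclass
class K0Series:
    """Per-spoke k0 magnitudes and their detrended/filtered versions."""

    rbc: np.ndarray          # raw RBC k0 magnitude per spoke
    membrane: np.ndarray     # raw membrane k0 magnitude per spoke
    time: np.ndarray         # [s], strictly increasing
    detrended: np.ndarray | None = None
    filtered: np.ndarray | None = None
    decay_params: tuple | None = None    # (a1, tau1, a2, tau2) or (a, tau)
    decay_model: str = "biexponential"
    fit_residual: float | None = None

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.rbc) == len(self.membrane) == n):
            raise ValueError("rbc, membrane and time must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def decay_fit(self, t) -> np.ndarray:
        """Evaluate the fitted (unit-mean-normalized) membrane decay at t."""
        if self.decay_params is None:
            raise ValueError("detrend_rbc has not been run")
        fn = _biexp if self.decay_model == "biexponential" else _monoexp
        return fn(np.asarray(t, dtype=float), *self.decay_params)


@dataclass
class PeakSet:
    """Detected extrema of the filtered k0 oscillation."""

    maxima: np.ndarray       # spoke indices
    minima: np.ndarray
    window: tuple            # analysis interval [s]
    heart_rate: float        # [bpm]
    n_per_cycle: int         # mean spokes between adjacent maxima, rounded

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


# ---------------------------------------------------------------------------


def detrend_rbc(rbc_k0, membrane_k0, time) -> K0Series:
    """Normalize and decay-correct the RBC k0 series.

    The membrane series is normalized by its mean and fit to
    a1 exp(-t/tau1) + a2 exp(-t/tau2); the RBC series is normalized by its
    mean and divided by the fit.  Falls back to a monoexponential with a
    warning if the biexponential fit does not converge.
    """
    rbc = np.abs(np.asarray(rbc_k0, dtype=float))
    mem = np.abs(np.asarray(membrane_k0, dtype=float))
    time = np.asarray(time, dtype=float)
    if len(rbc) < 100:
        raise ValueError("need at least 100 spokes for decay fitting")
    if np.any(rbc <= 0) or np.any(mem <= 0):
        raise ValueError("k0 magnitudes must be positive")
    t0 = time[0]
    ts = time - t0
    mem_n = mem / mem.mean()
    try:
        p, _ = curve_fit(_biexp, ts, mem_n, p0=(0.5, 2.0, 0.5, 15.0),
                         bounds=([0, 1e-3, 0, 1e-3], [np.inf] * 4), maxfev=10000)
        model = "biexponential"
    except RuntimeError:
        warnings.warn("biexponential decay fit failed; falling back to monoexponential",
                      stacklevel=2)
        p, _ = curve_fit(_monoexp, ts, mem_n, p0=(1.0, 10.0),
                         bounds=([0, 1e-3], [np.inf] * 2), maxfev=10000)
        model = "monoexponential"
    fn = _biexp if model == "biexponential" else _monoexp
    fit = fn(ts, *p)
    resid = float(np.sqrt(np.mean((mem_n - fit) ** 2)))
    detrended = (rbc / rbc.mean()) / fit
    series = K0Series(rbc=rbc, membrane=mem, time=time, detrended=detrended,
                      decay_params=tuple(p), decay_model=model, fit_residual=resid)
    # decay_fit must be evaluated at absolute times downstream
    series.decay_fit = lambda t: fn(np.asarray(t, dtype=float) - t0, *p)  # type: ignore
    return series


def bandpass(series, sample_rate: float, band=(0.5, 2.5), order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; peak positions of in-band tones are
    preserved (forward-backward filtering)."""
    lo, hi = band
    nyq = sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3g}) Hz")
    if sample_rate <= 5.0:
        raise ValueError("sample rate too low for the 0.5-2.5 Hz band")
    sos = butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(series, dtype=float))


def detect_extrema(
    filtered,
    time,
    exclude_head: float = 1.0,
    exclude_tail: float = 0.0,
    min_separation_s: float = 0.2,
    prominence_factor: float = 0.25,
) -> PeakSet:
    """Detect alternating maxima/minima of the filtered k0 oscillation.

    The first ``exclude_head`` seconds (transient behaviour) and optionally a
    noisy tail are excluded.  Peaks must be separated by at least
    ``min_separation_s`` (the 2.5-Hz band limit implies >= 0.2 s between
    extrema of the same kind) and exceed a prominence of
    ``prominence_factor`` x the in-window standard deviation.
    """
    x = np.asarray(filtered, dtype=float)
    time = np.asarray(time, dtype=float)
    dt = float(np.median(np.diff(time)))
    t_lo = time[0] + exclude_head
    t_hi = time[-1] - exclude_tail
    sel = (time >= t_lo) & (time <= t_hi)
    if sel.sum() < 10:
        raise OscillationsNotDetected("analysis window contains too few spokes")
    off = int(np.argmax(sel))
    xs = x[sel]
    prom = prominence_factor * xs.std()
    dist = max(1, int(round(min_separation_s / dt)))
    if prom <= 1e-9 * max(1.0, float(np.max(np.abs(xs)))):
        raise OscillationsNotDetected("flat series: oscillations indistinguishable from noise")
    maxima, _ = find_peaks(xs, distance=dist, prominence=prom)
    minima, _ = find_peaks(-xs, distance=dist, prominence=prom)
    # enforce alternation: between consecutive maxima keep the deepest minimum, etc.
    events = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    cleaned = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev = cleaned[-1][0]
            better = idx if (xs[idx] > xs[prev]) == (kind > 0) else prev
            cleaned[-1] = (better, kind)
        else:
            cleaned.append((idx, kind))
    maxima = np.array([i for i, k in cleaned if k > 0], dtype=int)
    minima = np.array([i for i, k in cleaned if k < 0], dtype=int)
    if len(maxima) < 3:
        raise OscillationsNotDetected(
            "fewer than 3 maxima: oscillations indistinguishable from noise")
    intervals = np.diff(time[sel][maxima])
    heart_rate = 60.0 / float(np.mean(intervals))
    n_per_cycle = int(round(float(np.mean(np.diff(maxima)))))
    return PeakSet(maxima=maxima + off, minima=minima + off, window=(t_lo, t_hi),
                   heart_rate=heart_rate, n_per_cycle=n_per_cycle)


def alpha_k0(series: K0Series, peaks: PeakSet, window: tuple | None = None) -> float:
    """Whole-lung peak-to-peak oscillation amplitude [%].

    alpha_k0 = 100 x (mean detrended value at maxima - mean at minima),
    using extrema inside ``window`` (default: start of the peak-analysis
    window to 7 s, the high-SNR part of the breath hold).
    """
    if series.detrended is None:
        raise ValueError("series has not been detrended")
    if window is None:
        window = (peaks.window[0], 7.0)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty alpha_k0 window")
    t = series.time
    mx = peaks.maxima[(t[peaks.maxima] >= lo) & (t[peaks.maxima] <= hi)]
    mn = peaks.minima[(t[peaks.minima] >= lo) & (t[peaks.minima] <= hi)]
    if len(mx) < 3 or len(mn) < 3:
        raise OscillationsNotDetected(
            "fewer than 3 extrema of each kind in the alpha_k0 window")
    return 100.0 * float(series.detrended[mx].mean() - series.detrended[mn].mean())
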