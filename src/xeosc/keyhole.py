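"""Two-Key and sliding-window keyhole assembly and oscillation maps.

A keyhole image combines the high-spatial-frequency data of *every* spoke
(readout points beyond the keyhole radius) with the low-frequency points of
a temporally selected subset of spokes (the "key").  The image then carries
the temporal weighting of the key:

* Two-Key: two keys hold the spokes adjacent to the k0 RBC maxima ("high")
  and minima ("low"); the amplitude map is the pixelwise difference of the
  two images divided by their mean, x100%.  A voxel oscillating out of phase
  with the whole-lung k0 signal yields a *negative* Two-Key amplitude.
* Sliding window (SW): key 1 equals the Two-Key high key; key j is key 1
  stepped forward by j-1 spokes; N keys sample one mean cardiac cycle.  Per
  voxel, the signal across keys S(j) is Gaussian-smoothed, and
  alpha_SW = 100 (S_max - S_min)/S_mean is phase-independent; the key index
  j_max of the maximum converts to the local phase lag
  phi = wrap(2 pi (j_max - 1)/N).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .k0 import PeakSet
from .phantom import wrap_phase

__all__ = [
    "KeySchedule",
    "KeyholeImageStack",
    "OscillationMaps",
    "bin_two_key",
    "sliding_window_keys",
    "assemble_keyhole",
    "two_key_map",
    "sw_maps",
    "gaussian_window_kernel",
]

log = logging.getLogger(__name__)


@dataclass
class KeySchedule:
    """Spoke-index sets selecting the key of each keyhole reconstruction."""

    keys: list                      # list of int arrays
    bin_fraction: float = 0.20
    keyhole_radius: int = 6
    n_per_cycle: int | None = None
    j_pi: int | None = None         # key approximately in antiphase with key 1

    @property
    def n_keys(self) -> int:
        return len(self.keys)


@dataclass
class KeyholeImageStack:
    """Magnitude keyhole volumes per key, with the smoothed per-voxel series."""

    images: np.ndarray              # (n_keys, nx, ny, nz)
    smoothed: np.ndarray | None = None
    mask: np.ndarray | None = None


@dataclass
class OscillationMaps:
    """Regional oscillation amplitude and phase maps with intermediates."""

    alpha_2key: np.ndarray | None = None   # percent; may be negative
    alpha_sw: np.ndarray | None = None     # percent; >= 0 in mask
    phi: np.ndarray | None = None          # rad, (-pi, pi]
    j_max: np.ndarray | None = None        # 1-based key index
    s_high: np.ndarray | None = None
    s_low: np.ndarray | None = None
    s_max: np.ndarray | None = None
    s_min: np.ndarray | None = None
    s_mean: np.ndarray | None = None
    mask: np.ndarray | None = None
    n_keys: int | None = None


# ---------------------------------------------------------------------------
# Key binning
# ---------------------------------------------------------------------------

def _bin_around(centers_list, n_spokes, quota):
    """Grow symmetric windows around each list of centers until each set holds
    ``quota`` spokes; sets never overlap (growth stops there, with a warning)."""
    sets = [set() for _ in centers_list]
    claimed = np.full(n_spokes, -1, dtype=int)

    def try_add(which, idx):
        if 0 <= idx < n_spokes and claimed[idx] < 0 and len(sets[which]) < quota:
            claimed[idx] = which
            sets[which].add(idx)
            return True
        return False

    blocked = False
    for radius in range(n_spokes):
        progress = False
        done = all(len(s) >= quota for s in sets)
        if done:
            break
        for which, centers in enumerate(centers_list):
            for c in centers:
                for idx in ((c,) if radius == 0 else (c - radius, c + radius)):
                    if 0 <= idx < n_spokes and claimed[idx] >= 0 and claimed[idx] != which:
                        blocked = True
                    if try_add(which, idx):
                        progress = True
        if not progress and not all(len(s) >= quota for s in sets):
            break
    if any(len(s) < quota for s in sets):
        warnings.warn(
            "key windows collided or ran out of spokes before reaching the "
            f"target bin size {quota}; keys shrunk to "
            f"{[len(s) for s in sets]}", stacklevel=3)
    return [np.array(sorted(s), dtype=int) for s in sets]


def bin_two_key(peaks: PeakSet, n_spokes: int, bin_fraction: float = 0.20,
                keyhole_radius: int = 6, quota: int | None = None) -> KeySchedule:
    """Bin the spokes adjacent to the k0 maxima/minima into high/low keys.

    Each key grows symmetric windows around its extrema until it holds
    round(bin_fraction x n_spokes) spokes (~20% of the projections); the two
    keys never overlap.
    """
    if len(peaks.maxima) == 0 or len(peaks.minima) == 0:
        raise ValueError("peak set is empty")
    if quota is None:
        quota = int(round(bin_fraction * n_spokes))
    high, low = _bin_around([peaks.maxima, peaks.minima], n_spokes, quota)
    return KeySchedule(keys=[high, low], bin_fraction=bin_fraction,
                       keyhole_radius=keyhole_radius, n_per_cycle=peaks.n_per_cycle)


def sliding_window_keys(peaks: PeakSet, n_spokes: int, bin_fraction: float = 0.20,
                        keyhole_radius: int = 6) -> KeySchedule:
    """Sliding-window key schedule: key 1 around the k0 maxima, stepped
    forward by one spoke per key, N = mean spokes per cardiac cycle keys."""
    if peaks.n_per_cycle is None or peaks.n_per_cycle < 4:
        raise ValueError("need at least 4 spokes per cardiac cycle")
    key1 = bin_two_key(peaks, n_spokes, bin_fraction).keys[0]
    N = int(peaks.n_per_cycle)
    keys = []
    truncated = 0
    for j in range(N):
        k = key1 + j
        kept = k[k < n_spokes]
        truncated += len(k) - len(kept)
        keys.append(kept)
    if truncated:
        log.info("sliding-window keys truncated %d spoke indices beyond the last spoke",
                 truncated)
    return KeySchedule(keys=keys, bin_fraction=bin_fraction,
                       keyhole_radius=keyhole_radius, n_per_cycle=N,
                       j_pi=int(np.floor(N / 2 + 0.5)) + 1)


# ---------------------------------------------------------------------------
# Keyhole assembly
# ---------------------------------------------------------------------------

def assemble_keyhole(samples: np.ndarray, key: np.ndarray, keyhole_radius: int = 6):
    """Assemble hybrid keyhole k-space from multi-echo (or separated) samples.

    Readout points with index >= ``keyhole_radius`` (the high-frequency
    keyhole, e.g. points 7-13 of 13 for radius 6) come from every spoke;
    points below the radius come from key spokes only.

    ``samples`` has spokes on the first axis and readout points on the last.
    Returns (hybrid_samples, spoke_idx, point_idx) where the index arrays
    locate each hybrid sample in the original (spoke, point) layout.
    """
    key = np.asarray(key, dtype=int)
    if key.size == 0:
        raise ValueError("empty key")
    n_spokes = samples.shape[0]
    n_pts = samples.shape[-1]
    if not (0 <= keyhole_radius < n_pts):
        raise ValueError("keyhole_radius must be < number of readout points")
    sp_hi, pt_hi = np.meshgrid(np.arange(n_spokes),
                               np.arange(keyhole_radius, n_pts), indexing="ij")
    sp_lo, pt_lo = np.meshgrid(key, np.arange(keyhole_radius), indexing="ij")
    spoke_idx = np.concatenate([sp_lo.ravel(), sp_hi.ravel()])
    point_idx = np.concatenate([pt_lo.ravel(), pt_hi.ravel()])
    hybrid = samples[spoke_idx, ..., point_idx]
    return hybrid, spoke_idx, point_idx


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def phase_to_delay_ms(phi, heart_rate_bpm: float) -> np.ndarray:
    """Convert an oscillation phase lag [rad] to a time delay [ms].

    delay = 1000 * phi / omega with omega = 2 pi * heart_rate / 60; at a
    typical 70 bpm the maximum lag of +-pi corresponds to roughly 400 ms.
    """
    omega = 2.0 * np.pi * heart_rate_bpm / 60.0
    return 1000.0 * np.asarray(phi, dtype=float) / omega


def two_key_map(s_high: np.ndarray, s_low: np.ndarray,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Two-Key amplitude map: 100 (S_high - S_low) / ((S_high + S_low)/2)."""
    s_high = np.abs(np.asarray(s_high, dtype=float))
    s_low = np.abs(np.asarray(s_low, dtype=float))
    if s_high.shape != s_low.shape:
        raise ValueError("S_high and S_low must be co-registered (same shape)")
    mean = (s_high + s_low) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (s_high - s_low) / mean
    out[mean == 0] = np.nan
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def gaussian_window_kernel(window: int = 10, sigma: float = 2.0) -> np.ndarray:
    """Centered Gaussian moving-average kernel of the given window length.

    An even-length window has a half-sample centroid shift; the kernel is the
    average of its two integer placements, which restores exact symmetry
    (odd tap count, same window weights) so the smoothed argmax carries no
    systematic half-key phase bias.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    k = np.arange(window)
    w = np.exp(-((k - (window - 1) / 2.0) ** 2) / (2.0 * sigma ** 2))
    w = w / w.sum()
    if window % 2 == 1:
        return w
    sym = np.zeros(window + 1)
    sym[:-1] += 0.5 * w
    sym[1:] += 0.5 * w
    return sym


def sw_maps(stack: KeyholeImageStack, schedule: KeySchedule,
            window: int = 10, sigma: float = 2.0,
            mask: np.ndarray | None = None, boundary: str = "wrap") -> OscillationMaps:
    """Sliding-window amplitude and phase maps from a keyhole image stack.

    Per voxel, the signal across keys is smoothed with a Gaussian-weighted
    moving average (window length 10), then
    alpha_SW = 100 (S_max - S_min)/S_mean and phi = wrap(2 pi (j_max - 1)/N);
    j_max ties break to the smallest key index.  The key axis spans one
    cardiac cycle, so the default smoothing boundary is circular.
    """
    imgs = np.abs(np.asarray(stack.images, dtype=float))
    N = imgs.shape[0]
    if N < 4:
        raise ValueError("need at least 4 keyhole images")
    kern = gaussian_window_kernel(window, sigma)
    sm = convolve1d(imgs, kern, axis=0, mode=boundary)
    stack.smoothed = sm
    s_mean = sm.mean(axis=0)
    s_max = sm.max(axis=0)
    s_min = sm.min(axis=0)
    j_max = np.argmax(sm, axis=0) + 1           # first occurrence = smallest j
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = 100.0 * (s_max - s_min) / s_mean
    alpha[~(s_mean > 0)] = np.nan
    phi = wrap_phase(2.0 * np.pi * (j_max - 1) / N)
    if mask is None:
        mask = stack.mask
    if mask is not None:
        alpha = np.where(mask, alpha, np.nan)
        phi = np.where(mask, phi, np.nan)
    return OscillationMaps(alpha_sw=alpha, phi=phi, j_max=j_max,
                           s_max=s_max, s_min=s_min, s_mean=s_mean,
                           mask=mask, n_keys=N)
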