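"""Digital lung phantom for RBC oscillation mapping.

A phantom is a set of per-voxel maps on a cubic grid: compartment densities
(gas, membrane, RBC), the peak-to-peak fractional RBC oscillation amplitude
alpha(r), and the oscillation phase lag phi(r) relative to the aggregate
whole-lung oscillation.  The RBC density at time t is

    rho_rbc(r) * (1 + alpha(r)/2 * f(omega t - phi(r))),

with f a zero-mean periodic waveform of unit amplitude (peak-to-peak 2) and
omega = 2 pi * heart_rate / 60.  Positive phi means the local oscillation
peaks later than a phi = 0 voxel.

Array axes are (x, y, z) = (left-right, posterior-anterior, inferior-superior)
with voxel coordinates spanning [-FOV/2, FOV/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence import DecayModel, PeriodicWaveform, sine_waveform

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "ellipsoid_mask",
    "sphere_mask",
    "slab_mask",
    "two_ellipsoid_lungs",
]


def wrap_phase(phi):
    """Wrap angles to (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = -((-phi + np.pi) % (2 * np.pi) - np.pi)
    return out


# ---------------------------------------------------------------------------
# Geometry helpers (voxel-index space)
# ---------------------------------------------------------------------------

def _grids(grid: int):
    return np.meshgrid(*(np.arange(grid),) * 3, indexing="ij")


def ellipsoid_mask(grid: int, center: Sequence[float], semiaxes: Sequence[float]) -> np.ndarray:
    x, y, z = _grids(grid)
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def sphere_mask(grid: int, center: Sequence[float], radius: float) -> np.ndarray:
    return ellipsoid_mask(grid, center, (radius,) * 3)


def slab_mask(grid: int, axis: int, lo: float, hi: float) -> np.ndarray:
    """Voxels with lo <= index[axis] < hi."""
    idx = _grids(grid)[axis]
    return (idx >= lo) & (idx < hi)


def two_ellipsoid_lungs(grid: int = 32) -> np.ndarray:
    """Default lung support: two ellipsoids left/right of the midline."""
    g = grid
    semi = (0.15 * g, 0.2 * g, 0.32 * g)
    left = ellipsoid_mask(g, (0.32 * g, 0.5 * g, 0.5 * g), semi)
    right = ellipsoid_mask(g, (0.68 * g, 0.5 * g, 0.5 * g), semi)
    return left | right


# ---------------------------------------------------------------------------
# PhantomSpec
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Ground-truth voxel maps of the digital lung phantom."""

    grid: int
    rho_gas: np.ndarray
    rho_m: np.ndarray
    rho_rbc: np.ndarray
    alpha_map: np.ndarray           # peak-to-peak fractional amplitude (0.20 = 20%)
    phi_map: np.ndarray             # phase lag [rad], wrapped to (-pi, pi]
    heart_rate: float = 70.0        # [bpm]
    waveform: PeriodicWaveform = field(default_factory=sine_waveform)
    decay: DecayModel = field(default_factory=DecayModel)

    def __post_init__(self):
        shape = (self.grid,) * 3
        for name in ("rho_gas", "rho_m", "rho_rbc", "alpha_map", "phi_map"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)
        if np.any(self.rho_gas < 0) or np.any(self.rho_m < 0) or np.any(self.rho_rbc < 0):
            raise ValueError("densities must be nonnegative")
        if np.any(self.alpha_map < 0):
            raise ValueError("alpha_map must be nonnegative")
        self.phi_map = wrap_phase(self.phi_map)

    @property
    def omega(self) -> float:
        """Angular heartbeat frequency [rad/s]."""
        return 2 * np.pi * self.heart_rate / 60.0

    @property
    def lung_mask(self) -> np.ndarray:
        return (self.rho_m > 0) | (self.rho_rbc > 0) | (self.rho_gas > 0)

    def voxel_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Voxel center coordinates in FOV fractions, shape (n, 3)."""
        if mask is None:
            mask = np.ones((self.grid,) * 3, bool)
        idx = np.argwhere(mask).astype(float)
        return (idx - self.grid / 2.0) / self.grid

    def global_phase(self) -> float:
        """Phase lag of the aggregate (whole-lung) RBC oscillation [rad].

        Amplitude-weighted circular mean of phi over the phantom; this is the
        phase reference that the k0-derived key schedule locks onto, so the
        mapped phase of a region with programmed lag phi is phi - global_phase.
        """
        w = self.rho_rbc * self.alpha_map / 2.0
        z = np.sum(w * np.exp(1j * self.phi_map))
        if np.abs(z) == 0:
            return 0.0
        return float(np.angle(z))


# ---------------------------------------------------------------------------
# make_phantom
# ---------------------------------------------------------------------------

def _fill_regions(grid, base, regions, lung, rng, what):
    """Paint (mask, value) regions onto `base`; conflicting overlaps error."""
    out = base.copy()
    owner = np.full((grid,) * 3, -1, dtype=int)
    for i, (region, value) in enumerate(regions):
        mask = np.asarray(region, dtype=bool)
        if mask.shape != out.shape:
            raise ValueError(f"{what} region {i} has shape {mask.shape}, expected {out.shape}")
        if not np.all(lung[mask]):
            raise ValueError(f"{what} region {i} extends outside the lung mask")
        if np.isscalar(value) or isinstance(value, (int, float)):
            vals = float(value)
        else:  # random field: ("uniform", lo, hi) or ("normal", mu, sd)
            dist, *args = value
            n = int(mask.sum())
            if dist == "uniform":
                vals = rng.uniform(args[0], args[1], size=n)
            elif dist == "normal":
                vals = rng.normal(args[0], args[1], size=n)
            else:
                raise ValueError(f"unknown distribution {dist!r}")
        clash = (owner[mask] >= 0)
        if np.any(clash):
            prev = out[mask][clash]
            new = np.broadcast_to(np.asarray(vals), prev.shape)[clash] if not np.isscalar(vals) \
                else np.full(prev.shape, vals)
            if np.any(prev != new):
                bad = np.argwhere(mask)[clash][:5]
                raise ValueError(
                    f"overlapping {what} regions with conflicting values at voxels "
                    f"{[tuple(v) for v in bad]}")
        out[mask] = vals
        owner[mask] = i
    return out


def make_phantom(
    grid: int = 32,
    lung_mask: np.ndarray | str | None = "two_ellipsoids",
    alpha_regions: Sequence | None = None,
    phi_regions: Sequence | None = None,
    heart_rate: float = 70.0,
    seed: int = 0,
    alpha_default: float = 0.20,
    phi_default: float = 0.0,
    rho: tuple = (0.05, 1.0, 0.4),
    waveform: PeriodicWaveform | None = None,
    decay: DecayModel | None = None,
) -> PhantomSpec:
    """Construct a phantom with piecewise (or randomly drawn) alpha/phi maps.

    ``alpha_regions`` / ``phi_regions`` are lists of (boolean mask, value)
    pairs; a value may also be ("uniform", lo, hi) or ("normal", mu, sd) to
    draw voxelwise random values with the given ``seed``.  Unlisted in-mask
    voxels take the defaults.  Densities default to membrane 1.0, RBC 0.4
    (the healthy-cohort RBC:M ratio ~0.41) and a small gas contamination.
    """
    if isinstance(lung_mask, str):
        if lung_mask != "two_ellipsoids":
            raise ValueError(f"unknown lung shape {lung_mask!r}")
        lung = two_ellipsoid_lungs(grid)
    elif lung_mask is None:
        lung = two_ellipsoid_lungs(grid)
    else:
        lung = np.asarray(lung_mask, dtype=bool)
        if lung.shape != (grid,) * 3:
            raise ValueError("lung_mask shape does not match grid")
    rng = np.random.default_rng(seed)

    if alpha_default < 0:
        raise ValueError("alpha_default must be nonnegative")
    for i, (_, val) in enumerate(alpha_regions or []):
        if np.isscalar(val) and val < 0:
            raise ValueError(f"alpha region {i} has negative amplitude")
    alpha = np.where(lung, float(alpha_default), 0.0)
    phi = np.where(lung, float(phi_default), 0.0)
    if alpha_regions:
        alpha = _fill_regions(grid, alpha, alpha_regions, lung, rng, "alpha")
    if phi_regions:
        phi = _fill_regions(grid, phi, phi_regions, lung, rng, "phi")
    # randomly drawn amplitudes may graze zero; clip rather than reject
    alpha = np.clip(alpha, 0.0, None)

    rho_gas = np.where(lung, rho[0], 0.0)
    rho_m = np.where(lung, rho[1], 0.0)
    rho_rbc = np.where(lung, rho[2], 0.0)
    return PhantomSpec(
        grid=grid, rho_gas=rho_gas, rho_m=rho_m, rho_rbc=rho_rbc,
        alpha_map=alpha, phi_map=wrap_phase(phi), heart_rate=heart_rate,
        waveform=waveform or sine_waveform(), decay=decay or DecayModel(),
    )
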