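"""Ready-made phantoms for validation studies.

These define the study conditions used by the test suite and the acceptance
script.  Two parameter-recovery phantoms separate the two questions the
method answers:

* ``amplitude_phantom`` — how well are regional oscillation *amplitudes*
  recovered?  Three amplitude bands (10/20/40%) in the left lung, everything
  in phase, plus an antiphase pocket (phi = pi) that reproduces the
  negative Two-Key amplitude pathology.
* ``phase_phantom`` — how well are regional *phases* recovered?  A monotone
  phase ladder (0, pi/4, pi/2) across the right lung, with the whole left
  lung acting as a lagging ballast whose phase is solved so the phantom's
  aggregate oscillation is exactly in phase with the phi = 0 band (the
  mapped phase is defined relative to the whole-lung k0 oscillation, so a
  zero net reference shift makes programmed and recovered phases directly
  comparable).
"""

from __future__ import annotations

import numpy as np

from .phantom import (PhantomSpec, ellipsoid_mask, make_phantom, sphere_mask,
                      two_ellipsoid_lungs)

__all__ = [
    "uniform_phantom",
    "zero_oscillation_phantom",
    "amplitude_phantom",
    "phase_phantom",
]


def uniform_phantom(grid: int = 32, alpha: float = 0.20, phi: float = 0.0,
                    heart_rate: float = 70.0, seed: int = 0, **kw) -> PhantomSpec:
    """Two-ellipsoid lungs with uniform oscillation amplitude and phase."""
    return make_phantom(grid=grid, alpha_default=alpha, phi_default=phi,
                        heart_rate=heart_rate, seed=seed, **kw)


def zero_oscillation_phantom(grid: int = 32, heart_rate: float = 70.0, **kw) -> PhantomSpec:
    """Lungs without any cardiogenic modulation (alpha = 0 everywhere)."""
    return make_phantom(grid=grid, alpha_default=0.0, heart_rate=heart_rate, **kw)


def _lungs_and_bands(grid: int):
    g = grid
    lung = two_ellipsoid_lungs(g)
    left = lung.copy()
    left[g // 2:, :, :] = False
    right = lung & ~left
    z = np.arange(g)[None, None, :] * np.ones((g, g, 1))
    bands = [(z < g * 12 / 32), (z >= g * 12 / 32) & (z < g * 20 / 32),
             (z >= g * 20 / 32)]
    return lung, left, right, bands


def amplitude_phantom(grid: int = 32, heart_rate: float = 70.0, seed: int = 0):
    """Amplitude-recovery phantom: alpha bands 10/20/40% plus antiphase pocket.

    All tissue oscillates in phase (phi = 0) except a spherical pocket in the
    right lung at phi = pi (alpha = 30%); the pocket contributes nothing to
    the imaginary part of the aggregate phasor, so the whole-lung reference
    phase stays exactly zero.  Returns (phantom, truth) with ``truth``
    mapping labels to (mask, alpha_true_percent, phi_true_rad).
    """
    g = grid
    lung, left, right, bands = _lungs_and_bands(g)
    pocket = sphere_mask(g, (0.68 * g, 0.5 * g, 0.5 * g), 0.1 * g) & right

    alpha_vals = (0.10, 0.20, 0.40)
    alpha_regions, phi_regions, truth = [], [], {}
    for i, band in enumerate(bands):
        lmask = left & band
        alpha_regions.append((lmask, alpha_vals[i]))
        truth[f"alpha_{int(alpha_vals[i] * 100)}"] = (lmask, 100 * alpha_vals[i], 0.0)
    alpha_regions += [(right & ~pocket, 0.20), (pocket, 0.30)]
    phi_regions = [(pocket, np.pi)]
    truth["antiphase"] = (pocket, 30.0, np.pi)

    phantom = make_phantom(grid=g, lung_mask=lung, alpha_regions=alpha_regions,
                           phi_regions=phi_regions, heart_rate=heart_rate,
                           seed=seed, phi_default=0.0)
    assert abs(phantom.global_phase()) < 1e-9
    return phantom, truth


def phase_phantom(phi: float, grid: int = 32, alpha: float = 0.20,
                  heart_rate: float = 70.0, seed: int = 0):
    """Mirror-pair phase-recovery phantom.

    The right lung (the evaluated region) oscillates with lag +phi at
    amplitude ``alpha``; the left lung acts as a lagging counterweight at
    twice the amplitude and lag -arcsin(sin(phi)/2), which zeroes the
    imaginary part of the aggregate phasor while keeping its real part
    positive for every phi in [0, pi/2].  The k0-derived phase reference
    therefore has exactly zero lag and the recovered right-lung phase can be
    compared to +phi directly.  Phase structure is kept at whole-lung scale
    because the keyhole's low-frequency undersampling mixes the phase of
    finer structures (see docs/methods.md).

    Returns (phantom, truth) with truth labels "target" (right lung, +phi)
    and "ballast" (left lung).
    """
    g = grid
    lung, left, right, _ = _lungs_and_bands(g)
    if np.cos(phi) >= 0.3:
        # equal-amplitude mirror: aggregate phasor 2 u cos(phi) stays robust
        alpha_left, phi_left = alpha, -phi
    else:
        # near-quadrature phases cancel in an equal mirror; use a stronger,
        # less-lagged counterweight instead
        alpha_left = 2 * alpha
        phi_left = -float(np.arcsin(np.sin(phi) * (alpha * right.sum())
                                    / (alpha_left * left.sum())))
    phantom = make_phantom(grid=g, lung_mask=lung,
                           alpha_regions=[(right, alpha), (left, alpha_left)],
                           phi_regions=[(right, phi), (left, phi_left)],
                           heart_rate=heart_rate, seed=seed)
    assert abs(phantom.global_phase()) < 1e-6
    truth = {"target": (right, 100 * alpha, phi),
             "ballast": (left, 100 * alpha_left, phi_left)}
    return phantom, truth
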