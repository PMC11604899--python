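"""3D radial trajectory, iterative density compensation, and Kaiser-Bessel
gridding reconstruction.

The trajectory is center-out 3D radial with golden-means spoke ordering by
default, so that any temporally contiguous subset of spokes (a keyhole key)
is angularly well dispersed.  Because keyhole subsets sample k-space
nonuniformly, per-sample density compensation weights are computed by the
fixed-point iteration

    w  <-  w / (w (*) C),

where C is the autoconvolution of the gridding kernel and (*) denotes
convolution evaluated at the sample locations.  Gridding follows the
standard recipe: density-weighted samples are convolved onto a 2x oversampled
Cartesian grid with a Kaiser-Bessel kernel (width 4 grid units, Beatty's
optimal beta), inverse FFT, deapodization by the kernel's Fourier transform,
and crop to the reconstruction matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree

from .sequence import SequenceParams

__all__ = [
    "Trajectory",
    "DensityWeights",
    "KaiserBesselKernel",
    "radial_trajectory",
    "compute_dcf",
    "DcfSystem",
    "Gridder",
    "grid_reconstruct",
]

log = logging.getLogger(__name__)

# 3D golden means (Chan et al.); successive spokes are maximally dispersed.
GOLDEN_MEANS = (0.4656010700877055, 0.6823278038280193)


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Center-out 3D radial sampling pattern in cycles/FOV units."""

    coords: np.ndarray      # (n_spokes, n_points, 3)
    spoke_dirs: np.ndarray  # (n_spokes, 3) unit vectors
    radii: np.ndarray       # (n_points,) |k| along each spoke

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    @property
    def points(self) -> np.ndarray:
        """All sample locations flattened to (n_spokes * n_points, 3)."""
        return self.coords.reshape(-1, 3)

    def flat_index(self, spoke_idx, point_idx) -> np.ndarray:
        return np.asarray(spoke_idx) * self.n_points + np.asarray(point_idx)


def _golden_stride(n: int) -> int:
    """Index stride closest to n/golden-ratio that is coprime with n."""
    target = int(round(n * 0.6180339887498949))
    for d in range(n):
        for cand in (target - d, target + d):
            if 1 <= cand < n and np.gcd(cand, n) == 1:
                return cand
    return 1


def _golden_dirs(n: int) -> np.ndarray:
    """Uniform spherical Fibonacci lattice traversed in golden-ratio stride order.

    The complete direction set is the (near-optimal) spherical Fibonacci
    lattice, so the fully sampled trajectory is angularly uniform; traversing
    it with a golden-ratio index stride makes every temporally contiguous run
    of spokes an equidistributed subsample, which is what keyhole keys need.
    """
    stride = _golden_stride(n)
    perm = (np.arange(n) * stride) % n
    return _archimedean_dirs(n)[perm]


def _archimedean_dirs(n: int) -> np.ndarray:
    i = np.arange(n)
    z = -1.0 + 2.0 * (i + 0.5) / n
    az = np.sqrt(np.pi * n) * np.arcsin(z)
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([s * np.cos(az), s * np.sin(az), z], axis=1)


def _random_dirs(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def radial_trajectory(seq: SequenceParams, ordering: str = "golden", seed: int = 0) -> Trajectory:
    """Generate the center-out 3D radial trajectory for one echo.

    All flyback echoes retrace the same spoke, so a single trajectory serves
    every echo.  ``ordering`` is one of 'golden' (default), 'archimedean',
    or 'random'.
    """
    if ordering in ("golden", "golden-means"):
        dirs = _golden_dirs(seq.n_spokes)
    elif ordering == "archimedean":
        dirs = _archimedean_dirs(seq.n_spokes)
    elif ordering == "random":
        dirs = _random_dirs(seq.n_spokes, seed)
    else:
        raise ValueError(f"unknown spoke ordering {ordering!r}")
    radii = np.linspace(0.0, seq.k_max, seq.n_samples_per_echo)
    coords = dirs[:, None, :] * radii[None, :, None]
    return Trajectory(coords=coords, spoke_dirs=dirs, radii=radii)


# ---------------------------------------------------------------------------
# Kaiser-Bessel kernel
# ---------------------------------------------------------------------------

def _beatty_beta(width: float, os: float) -> float:
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


@dataclass(frozen=True)
class KaiserBesselKernel:
    """Separable Kaiser-Bessel gridding kernel.

    ``width`` is the full kernel width in oversampled-grid units and ``os``
    the grid oversampling factor; ``beta`` defaults to Beatty's optimal value.
    """

    width: float = 4.0
    os: float = 2.0
    beta: float | None = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("kernel width must be > 0")
        if self.beta is None:
            object.__setattr__(self, "beta", _beatty_beta(self.width, self.os))

    def __call__(self, u) -> np.ndarray:
        """Kernel value at offset u in oversampled-grid units (|u| <= width/2)."""
        u = np.asarray(u, dtype=float)
        t = 1.0 - (2.0 * u / self.width) ** 2
        inside = t > 0
        out = np.zeros_like(u)
        out[inside] = np.i0(self.beta * np.sqrt(t[inside]))
        return out / np.i0(self.beta)

    @property
    def half_width_k(self) -> float:
        """Kernel half-width in cycles/FOV (Delta-k) units."""
        return self.width / 2.0 / self.os

    @cached_property
    def _autoconv(self):
        # 1D autoconvolution of the kernel, tabulated in Delta-k units.
        n = 2001
        u = np.linspace(-self.half_width_k, self.half_width_k, n)
        du = u[1] - u[0]
        k1 = self(u * self.os)
        ac = np.convolve(k1, k1) * du
        uu = np.linspace(-2 * self.half_width_k, 2 * self.half_width_k, 2 * n - 1)
        return interp1d(uu, ac, bounds_error=False, fill_value=0.0, assume_sorted=True)

    def autoconv(self, delta) -> np.ndarray:
        """1D kernel autoconvolution at separation delta [cycles/FOV]."""
        return self._autoconv(np.asarray(delta, dtype=float))

    def apodization(self, xi) -> np.ndarray:
        """Continuous Fourier transform of the 1D kernel at frequency xi.

        ``xi`` is in cycles per oversampled-grid unit; image voxel m of a
        G-cell grid sits at xi = (m - G/2) / G.
        """
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        n = 4001
        u = np.linspace(-self.width / 2, self.width / 2, n)
        k1 = self(u)
        ph = np.cos(2 * np.pi * u[None, :] * xi[:, None])
        return np.trapezoid(k1[None, :] * ph, u, axis=1)


# ---------------------------------------------------------------------------
# Density compensation (Pipe-Menon fixed point)
# ---------------------------------------------------------------------------

@dataclass
class DensityWeights:
    """Per-sample density compensation weights."""

    w: np.ndarray
    n_iter_used: int
    residual: float
    residual_history: np.ndarray

    @property
    def max_weight(self) -> float:
        return float(self.w.max())


class DcfSystem:
    """Kernel autoconvolution system C over a fixed set of sample points.

    C uses the radially symmetric autoconvolution profile of the gridding
    kernel, C(delta) = A(|delta|): density compensation must not depend on
    the orientation of a sampling pattern (a separable product kernel has a
    square footprint and breaks rotational symmetry).

    Exactly coincident points (every spoke passes through k = 0) are collapsed
    to a single node with a multiplicity, which keeps C compact; the physical
    per-sample weight is the node weight itself (coincident samples share the
    total weight equally).  ``subset`` extracts the system of any sample
    subset, reusing the assembled sparse matrix — keyhole trajectories are
    subsets of the full trajectory.
    """

    def __init__(self, points: np.ndarray, kernel: KaiserBesselKernel | None = None):
        self.kernel = kernel or KaiserBesselKernel()
        pts = np.ascontiguousarray(np.asarray(points, dtype=float))
        if pts.ndim != 2:
            raise ValueError("points must be (n, d)")
        uniq, inverse = np.unique(np.round(pts, 9), axis=0, return_inverse=True)
        self.unique_points = uniq
        self.inverse = inverse.ravel()
        self.n_points = pts.shape[0]
        support = 2.0 * self.kernel.half_width_k
        tree = cKDTree(uniq)
        pairs = tree.query_pairs(support, output_type="ndarray")
        i = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(len(uniq))])
        j = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(len(uniq))])
        d = np.linalg.norm(uniq[i] - uniq[j], axis=1)
        vals = np.asarray(self.kernel.autoconv(d))
        keep = vals > 0
        self.C = sp.csr_matrix((vals[keep], (i[keep], j[keep])),
                               shape=(len(uniq), len(uniq)))

    def subset(self, idx: np.ndarray | None = None):
        """(C_sub, multiplicity, inverse) restricted to sample indices idx."""
        if idx is None:
            inv = self.inverse
        else:
            inv = self.inverse[np.asarray(idx)]
        nodes, node_inv = np.unique(inv, return_inverse=True)
        mult = np.bincount(node_inv).astype(float)
        C_sub = self.C[nodes][:, nodes]
        return C_sub, mult, node_inv


def compute_dcf(
    points: np.ndarray | None = None,
    kernel: KaiserBesselKernel | None = None,
    max_iter: int = 25,
    tol: float = 0.05,
    system: DcfSystem | None = None,
    subset: np.ndarray | None = None,
) -> DensityWeights:
    """Iterative sample-density compensation weights.

    Either ``points`` (n, d) or a prebuilt ``system`` (optionally with a
    ``subset`` of its sample indices) must be given.  Iterates
    w <- w / (w (*) C) until max |(w (*) C) - 1| < tol at every sample or
    ``max_iter`` is reached; raises if the residual grows three iterations
    in a row.
    """
    if system is None:
        if points is None:
            raise ValueError("need points or a DcfSystem")
        system = DcfSystem(points, kernel=kernel)
    C, mult, node_inv = system.subset(subset)
    if C.shape[0] == 0:
        raise ValueError("empty point set")
    w = np.ones(C.shape[0])
    history = []
    grow = 0
    best = np.inf
    n_it = 0
    for n_it in range(1, max_iter + 1):
        conv = C @ (mult * w)
        resid = float(np.max(np.abs(conv - 1.0)))
        history.append(resid)
        # divergence: residual growing clear of the best value three times running
        # (the fixed point of undersampled geometries plateaus with a slow
        #  percent-level creep, which is not divergence)
        if resid > 1.5 * best:
            grow += 1
            if grow >= 3:
                raise RuntimeError(
                    f"density compensation diverging: residual {resid:.3g} after {n_it} iterations")
        else:
            grow = 0
        best = min(best, resid)
        if resid < tol:
            break
        w = w / conv
    weights = w[node_inv]
    return DensityWeights(w=weights, n_iter_used=n_it, residual=history[-1],
                          residual_history=np.asarray(history))


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------

class Gridder:
    """Kaiser-Bessel gridding reconstructor for a fixed set of sample points.

    Builds the sparse interpolation matrix once; ``reconstruct`` then grids
    any (subset of the) samples.  The grid is oversampled by ``kernel.os``
    relative to ``recon_matrix``.
    """

    def __init__(self, points: np.ndarray, seq: SequenceParams,
                 kernel: KaiserBesselKernel | None = None):
        self.kernel = kernel or KaiserBesselKernel()
        if self.kernel.os < 1.25:
            warnings.warn("grid oversampling < 1.25: aliasing risk", stacklevel=2)
        self.seq = seq
        self.matrix = seq.recon_matrix
        self.G = int(round(self.kernel.os * self.matrix))
        pts = np.asarray(points, dtype=float)
        self.n_points = pts.shape[0]
        g = pts * self.kernel.os + self.G / 2.0  # grid coordinates
        base = np.floor(g).astype(int)
        half = self.kernel.width / 2.0
        taps = int(np.ceil(self.kernel.width)) + 1
        offs = np.arange(taps) - taps // 2
        rows, cols, vals = [], [], []
        npts = pts.shape[0]
        for ox in offs:
            kx = self.kernel(base[:, 0] + ox - g[:, 0])
            for oy in offs:
                ky = self.kernel(base[:, 1] + oy - g[:, 1])
                kxy = kx * ky
                for oz in offs:
                    kz = self.kernel(base[:, 2] + oz - g[:, 2])
                    v = kxy * kz
                    nzi = np.nonzero(v)[0]
                    if nzi.size == 0:
                        continue
                    cell = (np.mod(base[nzi, 0] + ox, self.G) * self.G
                            + np.mod(base[nzi, 1] + oy, self.G)) * self.G \
                        + np.mod(base[nzi, 2] + oz, self.G)
                    rows.append(cell)
                    cols.append(nzi)
                    vals.append(v[nzi])
        self.A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.G ** 3, npts))
        xi = (np.arange(self.G) - self.G / 2) / self.G
        ap = self.kernel.apodization(xi)
        self._deapod3 = 1.0 / (ap[:, None, None] * ap[None, :, None] * ap[None, None, :])

    def reconstruct(self, samples: np.ndarray, weights: np.ndarray,
                    subset: np.ndarray | None = None) -> np.ndarray:
        """Grid density-weighted samples and return the complex image.

        ``samples``/``weights`` are per-point (optionally already restricted
        to ``subset`` of the points this Gridder was built on).
        """
        samples = np.asarray(samples)
        weights = np.asarray(weights)
        A = self.A if subset is None else self.A[:, np.asarray(subset)]
        grid = (A @ (weights * samples)).reshape((self.G,) * 3)
        img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid)))
        img = img * self._deapod3
        lo = (self.G - self.matrix) // 2
        hi = lo + self.matrix
        return img[lo:hi, lo:hi, lo:hi]


def grid_reconstruct(samples: np.ndarray, points: np.ndarray, dcf: DensityWeights,
                     seq: SequenceParams, kernel: KaiserBesselKernel | None = None) -> np.ndarray:
    """One-shot Kaiser-Bessel gridding reconstruction (complex image)."""
    samples = np.asarray(samples).ravel()
    if not (len(samples) == len(points) == len(dcf.w)):
        raise ValueError("samples, trajectory points and weights must align 1:1")
    return Gridder(points, seq, kernel=kernel).reconstruct(samples, dcf.w)
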