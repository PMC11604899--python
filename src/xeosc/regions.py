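"""Lung masking, eight-region partition, map summaries, SNR gating, and
scan-rescan repeatability metrics.

Array axes follow (x, y, z) = (left-right, posterior-anterior,
inferior-superior): left/right split along x, anterior/posterior along y,
upper/lower along z, and central/peripheral by erosion of the lung mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RegionSet",
    "RepeatabilityReport",
    "SnrDecision",
    "estimate_background_sigma",
    "make_mask",
    "snr_gate",
    "region_partition",
    "summarize_maps",
    "repeatability",
]

#: SD of a Rayleigh-distributed magnitude relative to the underlying complex
#: Gaussian sigma: sqrt((4 - pi)/2).
RAYLEIGH_SD_FACTOR = float(np.sqrt((4.0 - np.pi) / 2.0))

REGION_NAMES = ("left", "right", "upper", "lower", "anterior", "posterior",
                "central", "peripheral")


@dataclass
class RegionSet:
    """Eight regional lung masks partitioning the whole-lung mask."""

    left: np.ndarray
    right: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    central: np.ndarray
    peripheral: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def items(self):
        return [(n, getattr(self, n)) for n in REGION_NAMES]

    @property
    def lung(self) -> np.ndarray:
        return self.left | self.right


@dataclass
class RepeatabilityReport:
    """Scan-rescan agreement metrics."""

    bias: float                     # mean difference between two scans
    loa: tuple                      # bias +/- 1.96 SD of the differences
    pct_diff: float                 # mean absolute percentage difference
    cv3: float | None = None        # coefficient of variation across 3 scans


@dataclass
class SnrDecision:
    snr: float
    include: bool
    borderline: bool


# ---------------------------------------------------------------------------


def estimate_background_sigma(image: np.ndarray, mask: np.ndarray | None = None,
                              exclusion_dilate: int = 2) -> float:
    """Underlying complex-noise sigma from the background magnitude SD.

    Background voxels are those outside the (dilated) mask; the Rayleigh SD
    of a magnitude image is sqrt((4-pi)/2) x the complex-channel sigma.
    """
    mag = np.abs(np.asarray(image))
    if mask is None:
        bg = np.ones(mag.shape, bool)
        bg[3:-3, 3:-3, 3:-3] = False        # image border shell
    else:
        bg = ~ndimage.binary_dilation(mask, iterations=exclusion_dilate)
    if not np.any(bg):
        raise ValueError("no background voxels available")
    return float(mag[bg].std() / RAYLEIGH_SD_FACTOR)


def make_mask(membrane_image: np.ndarray, noise_sigma: float | None = None,
              k: float = 3.0, max_components: int = 2) -> np.ndarray:
    """Lung mask from a noise threshold on the membrane image.

    mask = |membrane| > k x sigma_noise, keeping the (up to) two largest
    connected components followed by a one-voxel morphological closing.
    With ``noise_sigma = 0`` (noiseless phantom) the mask is the exact
    nonzero support.
    """
    mag = np.abs(np.asarray(membrane_image))
    if noise_sigma is None:
        noise_sigma = estimate_background_sigma(mag)
    raw = mag > k * noise_sigma
    if not np.any(raw):
        raise ValueError("empty mask: no voxels above the noise threshold")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1][:max_components]
        # a genuine second lung is comparable in size; spurious blobs are not
        keep = [order[0] + 1] + [i + 1 for i in order[1:]
                                 if sizes[i] >= 0.1 * sizes[order[0]]]
        raw = np.isin(labels, keep)
    closed = ndimage.binary_closing(raw, iterations=1)
    return closed | raw


def snr_gate(rbc_image: np.ndarray, mask: np.ndarray,
             threshold: float = 4.5, borderline: float = 5.5) -> SnrDecision:
    """RBC image SNR and the inclusion decision.

    SNR = mean in-mask magnitude / Rayleigh-corrected background magnitude
    SD.  Subjects below the Rose-criterion threshold (4.5) are excluded;
    values in (4.5, 5.5] are flagged borderline (visual inspection advised).
    """
    sigma = estimate_background_sigma(rbc_image, mask=mask)
    mag = np.abs(np.asarray(rbc_image))
    if sigma == 0:
        snr = np.inf
    else:
        snr = float(mag[mask].mean() / sigma)
    include = snr > threshold
    return SnrDecision(snr=snr, include=include,
                       borderline=include and snr <= borderline)


def region_partition(mask: np.ndarray, erosion: int = 2) -> RegionSet:
    """Partition the lung mask into the eight standard regions.

    Left/right split at the sagittal gap between the lungs (fallback:
    bounding-box midline); upper/lower and anterior/posterior at the mask's
    extent midlines; central by erosion (depth ``erosion``), peripheral is
    the remainder.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    idx = np.argwhere(mask)
    x_lo, y_lo, z_lo = idx.min(axis=0)
    x_hi, y_hi, z_hi = idx.max(axis=0)

    # sagittal split: prefer an empty x-column gap near the middle third
    col_counts = mask.sum(axis=(1, 2))
    mid = (x_lo + x_hi + 1) / 2.0
    third = (x_hi - x_lo) / 3.0
    cols = np.arange(mask.shape[0])
    gap_cols = np.nonzero((col_counts == 0) & (np.abs(cols - mid) <= third / 2))[0]
    x_split = float(gap_cols[np.argmin(np.abs(gap_cols - mid))]) + 0.5 if gap_cols.size else mid

    xg, yg, zg = np.meshgrid(*(np.arange(s) for s in mask.shape), indexing="ij")
    left = mask & (xg < x_split)
    right = mask & ~left
    lower = mask & (zg < (z_lo + z_hi + 1) / 2.0)
    upper = mask & ~lower
    posterior = mask & (yg < (y_lo + y_hi + 1) / 2.0)
    anterior = mask & ~posterior

    depth = erosion
    central = ndimage.binary_erosion(mask, iterations=depth) if depth > 0 else mask.copy()
    while depth > 1 and not np.any(central):
        depth -= 1
        warnings.warn(f"mask too thin for erosion depth {erosion}; falling back to {depth}",
                      stacklevel=2)
        central = ndimage.binary_erosion(mask, iterations=depth)
    peripheral = mask & ~central
    return RegionSet(left=left, right=right, upper=upper, lower=lower,
                     anterior=anterior, posterior=posterior,
                     central=central, peripheral=peripheral,
                     provenance={"x_split": x_split, "erosion": depth})


# ---------------------------------------------------------------------------


def _masked(values, region):
    v = np.asarray(values, dtype=float)[region]
    return v[np.isfinite(v)]


def summarize_maps(maps, regions: RegionSet) -> pd.DataFrame:
    """Whole-lung and per-region summaries of the oscillation maps.

    The Two-Key amplitude is summarized by its mean (approximately normal);
    alpha_SW and phi are summarized by their medians (skewed distributions).
    The whole-lung row also reports each map's spatial coefficient of
    variation (SD/mean); for phi the CV is only meaningful while the phase
    distribution stays away from the wrap point (median |phi| < pi/2),
    otherwise it is set to NaN and flagged.
    """
    lung = regions.lung
    rows = {}
    region_masks = [("whole", lung)] + regions.items()
    for name, rmask in region_masks:
        row = {}
        if maps.alpha_2key is not None:
            row["alpha_2key_mean"] = float(np.mean(_masked(maps.alpha_2key, rmask)))
        if maps.alpha_sw is not None:
            row["alpha_sw_median"] = float(np.median(_masked(maps.alpha_sw, rmask)))
        if maps.phi is not None:
            row["phi_median"] = float(np.median(_masked(maps.phi, rmask)))
        rows[name] = row
    df = pd.DataFrame(rows).T
    cvs = {}
    for attr, col in (("alpha_2key", "cv_2key"), ("alpha_sw", "cv_sw"), ("phi", "cv_phi")):
        vals = getattr(maps, attr, None)
        if vals is None:
            continue
        v = _masked(vals, lung)
        if attr == "phi" and np.median(np.abs(v)) >= np.pi / 2:
            warnings.warn("phase distribution near the wrap point; CV of phi not meaningful",
                          stacklevel=2)
            cvs[col] = np.nan
            continue
        m = v.mean()
        cvs[col] = float(v.std() / m) if m != 0 else np.nan
    df.attrs["cv"] = cvs
    return df


def repeatability(values) -> RepeatabilityReport:
    """Scan-rescan repeatability of a per-scan summary value.

    ``values``: (n_subjects, n_scans) with 2 or 3 scans (a single subject's
    pair/triple is also accepted).  Bias and limits of agreement use
    scan1 - scan2; the percentage difference normalizes by the two-scan
    mean; the 3-scan CV is the per-subject SD/mean (sample SD), averaged.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 scans per subject")
    a, b = arr[:, 0], arr[:, 1]
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    denom = (a + b) / 2.0
    pct = float(np.mean(100.0 * np.abs(d) / denom))
    cv3 = None
    if arr.shape[1] >= 3:
        cv3 = float(np.mean(arr.std(axis=1, ddof=1) / arr.mean(axis=1)))
    return RepeatabilityReport(bias=bias, loa=loa, pct_diff=pct, cv3=cv3)
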