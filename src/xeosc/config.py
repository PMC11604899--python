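"""Validated run configuration with the published processing defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Processing parameters for the oscillation-mapping pipeline.

    Defaults follow the published protocol where one exists: key bins hold
    20% of the projections, keyhole radius 6 readout points, 0.5-2.5 Hz
    band-pass, Gaussian smoothing window 10 along the key axis, and an RBC
    SNR inclusion threshold of 4.5 (Rose criterion).
    """

    bin_fraction: float = 0.20
    keyhole_radius: int = 6
    band_lo: float = 0.5            # [Hz]
    band_hi: float = 2.5            # [Hz]
    smooth_window: int = 10
    smooth_sigma: float = 2.0
    smooth_boundary: str = "wrap"   # key axis spans one cardiac cycle
    dcf_max_iter: int = 25
    dcf_tol: float = 0.05
    erosion_depth: int = 2
    snr_threshold: float = 4.5
    snr_borderline: float = 5.5
    exclude_head: float = 1.0       # [s]
    exclude_tail: float = 0.0       # [s]
    alpha_window_end: float = 7.0   # [s]
    mask_threshold_k: float = 3.0
    ordering: str = "golden"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.bin_fraction < 1:
            raise ValueError("bin_fraction must be in (0, 1)")
        if self.keyhole_radius < 0:
            raise ValueError("keyhole_radius must be >= 0")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("invalid band-pass range")
        if self.smooth_window < 1 or self.smooth_sigma <= 0:
            raise ValueError("invalid smoothing parameters")
        if self.dcf_max_iter < 1 or self.dcf_tol <= 0:
            raise ValueError("invalid DCF settings")

    @property
    def band(self) -> tuple:
        return (self.band_lo, self.band_hi)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
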