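"""Instrument-level constants: the acquisition grid and ATR optics.

ATR-FTIR spectrometers record absorbance on a regular wavenumber grid,
conventionally reported from high to low wavenumber.  The optical
resolution (set by the interferometer) is coarser than the data spacing
(set by zero-filling), so both are carried as metadata.

The single piece of physics kept here is the penetration depth of the
evanescent wave at the internal-reflection-element (IRE) / sample
interface, which sets how deep into the dried serum film the beam probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EvanescenceError


@dataclass(frozen=True)
class AcquisitionSettings:
    """Spectrometer acquisition parameters.

    Parameters
    ----------
    wavenumber_start, wavenumber_end : float
        Grid endpoints in cm⁻¹; ``start > end`` (descending convention).
    spacing : float
        Data spacing in cm⁻¹ between adjacent grid points.
    resolution : float
        Optical resolution in cm⁻¹; must be ≥ ``spacing``.
    coadded_scans : int
        Number of co-added interferometer scans (metadata only).
    """

    wavenumber_start: float = 4000.0
    wavenumber_end: float = 950.0
    spacing: float = 1.0
    resolution: float = 4.0
    coadded_scans: int = 16

    def __post_init__(self) -> None:
        if not self.wavenumber_start > self.wavenumber_end:
            raise ConfigurationError(
                "wavenumber_start must exceed wavenumber_end "
                f"(got {self.wavenumber_start} ≤ {self.wavenumber_end})"
            )
        if not self.spacing > 0:
            raise ConfigurationError(f"spacing must be positive (got {self.spacing})")
        if self.resolution < self.spacing:
            raise ConfigurationError(
                f"resolution ({self.resolution}) must be ≥ spacing ({self.spacing})"
            )
        if self.coadded_scans < 1:
            raise ConfigurationError(
                f"coadded_scans must be ≥ 1 (got {self.coadded_scans})"
            )

    @property
    def n_points(self) -> int:
        span = self.wavenumber_start - self.wavenumber_end
        return int(math.floor(span / self.spacing)) + 1

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid in cm⁻¹."""
        return float(self.wavenumber_start) - float(self.spacing) * np.arange(
            self.n_points, dtype=float
        )


@dataclass(frozen=True)
class OpticsParams:
    """ATR optics: wavelength (µm), IRE index n₁, sample index n₂, incidence angle (°)."""

    wavelength_um: float
    n_ire: float
    n_sample: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.n_ire > self.n_sample > 0):
            raise ConfigurationError(
                f"require n_ire > n_sample > 0 (got n_ire={self.n_ire}, n_sample={self.n_sample})"
            )
        if self.wavelength_um <= 0:
            raise ConfigurationError(
                f"wavelength_um must be positive (got {self.wavelength_um})"
            )
        sin2 = math.sin(math.radians(self.angle_deg)) ** 2
        if sin2 <= (self.n_sample / self.n_ire) ** 2:
            raise EvanescenceError(
                "total internal reflection requires sin²θ > (n₂/n₁)²: "
                f"sin²({self.angle_deg}°)={sin2:.4f} ≤ {(self.n_sample / self.n_ire) ** 2:.4f}"
            )


def penetration_depth(p: OpticsParams) -> float:
    """Evanescent-wave penetration depth in µm.

    d_p = λ / (2π · n₁ · sqrt(sin²θ − (n₂/n₁)²))

    Strictly decreasing in both n₁ and θ over the valid domain, and linear
    in λ: a silicon IRE (n₁ ≈ 3.42) probes a shallower layer than diamond
    (n₁ ≈ 2.40) at the same geometry.
    """
    sin2 = math.sin(math.radians(p.angle_deg)) ** 2
    root = math.sqrt(sin2 - (p.n_sample / p.n_ire) ** 2)
    return p.wavelength_um / (2.0 * math.pi * p.n_ire * root)
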