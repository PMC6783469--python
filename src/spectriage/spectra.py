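"""In-memory containers for absorbance spectra.

A :class:`Spectrum` is one absorbance trace on a strictly monotone
wavenumber grid, tagged with the identity of the measurement: which
patient, which well of the four-well sample slide (three sample wells
plus one background well), and which replicate acquisition.  A
:class:`SpectraCollection` groups spectra by patient on one shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import UsageError
from .instrument import AcquisitionSettings

BACKGROUND_WELL = "background"
SAMPLE_ROLE = "sample"
BACKGROUND_ROLE = "background"


@dataclass
class Spectrum:
    """One absorbance trace with measurement identity.

    ``well`` is "1", "2" or "3" for sample wells, or "background";
    ``role`` is "sample" or "background" and must agree with the well.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    patient_id: str = "unknown"
    well: str = "1"
    replicate: int = 1
    role: str = SAMPLE_ROLE
    acquisition: AcquisitionSettings | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise UsageError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.shape != self.absorbance.shape:
            raise UsageError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.absorbance)
        ):
            raise UsageError("spectrum contains non-finite values")
        diffs = np.diff(self.wavenumbers)
        if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise UsageError("wavenumber grid must be strictly monotone")
        if self.role not in (SAMPLE_ROLE, BACKGROUND_ROLE):
            raise UsageError(f"unknown role {self.role!r}")
        if (self.role == BACKGROUND_ROLE) != (self.well == BACKGROUND_WELL):
            raise UsageError(
                f"role {self.role!r} inconsistent with well {self.well!r}"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def descending(self) -> bool:
        return self.wavenumbers.size < 2 or self.wavenumbers[0] > self.wavenumbers[-1]

    def with_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        """Copy with new absorbance values on the same grid."""
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))

    def with_grid(self, wavenumbers: np.ndarray, absorbance: np.ndarray) -> "Spectrum":
        """Copy with a new grid (used by crop / bin operations)."""
        return replace(
            self,
            wavenumbers=np.asarray(wavenumbers, dtype=float),
            absorbance=np.asarray(absorbance, dtype=float),
        )

    def value_at(self, wavenumber: float) -> float:
        """Absorbance at the grid point nearest ``wavenumber``."""
        idx = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        return float(self.absorbance[idx])

    @property
    def column_key(self) -> str:
        return f"{self.patient_id}_{self.well}_{self.replicate}"


@dataclass
class SpectraCollection:
    """Spectra grouped by patient, all sharing one wavenumber grid."""

    spectra: dict[str, list[Spectrum]] = field(default_factory=dict)

    def add(self, spectrum: Spectrum) -> None:
        grid = self.grid
        if grid is not None and not np.array_equal(grid, spectrum.wavenumbers):
            raise UsageError(
                f"spectrum for patient {spectrum.patient_id!r} is on a different grid"
            )
        self.spectra.setdefault(spectrum.patient_id, []).append(spectrum)

    @property
    def grid(self) -> np.ndarray | None:
        for specs in self.spectra.values():
            if specs:
                return specs[0].wavenumbers
        return None

    @property
    def patient_ids(self) -> list[str]:
        return list(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        for specs in self.spectra.values():
            yield from specs

    def __len__(self) -> int:
        return sum(len(s) for s in self.spectra.values())

    def sample_spectra(self) -> Iterator[Spectrum]:
        return (s for s in self if s.role == SAMPLE_ROLE)

    def background_spectra(self) -> Iterator[Spectrum]:
        return (s for s in self if s.role == BACKGROUND_ROLE)

    def n_sample_spectra(self, patient_id: str) -> int:
        return sum(1 for s in self.spectra.get(patient_id, []) if s.role == SAMPLE_ROLE)
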