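"""Hierarchical simulator for serum-like ATR-FTIR spectra.

Real study data of this kind (dried serum films measured through a
silicon IRE) are rarely deposited, so the simulator provides cohorts
with the statistical structure the downstream analysis assumes:

* each patient contributes 3 wells × 3 replicate acquisitions = 9
  sample spectra, plus one background spectrum per slide;
* absorbance is a sum of Gaussian bands at the canonical serum
  positions (amide A/I/II/III, CH stretches, carbohydrate C–O), with
  class-dependent multiplicative effects on selected bands for cancer
  patients — by default a perturbed amide II and 1080 cm⁻¹ band, which
  shifts the amide I/II ratio;
* nested variance components: a lognormal per-patient amplitude effect,
  a lognormal per-well effect, and additive white replicate noise;
* a smooth random polynomial baseline and an optional broad Gaussian
  near 1100 cm⁻¹ emulating the silicon lattice contribution.

Seeding is hierarchical: every stream is derived deterministically from
``(seed, patient index, well, replicate)`` via ``numpy`` seed
sequences, so cohorts are bit-reproducible and individual spectra can
be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CANCER, NON_CANCER, MANIFEST_COLUMNS, CohortManifest
from .errors import ConfigurationError, DesignError
from .instrument import AcquisitionSettings
from .spectra import (
    BACKGROUND_ROLE,
    BACKGROUND_WELL,
    SAMPLE_ROLE,
    SpectraCollection,
    Spectrum,
)

import pandas as pd

SI_BAND_CENTER = 1100.0  # cm⁻¹, silicon lattice contribution
SI_BAND_WIDTH = 60.0  # cm⁻¹ (Gaussian σ)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_effect`` multiplies the amplitude for cancer patients
    (1.0 = no disease effect on this band).
    """

    center: float
    width: float
    base_amplitude: float
    class_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"width must be positive (got {self.width})")
        if self.base_amplitude < 0:
            raise ConfigurationError(
                f"base_amplitude must be ≥ 0 (got {self.base_amplitude})"
            )
        if self.class_effect <= 0:
            raise ConfigurationError(
                f"class_effect must be positive (got {self.class_effect})"
            )


def default_band_table() -> list[BandSpec]:
    """Canonical serum band table with the default cancer effects.

    Amplitudes are in absorbance units at typical dried-serum film
    scale; cancer multiplies amide II by 1.10 and the 1080 cm⁻¹
    carbohydrate band by 1.15.
    """
    return [
        BandSpec(center=3300.0, width=80.0, base_amplitude=0.25),  # amide A (N–H)
        BandSpec(center=2960.0, width=15.0, base_amplitude=0.08),  # CH₃ asym stretch
        BandSpec(center=2873.0, width=15.0, base_amplitude=0.05),  # CH₂ sym stretch
        BandSpec(center=1655.0, width=25.0, base_amplitude=0.40),  # amide I
        BandSpec(center=1545.0, width=25.0, base_amplitude=0.25, class_effect=1.10),  # amide II
        BandSpec(center=1240.0, width=30.0, base_amplitude=0.08),  # amide III
        BandSpec(center=1080.0, width=30.0, base_amplitude=0.10, class_effect=1.15),  # C–O
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the spectral simulator.

    Parameters
    ----------
    acquisition : AcquisitionSettings
        Grid and instrument metadata (default 4000→950 cm⁻¹, 1 cm⁻¹
        spacing, 4 cm⁻¹ resolution, 16 scans).
    bands : list of BandSpec
        Gaussian band table; defaults to :func:`default_band_table`.
    sigma_patient, sigma_well : float
        Lognormal scales of the per-patient and per-well multiplicative
        amplitude effects.
    sigma_noise : float
        Additive white-noise standard deviation (absorbance units) per
        replicate acquisition.
    baseline_order : int
        Degree of the random polynomial baseline.
    baseline_scale : float
        Standard deviation of each polynomial coefficient (evaluated on
        a wavenumber axis rescaled to [−1, 1]).
    si_band_amplitude : float
        Amplitude of the broad silicon-lattice Gaussian near
        1100 cm⁻¹; 0 disables it.
    n_wells_per_patient, n_spectra_per_well : int
        Replicate structure (3 × 3 = 9 spectra per patient by default).
    seed : int
        Base seed for the hierarchical random streams.
    """

    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    bands: list[BandSpec] = field(default_factory=default_band_table)
    sigma_patient: float = 0.05
    sigma_well: float = 0.02
    sigma_noise: float = 0.005
    baseline_order: int = 2
    baseline_scale: float = 0.01
    si_band_amplitude: float = 0.02
    n_wells_per_patient: int = 3
    n_spectra_per_well: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_patient", "sigma_well", "sigma_noise", "baseline_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(
                    f"{name} must be ≥ 0 (got {getattr(self, name)})"
                )
        if self.si_band_amplitude < 0:
            raise ConfigurationError(
                f"si_band_amplitude must be ≥ 0 (got {self.si_band_amplitude})"
            )
        if self.baseline_order < 0:
            raise ConfigurationError(
                f"baseline_order must be ≥ 0 (got {self.baseline_order})"
            )
        if self.n_wells_per_patient < 1 or self.n_spectra_per_well < 1:
            raise ConfigurationError(
                "n_wells_per_patient and n_spectra_per_well must be ≥ 1 "
                f"(got {self.n_wells_per_patient}, {self.n_spectra_per_well})"
            )

    @property
    def spectra_per_patient(self) -> int:
        return self.n_wells_per_patient * self.n_spectra_per_well


@dataclass(frozen=True)
class CohortDesignSpec:
    """Cohort composition for :func:`simulate_cohort`.

    ``tumour_type_counts`` optionally assigns tumour types to the
    cancer patients; when given, its counts must sum to ``n_cancer``.
    """

    n_cancer: int
    n_control: int
    tumour_type_counts: dict[str, int] | None = None
    age_range_cancer: tuple[int, int] = (21, 96)
    age_range_control: tuple[int, int] = (19, 69)
    male_fraction: float = 0.55
    allow_empty_class: bool = False
    cohort_name: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_control < 0:
            raise ConfigurationError("patient counts must be ≥ 0")
        if not self.allow_empty_class and (self.n_cancer == 0 or self.n_control == 0):
            raise DesignError(
                "a class with zero patients requires allow_empty_class=True "
                f"(n_cancer={self.n_cancer}, n_control={self.n_control})"
            )
        if self.tumour_type_counts is not None:
            total = sum(self.tumour_type_counts.values())
            if total != self.n_cancer:
                raise ConfigurationError(
                    f"tumour_type_counts sum to {total}, expected n_cancer={self.n_cancer}"
                )


def _gaussian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((grid - center) ** 2) / (2.0 * width**2))


def _baseline(
    grid: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random smooth baseline: polynomial drift plus the Si lattice band."""
    base = np.zeros_like(grid)
    if config.baseline_scale > 0:
        lo, hi = grid.min(), grid.max()
        u = 2.0 * (grid - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros_like(grid)
        coeffs = rng.normal(0.0, config.baseline_scale, size=config.baseline_order + 1)
        base = base + np.polynomial.polynomial.polyval(u, coeffs)
    else:
        # keep the stream advanced identically whether or not drift is on
        rng.normal(0.0, 1.0, size=config.baseline_order + 1)
    if config.si_band_amplitude > 0:
        base = base + config.si_band_amplitude * _gaussian(
            grid, SI_BAND_CENTER, SI_BAND_WIDTH
        )
    return base


def simulate_spectrum(
    config: SimulationConfig,
    patient_label: str,
    patient_effect: float = 1.0,
    well_effect: float = 1.0,
    rng: np.random.Generator | None = None,
    *,
    patient_id: str = "sim",
    well: str = "1",
    replicate: int = 1,
) -> Spectrum:
    """Draw one sample spectrum from the generative model.

    absorbance(ν) = Σ_b A_b · e_b^[cancer] · patient_effect · well_effect
                    · exp(−(ν − c_b)² / 2σ_b²) + baseline(ν) + noise(ν)

    where e_b is the band's ``class_effect`` (applied only when
    ``patient_label == "cancer"``).
    """
    if patient_label not in (CANCER, NON_CANCER):
        raise ConfigurationError(
            f"patient_label must be {CANCER!r} or {NON_CANCER!r} (got {patient_label!r})"
        )
    if patient_effect <= 0 or well_effect <= 0:
        raise ConfigurationError("patient_effect and well_effect must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grid = config.acquisition.grid()
    signal = np.zeros_like(grid)
    is_cancer = patient_label == CANCER
    for band in config.bands:
        amp = band.base_amplitude * (band.class_effect if is_cancer else 1.0)
        signal += amp * _gaussian(grid, band.center, band.width)
    signal *= patient_effect * well_effect
    signal += _baseline(grid, config, rng)
    if config.sigma_noise > 0:
        signal = signal + rng.normal(0.0, config.sigma_noise, size=grid.size)
    return Spectrum(
        wavenumbers=grid,
        absorbance=signal,
        patient_id=patient_id,
        well=well,
        replicate=replicate,
        role=SAMPLE_ROLE,
        acquisition=config.acquisition,
    )


def _background_spectrum(
    config: SimulationConfig, rng: np.random.Generator, patient_id: str
) -> Spectrum:
    grid = config.acquisition.grid()
    signal = _baseline(grid, config, rng)
    if config.sigma_noise > 0:
        signal = signal + rng.normal(0.0, config.sigma_noise, size=grid.size)
    return Spectrum(
        wavenumbers=grid,
        absorbance=signal,
        patient_id=patient_id,
        well=BACKGROUND_WELL,
        replicate=1,
        role=BACKGROUND_ROLE,
        acquisition=config.acquisition,
    )


def _rng_for(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, *key)))


def simulate_cohort(
    config: SimulationConfig, design: CohortDesignSpec
) -> tuple[CohortManifest, SpectraCollection]:
    """Generate a full cohort: manifest plus all sample/background spectra.

    Each patient receives ``n_wells_per_patient × n_spectra_per_well``
    sample spectra and one background spectrum (one slide per patient).
    Two runs with the same config are bit-identical; changing only the
    seed changes the spectra but not the cohort structure.
    """
    tumour_types: list[tuple[str, str]] = []
    if design.tumour_type_counts is not None:
        for ttype, count in design.tumour_type_counts.items():
            tumour_types.extend([(ttype, "")] * count)
    else:
        tumour_types = [("Simulated tumour", "")] * design.n_cancer

    rows: list[dict] = []
    collection = SpectraCollection()
    # demographics live on their own stream so spectra are unaffected by them
    demo_rng = _rng_for(config, 999_983)
    labels = [CANCER] * design.n_cancer + [NON_CANCER] * design.n_control
    for patient_idx, label in enumerate(labels):
        patient_id = f"S{patient_idx + 1:04d}"
        is_cancer = label == CANCER
        ttype, grade = tumour_types[patient_idx] if is_cancer else ("", "")
        lo, hi = design.age_range_cancer if is_cancer else design.age_range_control
        age = int(demo_rng.integers(lo, hi + 1))
        sex = "M" if demo_rng.random() < design.male_fraction else "F"
        rows.append(
            {
                "patient_id": patient_id,
                "cohort": design.cohort_name,
                "label": label,
                "tumour_type": ttype,
                "who_grade": grade,
                "age": age,
                "sex": sex,
            }
        )
        patient_rng = _rng_for(config, patient_idx)
        patient_effect = float(np.exp(patient_rng.normal(0.0, config.sigma_patient)))
        for well_idx in range(1, config.n_wells_per_patient + 1):
            well_rng = _rng_for(config, patient_idx, well_idx)
            well_effect = float(np.exp(well_rng.normal(0.0, config.sigma_well)))
            for rep in range(1, config.n_spectra_per_well + 1):
                spec_rng = _rng_for(config, patient_idx, well_idx, rep)
                collection.add(
                    simulate_spectrum(
                        config,
                        label,
                        patient_effect,
                        well_effect,
                        spec_rng,
                        patient_id=patient_id,
                        well=str(well_idx),
                        replicate=rep,
                    )
                )
        bg_rng = _rng_for(config, patient_idx, config.n_wells_per_patient + 1, 0)
        collection.add(_background_spectrum(config, bg_rng, patient_id))
    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    return manifest, collection
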