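"""Spectral quality control and pre-processing.

The chain that turns a raw absorbance trace into a classifier-ready
feature vector runs, in this fixed order:

    crop → baseline correction → normalization → data reduction

Defaults: crop to the 1800–1000 cm⁻¹ fingerprint region, rubber-band
(convex hull) baseline correction, vector (L2) normalization, and
mean-binning by a factor of 4 — matching a 4 cm⁻¹ optical resolution
sampled on a 1 cm⁻¹ grid.  On the default acquisition the fingerprint
crop holds 801 points; the final odd point is truncated before binning,
giving 200 features per spectrum.

Every step is deterministic and strictly per-spectrum: no statistic is
pooled across patients, so preprocessing cannot leak information
between training and test portions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortManifest
from .errors import DegenerateInputError, UsageError
from .spectra import BACKGROUND_ROLE, SAMPLE_ROLE, SpectraCollection, Spectrum

AMIDE_I_WINDOW = (1620.0, 1680.0)  # cm⁻¹ search window for the amide I maximum
RMS_NOISE_WINDOW = (2000.0, 2200.0)  # cm⁻¹, biologically quiet region


@dataclass(frozen=True)
class QCRule:
    """Acceptance interval for one background-quality metric."""

    metric: str  # rms_noise_2200_2000 | integrated_absorbance | max_absorbance
    min: float = -np.inf
    max: float = np.inf

    _METRICS = ("rms_noise_2200_2000", "integrated_absorbance", "max_absorbance")

    def __post_init__(self) -> None:
        if self.metric not in self._METRICS:
            raise UsageError(
                f"unknown QC metric {self.metric!r}; choose from {self._METRICS}"
            )
        if self.min > self.max:
            raise UsageError(f"QC rule {self.metric}: min {self.min} > max {self.max}")


@dataclass
class QCVerdict:
    passed: bool
    values: dict[str, float]
    failures: list[str]


def _window(spectrum: Spectrum, lo: float, hi: float) -> np.ndarray:
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    return spectrum.absorbance[mask]


def _qc_metric(spectrum: Spectrum, metric: str) -> float:
    if metric == "rms_noise_2200_2000":
        window = _window(spectrum, *RMS_NOISE_WINDOW)
        if window.size < 2:
            raise UsageError("spectrum does not cover the 2200–2000 cm⁻¹ noise window")
        return float(np.sqrt(np.mean((window - window.mean()) ** 2)))
    if metric == "integrated_absorbance":
        order = np.argsort(spectrum.wavenumbers)
        return float(
            np.trapezoid(spectrum.absorbance[order], spectrum.wavenumbers[order])
        )
    if metric == "max_absorbance":
        return float(np.max(spectrum.absorbance))
    raise UsageError(f"unknown QC metric {metric!r}")


def qc_background(spectrum: Spectrum, rules: list[QCRule]) -> QCVerdict:
    """Evaluate a background spectrum against acceptance rules.

    The verdict records every metric value; it fails iff any metric
    falls outside its [min, max] interval.
    """
    if spectrum.role != BACKGROUND_ROLE:
        raise UsageError(
            f"qc_background expects a background spectrum (got role {spectrum.role!r})"
        )
    values: dict[str, float] = {}
    failures: list[str] = []
    for rule in rules:
        value = _qc_metric(spectrum, rule.metric)
        values[rule.metric] = value
        if not (rule.min <= value <= rule.max):
            failures.append(rule.metric)
    return QCVerdict(passed=not failures, values=values, failures=failures)


def _lower_convex_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (Andrew monotone chain).

    ``x`` must be strictly increasing.
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j→i
            if (y[k] - y[j]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[k] - x[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubber_band_baseline(spectrum: Spectrum) -> Spectrum:
    """Rubber-band (lower convex hull) baseline correction.

    The baseline is the lower convex hull of the (ν, A) points,
    linearly interpolated between hull vertices; the corrected spectrum
    is the original minus this baseline.  The result is non-negative,
    touches zero at every hull vertex (at least the two endpoints), and
    the operation is idempotent.
    """
    if len(spectrum) < 3:
        raise UsageError("rubber-band baseline requires at least 3 points")
    order = np.argsort(spectrum.wavenumbers)
    x, y = spectrum.wavenumbers[order], spectrum.absorbance[order]
    hull = _lower_convex_hull(x, y)
    baseline_asc = np.interp(x, x[hull], y[hull])
    corrected_asc = np.maximum(y - baseline_asc, 0.0)
    corrected = np.empty_like(corrected_asc)
    corrected[order] = corrected_asc
    return spectrum.with_absorbance(corrected)


def normalize(spectrum: Spectrum, method: str = "vector_l2") -> Spectrum:
    """Normalize a spectrum.

    ``vector_l2`` scales to unit Euclidean norm; ``amide_i_peak``
    scales so the maximum within 1680–1620 cm⁻¹ equals 1; ``none`` is
    the identity.
    """
    if method == "none":
        return spectrum.with_absorbance(spectrum.absorbance.copy())
    if method == "vector_l2":
        norm = float(np.linalg.norm(spectrum.absorbance))
        if norm == 0.0:
            raise DegenerateInputError(
                f"cannot vector-normalize the all-zero spectrum {spectrum.column_key!r}"
            )
        return spectrum.with_absorbance(spectrum.absorbance / norm)
    if method == "amide_i_peak":
        window = _window(spectrum, *AMIDE_I_WINDOW)
        if window.size == 0:
            raise UsageError("spectrum does not cover the amide I window (1680–1620)")
        peak = float(np.max(window))
        if peak == 0.0:
            raise DegenerateInputError("amide I window is identically zero")
        return spectrum.with_absorbance(spectrum.absorbance / peak)
    raise UsageError(f"unknown normalization method {method!r}")


def bin_spectrum(
    spectrum: Spectrum, bin_factor: int, truncate: bool = True
) -> Spectrum:
    """Mean-bin a spectrum by ``bin_factor``.

    Each output value is the mean of ``bin_factor`` consecutive input
    points; the output grid holds the mean wavenumber of each bin.  A
    trailing remainder of points is truncated when ``truncate`` is
    true, otherwise it is an error.
    """
    if bin_factor < 1:
        raise UsageError(f"bin_factor must be ≥ 1 (got {bin_factor})")
    n = len(spectrum)
    n_out = n // bin_factor
    if n_out == 0:
        raise UsageError(f"spectrum of {n} points cannot be binned by {bin_factor}")
    if n % bin_factor and not truncate:
        raise UsageError(
            f"{n} points do not divide by bin_factor {bin_factor}; "
            "pass truncate=True to drop the remainder"
        )
    keep = n_out * bin_factor
    wn = spectrum.wavenumbers[:keep].reshape(n_out, bin_factor).mean(axis=1)
    ab = spectrum.absorbance[:keep].reshape(n_out, bin_factor).mean(axis=1)
    return spectrum.with_grid(wn, ab)


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-processing chain configuration (see module docstring for defaults)."""

    crop_range: tuple[float, float] = (1800.0, 1000.0)
    baseline_method: str = "rubber_band"  # rubber_band | polynomial | none
    normalization: str = "vector_l2"  # vector_l2 | amide_i_peak | none
    bin_factor: int = 4  # 1 = no reduction
    qc_rules: tuple[QCRule, ...] = ()

    def __post_init__(self) -> None:
        if self.bin_factor < 1:
            raise UsageError(f"bin_factor must be ≥ 1 (got {self.bin_factor})")
        if self.baseline_method not in ("rubber_band", "polynomial", "none"):
            raise UsageError(f"unknown baseline_method {self.baseline_method!r}")
        if self.normalization not in ("vector_l2", "amide_i_peak", "none"):
            raise UsageError(f"unknown normalization {self.normalization!r}")
        lo, hi = min(self.crop_range), max(self.crop_range)
        if lo == hi:
            raise UsageError("crop_range must span a non-empty interval")


def crop(spectrum: Spectrum, crop_range: tuple[float, float]) -> Spectrum:
    lo, hi = min(crop_range), max(crop_range)
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise UsageError(
            f"crop range {crop_range} does not intersect the grid "
            f"[{spectrum.wavenumbers.min()}, {spectrum.wavenumbers.max()}]"
        )
    return spectrum.with_grid(spectrum.wavenumbers[mask], spectrum.absorbance[mask])


def _polynomial_baseline(spectrum: Spectrum, degree: int = 2) -> Spectrum:
    coeffs = np.polynomial.polynomial.polyfit(
        spectrum.wavenumbers, spectrum.absorbance, degree
    )
    fitted = np.polynomial.polynomial.polyval(spectrum.wavenumbers, coeffs)
    return spectrum.with_absorbance(spectrum.absorbance - fitted)


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Apply crop → baseline → normalize → reduce to one spectrum."""
    out = crop(spectrum, config.crop_range)
    if config.baseline_method == "rubber_band":
        out = rubber_band_baseline(out)
    elif config.baseline_method == "polynomial":
        out = _polynomial_baseline(out)
    out = normalize(out, config.normalization)
    if config.bin_factor > 1:
        out = bin_spectrum(out, config.bin_factor, truncate=True)
    return out


ID_COLUMNS = ("patient_id", "well", "replicate")


@dataclass
class FeatureTable:
    """Per-spectrum feature vectors with their measurement identity.

    ``frame`` holds the identity columns followed by one feature column
    per retained bin, labelled by the bin-center wavenumber.
    """

    frame: pd.DataFrame
    feature_columns: list[str]
    wavenumbers: np.ndarray
    flagged_patients: list[str] = field(default_factory=list)
    background_verdicts: dict[str, QCVerdict] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    def matrix(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def rows_for(self, patient_ids) -> pd.DataFrame:
        wanted = set(patient_ids)
        return self.frame[self.frame["patient_id"].isin(wanted)]


def preprocess_collection(
    collection: SpectraCollection,
    config: PreprocessConfig | None = None,
    manifest: CohortManifest | None = None,
) -> FeatureTable:
    """Preprocess every sample spectrum of a collection into a feature table.

    Background spectra are first evaluated against ``config.qc_rules``
    (verdicts are retained on the result); sample spectra are then run
    through the fixed chain.  A patient whose every sample spectrum
    fails is flagged on the returned table, never silently dropped.
    When a manifest is supplied, patient ids must be covered by it.
    """
    config = config or PreprocessConfig()
    verdicts: dict[str, QCVerdict] = {}
    for bg in collection.background_spectra():
        verdicts[bg.patient_id] = qc_background(bg, list(config.qc_rules))
    if manifest is not None:
        known = set(manifest.patient_ids)
        extra = {s.patient_id for s in collection.sample_spectra()} - known
        if extra:
            raise UsageError(
                f"spectra for patients absent from the manifest: {sorted(extra)[:5]}"
            )
    rows: list[dict] = []
    out_grid: np.ndarray | None = None
    seen_patients: set[str] = set()
    kept_patients: set[str] = set()
    for spectrum in collection.sample_spectra():
        seen_patients.add(spectrum.patient_id)
        processed = preprocess_spectrum(spectrum, config)
        if out_grid is None:
            out_grid = processed.wavenumbers
        row = {
            "patient_id": spectrum.patient_id,
            "well": spectrum.well,
            "replicate": spectrum.replicate,
        }
        row.update(zip((f"{w:.2f}" for w in out_grid), processed.absorbance))
        rows.append(row)
        kept_patients.add(spectrum.patient_id)
    if out_grid is None:
        raise UsageError("collection holds no sample spectra")
    feature_columns = [f"{w:.2f}" for w in out_grid]
    frame = pd.DataFrame(rows, columns=list(ID_COLUMNS) + feature_columns)
    flagged = sorted(seen_patients - kept_patients)
    return FeatureTable(
        frame=frame,
        feature_columns=feature_columns,
        wavenumbers=out_grid,
        flagged_patients=flagged,
        background_verdicts=verdicts,
    )
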