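import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectriage as sp
from spectriage.errors import DegenerateInputError, UsageError
from spectriage.preprocess import crop, preprocess_spectrum
from spectriage.spectra import Spectrum


def _spectrum(values, start=4000.0, role="sample", well="1"):
    values = np.asarray(values, dtype=float)
    grid = start - np.arange(values.size)
    return Spectrum(wavenumbers=grid, absorbance=values, role=role, well=well)


def _background(values, start=4000.0):
    return _spectrum(values, start=start, role="background", well="background")


class TestBackgroundQc:
    def test_quiet_background_passes(self):
        rules = [
            sp.QCRule("rms_noise_2200_2000", max=0.01),
            sp.QCRule("integrated_absorbance", min=-1, max=1),
        ]
        verdict = sp.qc_background(_background(np.zeros(3051)), rules)
        assert verdict.passed
        assert set(verdict.values) == {"rms_noise_2200_2000", "integrated_absorbance"}

    def test_saturated_background_fails_on_max_absorbance(self):
        rules = [sp.QCRule("max_absorbance", max=2.0)]
        verdict = sp.qc_background(_background(np.full(3051, 10.0)), rules)
        assert not verdict.passed
        assert verdict.failures == ["max_absorbance"]
        assert verdict.values["max_absorbance"] == 10.0

    def test_white_noise_rms_matches_generating_sd(self):
        rng = np.random.default_rng(99)
        rules = [sp.QCRule("rms_noise_2200_2000", min=0.004, max=0.006)]
        verdict = sp.qc_background(_background(rng.normal(0, 0.005, 3051)), rules)
        assert verdict.passed  # ~201-point window: sample sd within ±20% of 0.005

    def test_sample_spectrum_rejected(self):
        with pytest.raises(UsageError, match="background"):
            sp.qc_background(_spectrum(np.zeros(3051)), [])


class TestRubberBandBaseline:
    def test_straight_line_maps_to_zero(self):
        grid = np.arange(1800.0, 999.0, -1.0)
        spec = Spectrum(wavenumbers=grid, absorbance=0.3 + 0.001 * grid)
        corrected = sp.rubber_band_baseline(spec)
        assert np.allclose(corrected.absorbance, 0.0, atol=1e-12)

    def test_gaussian_peak_on_slope_recovered(self):
        grid = np.arange(1800.0, 999.0, -1.0)
        peak = 0.5 * np.exp(-((grid - 1400.0) ** 2) / (2 * 20.0**2))
        slope = 0.2 + 1e-4 * (grid - 1000.0)
        spec = Spectrum(wavenumbers=grid, absorbance=peak + slope)
        corrected = sp.rubber_band_baseline(spec)
        assert corrected.value_at(1400) == pytest.approx(0.5, abs=0.005)  # within 1%

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        spec = _spectrum(rng.uniform(0, 1, 400))
        once = sp.rubber_band_baseline(spec)
        twice = sp.rubber_band_baseline(once)
        assert np.allclose(once.absorbance, twice.absorbance, atol=1e-9)

    def test_non_negative_with_zero_touch_points(self):
        rng = np.random.default_rng(11)
        spec = _spectrum(rng.normal(0, 1, 500))
        corrected = sp.rubber_band_baseline(spec)
        assert np.all(corrected.absorbance >= -1e-12)
        assert np.sum(corrected.absorbance == 0.0) >= 2

    def test_too_few_points_rejected(self):
        with pytest.raises(UsageError, match="3 points"):
            sp.rubber_band_baseline(_spectrum([1.0, 2.0]))


class TestNormalize:
    def test_two_point_toy(self):
        spec = _spectrum([3.0, 4.0])
        out = sp.normalize(spec, "vector_l2")
        assert np.allclose(out.absorbance, [0.6, 0.8])

    def test_scale_invariance(self):
        spec = _spectrum([0.1, 0.5, 0.2, 0.9])
        scaled = spec.with_absorbance(spec.absorbance * 7.0)
        assert np.allclose(
            sp.normalize(spec, "vector_l2").absorbance,
            sp.normalize(scaled, "vector_l2").absorbance,
        )

    def test_amide_peak_normalization_on_band_table(self, noiseless_config):
        spec = sp.simulate_spectrum(noiseless_config, sp.NON_CANCER)
        out = sp.normalize(spec, "amide_i_peak")
        assert out.value_at(1655) == pytest.approx(1.0, abs=1e-9)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            sp.normalize(_spectrum(np.zeros(10)), "vector_l2")


class TestBinning:
    def test_800_points_factor_4(self):
        spec = _spectrum(np.arange(800.0))
        out = sp.bin_spectrum(spec, 4)
        assert len(out) == 200

    def test_constant_stays_constant(self):
        out = sp.bin_spectrum(_spectrum(np.full(100, 0.7)), 5)
        assert np.allclose(out.absorbance, 0.7)

    def test_linear_ramp_through_bin_midpoints(self):
        grid = 2000.0 - np.arange(12.0)
        spec = Spectrum(wavenumbers=grid, absorbance=2.0 * grid + 1.0)
        out = sp.bin_spectrum(spec, 3)
        # mean of an arithmetic sequence = value at the mean abscissa
        assert np.allclose(out.absorbance, 2.0 * out.wavenumbers + 1.0)

    def test_bad_factor_rejected(self):
        with pytest.raises(UsageError):
            sp.bin_spectrum(_spectrum(np.arange(10.0)), 0)

    def test_remainder_requires_truncate(self):
        with pytest.raises(UsageError, match="truncate"):
            sp.bin_spectrum(_spectrum(np.arange(10.0)), 4, truncate=False)


class TestPreprocessCollection:
    def test_default_chain_yields_200_features(self, small_features):
        _, table = small_features
        assert table.n_features == 200
        # fingerprint crop is 801 points; the final odd point is truncated
        assert table.wavenumbers.max() < 1800.0
        assert len(table.frame) == 10 * 2 * 9

    def test_identity_config_preserves_values(self, small_cohort):
        _, manifest, collection = small_cohort
        config = sp.PreprocessConfig(
            crop_range=(4000.0, 950.0),
            baseline_method="none",
            normalization="none",
            bin_factor=1,
        )
        table = sp.preprocess_collection(collection, config, manifest)
        first = next(iter(collection.sample_spectra()))
        row = table.frame[
            (table.frame["patient_id"] == first.patient_id)
            & (table.frame["well"] == first.well)
            & (table.frame["replicate"] == first.replicate)
        ]
        assert np.allclose(
            row[table.feature_columns].to_numpy().ravel(), first.absorbance
        )

    def test_deterministic(self, small_cohort):
        _, manifest, collection = small_cohort
        a = sp.preprocess_collection(collection, manifest=manifest)
        b = sp.preprocess_collection(collection, manifest=manifest)
        assert a.frame.equals(b.frame)

    def test_every_row_traceable(self, small_features):
        manifest, table = small_features
        assert set(table.frame["patient_id"]) == set(manifest.patient_ids)
        per_patient = table.frame.groupby("patient_id").size()
        assert (per_patient == 9).all()

    def test_unit_norms_before_reduction(self, small_cohort):
        # normalization precedes binning, so unit norms hold at bin_factor=1
        _, manifest, collection = small_cohort
        config = sp.PreprocessConfig(bin_factor=1)
        table = sp.preprocess_collection(collection, config, manifest)
        norms = np.linalg.norm(table.matrix(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=3, max_size=200
    )
)
def test_rubber_band_properties_hold_for_arbitrary_signals(data):
    corrected = sp.rubber_band_baseline(_spectrum(data))
    assert np.all(corrected.absorbance >= -1e-12)
    again = sp.rubber_band_baseline(corrected)
    assert np.allclose(corrected.absorbance, again.absorbance, atol=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=1, max_value=300), factor=st.integers(min_value=1, max_value=12)
)
def test_binned_length_is_floor_division(n, factor):
    if n < factor:
        return
    out = sp.bin_spectrum(_spectrum(np.arange(float(n))), factor)
    assert len(out) == n // factor


def test_fixed_operation_order_crop_before_baseline(noiseless_config):
    """The chain crops first: hull anchoring happens inside the fingerprint region."""
    spec = sp.simulate_spectrum(noiseless_config, sp.NON_CANCER)
    config = sp.PreprocessConfig(normalization="none", bin_factor=1)
    chained = preprocess_spectrum(spec, config)
    manual = sp.rubber_band_baseline(crop(spec, (1800.0, 1000.0)))
    assert np.allclose(chained.absorbance, manual.absorbance)
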