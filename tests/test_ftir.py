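"""FTIR preprocessing chain and stepwise secondary-structure calibration."""

import numpy as np
import pytest

from confmap import ftir
from confmap import synthetic as syn
from confmap.errors import (
    DegenerateReferenceError,
    GridMismatchError,
    NormalizationError,
    ValidationError,
)


def _clean_spectrum(seed=0, **kw):
    return syn.simulate_ftir_spectrum(syn.FTIRSimSpec(seed=seed, **kw))


class TestSpectrum:
    def test_ascending_input_reversed_to_canonical(self):
        wn = np.arange(600.0, 4001.0, 2.0)
        s = ftir.Spectrum(wn, np.linspace(0, 1, wn.size))
        assert s.wavenumbers[0] == 4000.0
        assert s.absorbance[0] == 1.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValidationError):
            ftir.Spectrum(np.array([3.0, 1.0, 2.0]), np.zeros(3))

    def test_read_write_round_trip(self, tmp_path):
        s = _clean_spectrum(noise_sd=0.01, seed=3)
        path = tmp_path / "spec.txt"
        ftir.write_spectrum(s, path)
        back = ftir.read_spectrum(path)
        np.testing.assert_array_equal(back.wavenumbers, s.wavenumbers)
        np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-9)

    def test_comma_separated_input_accepted(self, tmp_path):
        path = tmp_path / "spec.csv"
        path.write_text("# header\n1720,0.5\n1718,0.6\n1716,0.4\n")
        s = ftir.read_spectrum(path)
        assert s.value_at(1718.0) == 0.6


class TestVaporSubtraction:
    def test_uncontaminated_spectrum_unchanged(self, vapor_reference):
        s = _clean_spectrum()
        out, c = ftir.subtract_water_vapor(s, vapor_reference)
        assert abs(c) < 1e-12
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-10)

    def test_recovers_planted_scaling_coefficient(self, vapor_reference):
        s = _clean_spectrum()
        contaminated = s.copy_with(
            s.absorbance + 0.3 * vapor_reference.absorbance
        )
        out, c = ftir.subtract_water_vapor(contaminated, vapor_reference)
        assert c == pytest.approx(0.3, abs=1e-10)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-9)

    def test_window_rms_never_increases(self, vapor_reference):
        rng = np.random.default_rng(5)
        m = vapor_reference.window_mask(1935, 1956)
        for seed in range(5):
            s = _clean_spectrum(noise_sd=0.01, vapor_amplitude=0.05,
                                seed=seed)
            out, _ = ftir.subtract_water_vapor(s, vapor_reference)
            assert (np.sqrt(np.mean(out.absorbance[m] ** 2))
                    <= np.sqrt(np.mean(s.absorbance[m] ** 2)) + 1e-15)

    def test_grid_mismatch_is_an_error(self, vapor_reference):
        short = ftir.Spectrum(np.arange(2000.0, 999.0, -2.0),
                              np.zeros(501))
        with pytest.raises(GridMismatchError):
            ftir.subtract_water_vapor(short, vapor_reference)

    def test_zero_reference_in_window_rejected(self):
        grid = syn.default_grid()
        s = _clean_spectrum()
        dead = ftir.Spectrum(grid, np.zeros_like(grid))
        with pytest.raises(DegenerateReferenceError):
            ftir.subtract_water_vapor(s, dead)


class TestBaseline:
    def test_piecewise_linear_spectrum_zeroed(self):
        grid = syn.default_grid()
        anchors = np.asarray(ftir.BASELINE_ANCHORS)
        values = np.interp(grid, np.sort(anchors),
                           [0.1, 0.4, 0.2, 0.5, 0.3, 0.6, 0.2])
        s = ftir.Spectrum(grid, values)
        out = ftir.baseline_correct(s)
        inside = (grid >= 980) & (grid <= 3700)
        np.testing.assert_allclose(out.absorbance[inside], 0.0, atol=1e-12)

    def test_constant_spectrum_zeroed_inside_anchor_range(self):
        grid = syn.default_grid()
        out = ftir.baseline_correct(ftir.Spectrum(grid, np.full_like(grid, 0.7)))
        inside = (grid >= 980) & (grid <= 3700)
        np.testing.assert_allclose(out.absorbance[inside], 0.0, atol=1e-12)
        outside = ~inside
        np.testing.assert_allclose(out.absorbance[outside], 0.7)

    def test_output_zero_at_every_anchor(self):
        s = _clean_spectrum(noise_sd=0.01, baseline_slope=2e-5, seed=9)
        out = ftir.baseline_correct(s)
        for a in ftir.BASELINE_ANCHORS:
            assert out.value_at(a) == 0.0

    def test_idempotent(self):
        s = _clean_spectrum(noise_sd=0.01, baseline_slope=1e-5, seed=10)
        once = ftir.baseline_correct(s)
        twice = ftir.baseline_correct(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance,
                                   atol=1e-15)

    def test_anchor_off_grid_rejected(self):
        s = _clean_spectrum()
        with pytest.raises(ValidationError):
            ftir.baseline_correct(s, anchors=(3701.0, 980.0))


class TestNormalization:
    def test_window_area_becomes_exactly_one(self):
        s = _clean_spectrum(noise_sd=0.005, seed=11)
        out = ftir.normalize_area(ftir.baseline_correct(s))
        assert ftir.amide_area(out) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        s = _clean_spectrum(seed=12)
        n1 = ftir.normalize_area(s)
        n2 = ftir.normalize_area(s.copy_with(37.0 * s.absorbance))
        np.testing.assert_allclose(n1.absorbance, n2.absorbance, atol=1e-12)

    def test_trapezoid_area_matches_fine_grid_integration(self):
        # oracle: evaluate the analytic band sum on a 0.01 cm⁻¹ grid
        spec = syn.FTIRSimSpec()
        s = syn.simulate_ftir_spectrum(spec)
        coarse = ftir.amide_area(s)
        fine_x = np.arange(1480.0, 1720.0 + 1e-9, 0.01)
        fine_y = np.zeros_like(fine_x)
        for frac, cls in zip(spec.fractions, syn.STRUCTURE_CLASSES):
            c, w = syn.DEFAULT_BAND_CENTERS[cls], syn.DEFAULT_BAND_WIDTHS[cls]
            fine_y += frac / 100.0 * np.exp(-0.5 * ((fine_x - c) / w) ** 2)
        assert coarse == pytest.approx(np.trapezoid(fine_y, fine_x), abs=1e-6)

    def test_zero_area_rejected(self):
        grid = syn.default_grid()
        with pytest.raises(NormalizationError):
            ftir.normalize_area(ftir.Spectrum(grid, np.zeros_like(grid)))


def test_full_chain_idempotent_to_numerical_precision(vapor_reference):
    s = _clean_spectrum(vapor_amplitude=0.02, baseline_slope=1e-5,
                        noise_sd=0.002, seed=13)
    once = ftir.preprocess(s, vapor_reference)
    twice = ftir.preprocess(once, vapor_reference)
    assert np.abs(twice.absorbance - once.absorbance).max() < 1e-9


def test_prediction_invariant_to_global_scaling(vapor_reference, noisy_library):
    model = ftir.stepwise_calibrate(noisy_library, loocv=False)
    s = _clean_spectrum(vapor_amplitude=0.01, baseline_slope=5e-6,
                        noise_sd=0.001, seed=14)
    a = ftir.predict_fractions(model, [ftir.preprocess(s, vapor_reference)])
    scaled = s.copy_with(3.5 * s.absorbance)
    b = ftir.predict_fractions(model, [ftir.preprocess(scaled, vapor_reference)])
    np.testing.assert_allclose(a.mean, b.mean, atol=1e-9)


def _planted_library(n=30, seed=20, noise_sd=0.0):
    """Library whose α-helix fraction is exactly 200·A(1656)."""
    lib = syn.simulate_ftir_library(n_proteins=n, noise_sd=noise_sd, seed=seed)
    alpha = np.array([200.0 * s.value_at(1656.0) for s in lib.spectra])
    return syn.FTIRLibrary(spectra=lib.spectra,
                           fractions=alpha[:, None],
                           classes=("alpha_helix",))


class TestStepwiseCalibration:
    def test_planted_single_wavenumber_is_selected_exactly(self):
        model = ftir.stepwise_calibrate(_planted_library())
        assert model.wavenumbers["alpha_helix"][0] == 1656.0
        assert model.sep_loocv["alpha_helix"] < 1e-6
        coef = model.coefficients["alpha_helix"]
        assert coef[1] == pytest.approx(200.0, rel=1e-9)

    def test_at_most_three_wavenumbers_per_class(self, noisy_library):
        model = ftir.stepwise_calibrate(noisy_library, loocv=False)
        assert all(len(v) <= 3 for v in model.wavenumbers.values())

    def test_pure_noise_fractions_yield_sep_near_fraction_sd(self):
        lib = syn.simulate_ftir_library(n_proteins=50, noise_sd=0.0, seed=21)
        rng = np.random.default_rng(22)
        noise_fracs = rng.normal(50.0, 5.0, size=(50, 1))
        null_lib = syn.FTIRLibrary(spectra=lib.spectra,
                                   fractions=noise_fracs,
                                   classes=("alpha_helix",))
        model = ftir.stepwise_calibrate(null_lib)
        sd = noise_fracs.std(ddof=1)
        assert model.sep_loocv["alpha_helix"] == pytest.approx(sd, rel=0.25)

    def test_loocv_sep_within_twice_noise_floor(self, noisy_library):
        model = ftir.stepwise_calibrate(noisy_library)
        for cls in model.classes:
            coef = np.asarray(model.coefficients[cls])
            floor = 0.002 * np.sqrt((coef[1:] ** 2).sum())
            assert model.sep_loocv[cls] <= 2.0 * floor

    def test_library_too_small_rejected(self):
        lib = syn.simulate_ftir_library(n_proteins=4, noise_sd=0.0, seed=23)
        with pytest.raises(ValidationError):
            ftir.stepwise_calibrate(lib)

    def test_model_json_round_trip(self, tmp_path, noisy_library):
        model = ftir.stepwise_calibrate(noisy_library, loocv=False)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ftir.CalibrationModel.from_json(path)
        assert back.wavenumbers == model.wavenumbers
        for cls in model.classes:
            np.testing.assert_allclose(back.coefficients[cls],
                                       model.coefficients[cls])


class TestPrediction:
    def test_training_spectrum_reproduced_exactly_on_planted_library(self):
        lib = _planted_library()
        model = ftir.stepwise_calibrate(lib, loocv=False)
        est = ftir.predict_fractions(model, [lib.spectra[0]])
        assert est.mean[0] == pytest.approx(lib.fractions[0, 0], abs=1e-9)

    def test_identical_replicates_have_zero_sd(self, noisy_library):
        model = ftir.stepwise_calibrate(noisy_library, loocv=False)
        reps = [noisy_library.spectra[0]] * 5
        est = ftir.predict_fractions(model, reps)
        assert est.n_replicates == 5
        np.testing.assert_allclose(est.sd, 0.0, atol=1e-12)

    def test_out_of_range_predictions_flagged_verbatim(self):
        model = ftir.CalibrationModel(
            classes=("alpha_helix",),
            wavenumbers={"alpha_helix": [1656.0]},
            coefficients={"alpha_helix": np.array([150.0, 0.0])},
        )
        est = ftir.predict_fractions(model, [_clean_spectrum()])
        assert est.mean[0] == 150.0
        assert est.out_of_range[0]

    def test_model_wavenumber_absent_from_grid_rejected(self):
        model = ftir.CalibrationModel(
            classes=("alpha_helix",),
            wavenumbers={"alpha_helix": [1656.5]},
            coefficients={"alpha_helix": np.array([0.0, 1.0])},
        )
        with pytest.raises(GridMismatchError):
            ftir.predict_fractions(model, [_clean_spectrum()])
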