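import numpy as np
import pytest

from ramanci import (
    AmorphousReference,
    CalibrationLine,
    DegenerateInputError,
    Diffractogram,
    RangeError,
    SegalWindows,
    Spectrum,
    SpectrumSet,
    ValidationError,
    amorphous_subtracted_ratio,
    batch_ci,
    build_amorphous_reference,
    builtin_amorphous_stats,
    builtin_calibration,
    ci_from_ratio,
    fit_calibration,
    peak_intensity,
    segal_ci,
    spot_area_mm2,
)
from ramanci.crystallinity import (
    load_amorphous_reference,
    load_calibration,
    save_amorphous_reference,
    save_calibration,
)
from ramanci.errors import FitError


def flat_spectrum(axis, value=1.0, tags=("baseline", "snv")):
    return Spectrum(axis, np.full(len(axis), float(value)),
                    processing_tags=tags)


class TestPeakIntensity:
    def test_window_maximum_arithmetic(self):
        axis = np.arange(374.0, 387.0)
        ints = np.ones(axis.size)
        ints[axis == 384] = 2.5
        s = Spectrum(axis, ints)
        assert peak_intensity(s, 380, 5) == 2.5
        assert peak_intensity(s, 380, 3) == 1.0

    def test_apex_inside_window(self):
        axis = np.arange(370.0, 391.0)
        s = Spectrum(axis, 7.3 * np.maximum(0, 1 - np.abs(axis - 380) / 8))
        assert peak_intensity(s, 380, 5) == pytest.approx(7.3)

    def test_half_window_zero_reads_interpolated_value(self):
        s = Spectrum([379.0, 381.0], [1.0, 3.0])
        assert peak_intensity(s, 380, 0) == pytest.approx(2.0)

    def test_window_outside_axis_is_range_error(self, axis):
        s = flat_spectrum(axis)
        with pytest.raises(RangeError):
            peak_intensity(s, 5000, 5)


class TestAmorphousReference:
    def test_single_spectrum_reference(self, axis):
        s = flat_spectrum(axis, 2.0)
        ref = build_amorphous_reference(SpectrumSet([s]))
        assert np.allclose(ref.spectrum.intensities, s.intensities)
        assert ref.i380_sd == 0.0 and ref.i1096_sd == 0.0
        assert ref.n_spectra == 1

    def test_band_stats_from_per_spectrum_intensities(self, axis):
        def with_380(height):
            ints = np.ones(len(axis))
            ints[axis == 380] = height
            return Spectrum(axis, ints, processing_tags=("baseline",))

        ref = build_amorphous_reference(SpectrumSet([with_380(0.4 + 1),
                                                     with_380(0.8 + 1)]))
        # heights 1.4 and 1.8 at the 380 band
        assert ref.i380_mean == pytest.approx(1.6)
        assert ref.i380_sd == pytest.approx(np.std([1.4, 1.8], ddof=1))

    def test_mean_of_identical_spectra_is_that_spectrum(self, random_spectrum):
        s = random_spectrum(seed=9)
        s = s.with_intensities(s.intensities, add_tag="baseline")
        ref = build_amorphous_reference(SpectrumSet([s, s, s]))
        assert np.allclose(ref.spectrum.intensities, s.intensities)

    def test_requires_preprocessing_tags(self, axis):
        s = Spectrum(axis, np.ones(len(axis)))
        with pytest.raises(ValidationError):
            build_amorphous_reference(SpectrumSet([s]))

    def test_round_trip_serialization(self, tmp_path, axis):
        ref = build_amorphous_reference(SpectrumSet([flat_spectrum(axis, 2.0)]))
        p = tmp_path / "ref.json"
        save_amorphous_reference(ref, p)
        back = load_amorphous_reference(p)
        assert back.i380_mean == ref.i380_mean
        assert np.allclose(back.spectrum.intensities, ref.spectrum.intensities)


class TestAmorphousSubtractedRatio:
    def _sample(self, axis, i380, i1096):
        ints = np.zeros(len(axis))
        ints[axis == 380] = i380
        ints[axis == 1096] = i1096
        return Spectrum(axis, ints, processing_tags=("baseline", "snv"))

    def test_against_published_mr_band_statistics(self, axis):
        ref = builtin_amorphous_stats("MR")
        s = self._sample(axis, 2.0, 3.5)
        ratio = amorphous_subtracted_ratio(s, ref, scale_at_857=False)
        assert ratio == pytest.approx((2.0 - 0.627) / (3.5 - 2.745))

    def test_against_published_phat_band_statistics(self, axis):
        ref = builtin_amorphous_stats("PHAT")
        s = self._sample(axis, 1.694, 3.607)
        ratio = amorphous_subtracted_ratio(s, ref, scale_at_857=False)
        assert ratio == pytest.approx(0.5)

    def test_sample_equal_to_reference_is_degenerate(self, axis):
        ref_spec = flat_spectrum(axis, 1.0)
        ref = build_amorphous_reference(SpectrumSet([ref_spec]))
        with pytest.raises(DegenerateInputError):
            amorphous_subtracted_ratio(ref_spec, ref, scale_at_857=True)

    def test_monotone_in_band_intensities(self, axis):
        ref = builtin_amorphous_stats("MR")
        base = amorphous_subtracted_ratio(self._sample(axis, 2.0, 3.5), ref,
                                          scale_at_857=False)
        up380 = amorphous_subtracted_ratio(self._sample(axis, 2.5, 3.5), ref,
                                           scale_at_857=False)
        up1096 = amorphous_subtracted_ratio(self._sample(axis, 2.0, 4.0), ref,
                                            scale_at_857=False)
        assert up380 > base
        assert up1096 < base


class TestCalibrations:
    def test_builtin_constants(self):
        orig = builtin_calibration("ORIGINAL")
        assert (orig.slope, orig.intercept) == (0.0065, 0.0286)
        mr = builtin_calibration("MR")
        assert (mr.slope, mr.intercept) == (0.005, -0.134)
        phat = builtin_calibration("PHAT")
        assert (phat.slope, phat.intercept) == (0.005, -0.129)

    def test_prediction_form(self):
        assert ci_from_ratio(0.0286, builtin_calibration("ORIGINAL")) == pytest.approx(0.0)
        assert ci_from_ratio(0.366, builtin_calibration("MR")) == pytest.approx(100.0)
        assert ci_from_ratio(0.678, builtin_calibration("ORIGINAL")) == pytest.approx(
            (0.678 - 0.0286) / 0.0065)

    def test_not_clipped_by_default_and_clip_warns(self):
        cal = builtin_calibration("MR")
        assert ci_from_ratio(-0.2, cal) < 0
        with pytest.warns(UserWarning):
            assert ci_from_ratio(-0.2, cal, clip=True) == 0.0

    def test_strictly_increasing_in_ratio(self):
        cal = builtin_calibration("PHAT")
        r = np.linspace(-0.2, 0.5, 20)
        ci = [ci_from_ratio(v, cal) for v in r]
        assert np.all(np.diff(ci) > 0)

    def test_fit_recovers_exact_line(self):
        for m, c in ((0.005, -0.134), (0.0065, 0.0286)):
            pairs = [(m * ci + c, ci) for ci in (0, 25, 50, 75, 100)]
            cal = fit_calibration(pairs)
            assert cal.slope == pytest.approx(m)
            assert cal.intercept == pytest.approx(c)
            assert cal.pearson_r == pytest.approx(1.0)
            for ratio, ci in pairs:
                assert ci_from_ratio(ratio, cal) == pytest.approx(ci, abs=1e-9)

    def test_fit_degenerate_designs(self):
        with pytest.raises(FitError):
            fit_calibration([(0.1, 50), (0.2, 50), (0.3, 50)])
        with pytest.raises(FitError):
            fit_calibration([(0.1, 10), (0.2, 20)])

    def test_calibration_serialization(self, tmp_path):
        cal = fit_calibration([(0.1, 10), (0.2, 30), (0.3, 50)], label="X")
        p = tmp_path / "cal.json"
        save_calibration(cal, p)
        back = load_calibration(p)
        assert back.slope == cal.slope and back.intercept == cal.intercept
        assert back.label == "X"

    def test_zero_slope_rejected(self):
        with pytest.raises(ValidationError):
            CalibrationLine(0.0, 0.1)


class TestSegal:
    def _diff(self, i200, iam, baseline=0.0):
        tt = np.arange(10.0, 30.0, 0.01)
        counts = np.full(tt.size, baseline)
        counts[(tt >= 22.55) & (tt <= 22.65)] = i200 + baseline
        counts[(tt >= 18.65) & (tt <= 18.75)] = iam + baseline
        return Diffractogram(tt, counts)

    @pytest.mark.parametrize("i200,iam,expect", [
        (1000, 0, 100.0), (1000, 1000, 0.0), (1000, 250, 75.0),
    ])
    def test_peak_height_arithmetic(self, i200, iam, expect):
        assert segal_ci(self._diff(i200, iam)) == pytest.approx(expect)

    def test_invariant_to_count_scaling(self):
        d = self._diff(1000, 300)
        d2 = Diffractogram(d.two_theta, d.counts * 17.3)
        assert segal_ci(d2) == pytest.approx(segal_ci(d))

    def test_blank_subtraction(self):
        d = self._diff(1000, 250, baseline=50.0)
        blank = Diffractogram(d.two_theta, np.full(d.two_theta.size, 50.0))
        assert segal_ci(d, blank=blank) == pytest.approx(75.0)

    def test_degenerate_and_range_errors(self):
        d = self._diff(0, 100)
        with pytest.raises(DegenerateInputError):
            segal_ci(d)
        short = Diffractogram(np.arange(19.0, 20.0, 0.01),
                              np.ones(100))
        with pytest.raises(RangeError):
            segal_ci(short)

    def test_windows_validated(self):
        with pytest.raises(ValidationError):
            SegalWindows((22.55, 22.65), (22.60, 22.70))  # overlap
        with pytest.raises(ValidationError):
            SegalWindows((22.65, 22.55), (18.65, 18.75))  # empty


class TestBatchCI:
    def _replicates(self, axis, triples):
        items = []
        for i, (i380, i1096) in enumerate(triples, start=1):
            ints = np.zeros(len(axis))
            ints[axis == 380] = i380
            ints[axis == 1096] = i1096
            items.append(Spectrum(axis, ints, sample_id="b", replicate=i,
                                  processing_tags=("baseline", "snv")))
        return SpectrumSet(items)

    def test_mean_and_sd_aggregation(self, axis):
        ref = builtin_amorphous_stats("MR")
        cal = CalibrationLine(1.0, 0.0, label="IDENT")  # ci == ratio
        # choose bands so that ratios come out at 80, 82, 84
        reps = []
        for target in (80.0, 82.0, 84.0):
            reps.append((0.627 + target * 1.0, 2.745 + 1.0))
        out = batch_ci(self._replicates(axis, reps), ref, cal,
                       scale_at_857=False)
        assert out.mean == pytest.approx(82.0)
        assert out.sd == pytest.approx(2.0)
        assert out.n_failed == 0

    def test_single_replicate_sd_zero(self, axis):
        ref = builtin_amorphous_stats("MR")
        cal = builtin_calibration("MR")
        out = batch_ci(self._replicates(axis, [(2.0, 3.5)]), ref, cal,
                       scale_at_857=False)
        assert out.sd == 0.0 and len(out.values) == 1

    def test_degenerate_replicate_flagged_not_fatal(self, axis):
        ref = builtin_amorphous_stats("MR")
        cal = CalibrationLine(1.0, 0.0)
        reps = [(0.627 + 80, 2.745 + 1), (0.9, 2.745)]  # second: zero denom
        out = batch_ci(self._replicates(axis, reps), ref, cal,
                       scale_at_857=False)
        assert out.n_failed == 1
        assert out.mean == pytest.approx(80.0)


class TestGeometry:
    def test_mr_probe_spot_area(self):
        # 100 um nominal beam diameter -> 7.85e-3 mm^2 (3 significant figures)
        area = spot_area_mm2(100.0)
        assert float(f"{area:.3g}") == pytest.approx(7.85e-3)

    def test_area_scales_quadratically(self):
        assert spot_area_mm2(200.0) == pytest.approx(4 * spot_area_mm2(100.0))
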