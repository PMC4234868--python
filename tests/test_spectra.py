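import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedprobe import spectra
from pedprobe.errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    RangeError,
)


WL = np.arange(340.0, 1021.0, 1.0)


def const_spectrum(value=1.0, wl=WL):
    return spectra.Spectrum(wl, np.full(wl.size, float(value)))


class TestSpectrumValidation:
    def test_rejects_unsorted_grid(self):
        with pytest.raises(InvalidParameterError):
            spectra.Spectrum(np.array([340.0, 339.0]), np.array([1.0, 1.0]))

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidParameterError):
            spectra.Spectrum(np.array([1.0, 2.0]), np.array([1.0, np.inf]))


class TestNormalizeReflectance:
    def setup_method(self):
        self.dark = const_spectrum(100.0)
        self.ref = const_spectrum(1100.0)

    def test_signal_equal_reference_gives_one(self):
        r = spectra.normalize_reflectance(self.ref, self.dark, self.ref)
        np.testing.assert_allclose(r.intensities, 1.0)

    def test_signal_equal_dark_gives_zero(self):
        r = spectra.normalize_reflectance(self.dark, self.dark, self.ref)
        np.testing.assert_allclose(r.intensities, 0.0)

    def test_midpoint_gives_half(self):
        mid = const_spectrum(600.0)
        r = spectra.normalize_reflectance(mid, self.dark, self.ref)
        np.testing.assert_allclose(r.intensities, 0.5)

    def test_grid_mismatch_rejected(self):
        other = const_spectrum(1.0, wl=WL[:-1])
        with pytest.raises(GridMismatchError):
            spectra.normalize_reflectance(other, self.dark, self.ref)

    def test_saturated_reference_rejected(self):
        with pytest.raises(InvalidParameterError):
            spectra.normalize_reflectance(self.ref, self.dark, self.dark)


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        reps = [const_spectrum(2.5) for _ in range(20)]
        avg = spectra.average_replicates(reps)
        np.testing.assert_allclose(avg.intensities, 2.5)

    def test_two_spectra_mean(self):
        with pytest.warns(UserWarning, match="protocol expects"):
            avg = spectra.average_replicates(
                [const_spectrum(0.0), const_spectrum(2.0)]
            )
        np.testing.assert_allclose(avg.intensities, 1.0)

    def test_matches_scalar_loop_oracle(self, rng):
        reps = [
            spectra.Spectrum(WL, rng.random(WL.size)) for _ in range(5)
        ]
        with pytest.warns(UserWarning):
            avg = spectra.average_replicates(reps)
        # brute-force elementwise mean
        for j in [0, 100, 680]:
            expect = sum(r.intensities[j] for r in reps) / 5
            assert avg.intensities[j] == pytest.approx(expect, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            spectra.average_replicates([])


class TestAreaFactor:
    def test_unit_constant_gives_window_width(self):
        assert spectra.area_factor(const_spectrum(1.0)) == pytest.approx(680.0)

    def test_zero_spectrum(self):
        assert spectra.area_factor(const_spectrum(0.0)) == 0.0

    def test_linear_ramp_triangle_area(self):
        ramp = spectra.Spectrum(WL, (WL - 340.0) / 680.0)
        assert spectra.area_factor(ramp) == pytest.approx(340.0)

    def test_additive_over_subintervals(self):
        s = spectra.Spectrum(WL, np.sin(WL / 50.0) + 2.0)
        whole = spectra.area_factor(s, 340, 1020)
        parts = spectra.area_factor(s, 340, 700) + spectra.area_factor(s, 700, 1020)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_range_not_covered(self):
        with pytest.raises(RangeError):
            spectra.area_factor(const_spectrum(1.0), 300, 1020)


class TestPeakFactor:
    def test_maximum_value(self):
        s = spectra.Spectrum(np.array([500.0, 600.0, 700.0]), np.array([1.0, 5.0, 3.0]))
        assert spectra.peak_factor(s, 500, 700) == 5.0

    def test_constant(self):
        assert spectra.peak_factor(const_spectrum(2.0)) == 2.0

    def test_tie_reports_smallest_wavelength(self):
        wl = np.array([500.0, 600.0, 700.0, 800.0])
        s = spectra.Spectrum(wl, np.array([1.0, 4.0, 4.0, 2.0]))
        assert spectra.peak_location(s, 500, 800) == 600.0


class TestSlopeFactor:
    def test_exact_line(self):
        s = spectra.Spectrum(WL, 0.004 * WL + 1.0)
        assert spectra.slope_factor(s) == pytest.approx(0.004 * 1000)

    def test_constant_zero_slope(self):
        assert spectra.slope_factor(const_spectrum(5.0)) == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        y = 0.01 * WL + rng.normal(0, 0.5, WL.size)
        s = spectra.Spectrum(WL, y)
        mask = (WL >= 500) & (WL <= 550)
        x = WL[mask]
        # independent normal-equations solve
        a = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(a.T @ a, a.T @ y[mask])
        assert spectra.slope_factor(s, scale=1.0) == pytest.approx(beta[0], rel=1e-9)

    def test_window_endpoints_inclusive(self):
        wl = np.array([499.0, 500.0, 550.0, 551.0])
        s = spectra.Spectrum(wl, np.array([0.0, 1.0, 2.0, 0.0]))
        # only 500 and 550 are in the window: slope (2-1)/50
        assert spectra.slope_factor(s, scale=1.0) == pytest.approx(0.02)

    def test_too_few_points(self):
        wl = np.array([340.0, 520.0, 1020.0])
        s = spectra.Spectrum(wl, np.ones(3))
        with pytest.raises(InsufficientDataError):
            spectra.slope_factor(s)


class TestExtractPatternFactors:
    def test_composition_on_constant_spectrum(self):
        pf = spectra.extract_pattern_factors(const_spectrum(1.0), mu_s_reduced=17.0)
        assert pf.area == pytest.approx(680.0)
        assert pf.peak == 1.0
        assert pf.slope == pytest.approx(0.0)
        assert pf.mu_s_reduced == 17.0

    def test_error_propagates_from_bad_window(self):
        s = spectra.Spectrum(np.array([600.0, 700.0]), np.array([1.0, 1.0]))
        with pytest.raises(RangeError):
            spectra.extract_pattern_factors(s, 10.0)

    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_area_linear_in_intensity_scale(self, scale):
        s = spectra.Spectrum(WL, np.cos(WL / 90.0) + 2.0)
        scaled = spectra.Spectrum(WL, s.intensities * scale)
        assert spectra.area_factor(scaled) == pytest.approx(
            scale * spectra.area_factor(s), rel=1e-9
        )


class TestSpectrumIO:
    def test_roundtrip_with_comments(self, tmp_path, rng):
        s = spectra.Spectrum(WL, rng.random(WL.size))
        path = tmp_path / "spec.csv"
        spectra.write_spectrum(s, path, header_lines=["seed=1", "depth=2.0mm"])
        back = spectra.read_spectrum(path)
        np.testing.assert_allclose(back.wavelengths, s.wavelengths)
        np.testing.assert_allclose(back.intensities, s.intensities)
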