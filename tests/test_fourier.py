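"""Fourier power spectrum, radial averaging, and reflectance prediction."""

import numpy as np
import pytest

from scalecolor.fourier import (
    analyze_index_map,
    frequency_to_wavelength,
    power_spectrum_2d,
    predicted_reflectance,
    radial_average,
    visible_frequency_band,
    RadialProfile,
)
from scalecolor.image_prep import IndexMap

from conftest import bilayer_spec, pipeline_index_map


def index_map_from(n_arr, pixel_size=1.0, n_bar=None):
    n_arr = np.asarray(n_arr, dtype=float)
    fill = (n_arr == 1.56).mean()
    return IndexMap(n=n_arr, n_high=1.56, n_low=1.0,
                    n_bar=n_bar or (fill * 1.56 + (1 - fill)),
                    pixel_size=pixel_size)


def sinusoid_map(n=221 * 3, period_px=221):
    rows = np.arange(n)[:, None]
    n_arr = 1.28 + 0.28 * np.sin(2 * np.pi * rows / period_px) * np.ones((1, n))
    return IndexMap(n=n_arr, n_high=1.56, n_low=1.0, n_bar=1.28, pixel_size=1.0)


class TestPowerSpectrum:
    def test_constant_map_has_zero_power(self):
        imap = index_map_from(np.full((32, 32), 1.56), n_bar=1.56)
        ps = power_spectrum_2d(imap)
        assert ps.total_power == pytest.approx(0.0, abs=1e-18)

    def test_sinusoid_concentrates_power_at_its_frequency(self):
        ps = power_spectrum_2d(sinusoid_map())
        n = ps.power.shape[0]
        c = n // 2
        iy, ix = np.unravel_index(np.argmax(ps.power), ps.power.shape)
        # two symmetric peaks at (±1/221, 0) cycles/nm
        assert ix == c
        assert abs(iy - c) * ps.freq_step == pytest.approx(1 / 221, rel=1e-9)
        assert ps.power[2 * c - iy, ix] == pytest.approx(ps.power[iy, ix])

    def test_parseval_conservation(self, rng):
        x = rng.choice([1.0, 1.56], size=(48, 48))
        imap = index_map_from(x)
        ps = power_spectrum_2d(imap)
        assert ps.total_power == pytest.approx(((x - x.mean()) ** 2).sum(),
                                               rel=1e-10)

    def test_point_symmetry_for_real_input(self, rng):
        imap = index_map_from(rng.choice([1.0, 1.56], size=(32, 32)))
        p = power_spectrum_2d(imap).power
        # power(k) == power(-k); with an even-size fftshift the Nyquist
        # row/column has no mirror partner, so compare the interior
        interior = p[1:, 1:]
        assert np.allclose(interior, interior[::-1, ::-1], rtol=1e-9)

    def test_requires_square_and_minimum_size(self):
        with pytest.raises(ValueError, match="square"):
            power_spectrum_2d(index_map_from(np.ones((32, 16))))
        with pytest.raises(ValueError, match="16x16"):
            power_spectrum_2d(index_map_from(np.ones((8, 8))))


class TestRadialAverage:
    def test_sinusoid_peak_bin(self):
        ps = power_spectrum_2d(sinusoid_map())
        prof = radial_average(ps)
        peak_f = prof.bin_centers[np.argmax(prof.mean_power)]
        assert peak_f == pytest.approx(1 / 221, abs=prof.bin_width / 2)

    def test_rotation_and_transposition_invariance(self, rng):
        x = rng.choice([1.0, 1.56], size=(40, 40))
        base = radial_average(power_spectrum_2d(index_map_from(x)))
        for xform in (np.rot90(x), np.rot90(x, 2), x.T):
            prof = radial_average(power_spectrum_2d(index_map_from(xform)))
            assert np.allclose(prof.mean_power, base.mean_power, atol=1e-8)

    def test_percent_power_sums_to_100(self, rng):
        x = rng.choice([1.0, 1.56], size=(40, 40))
        prof = radial_average(power_spectrum_2d(index_map_from(x)))
        assert prof.percent_power.sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_spectrum_gives_zero_profile(self):
        ps = power_spectrum_2d(index_map_from(np.full((32, 32), 1.56), n_bar=1.56))
        prof = radial_average(ps)
        assert (prof.mean_power == 0).all()

    def test_bin_width_bounds(self):
        ps = power_spectrum_2d(sinusoid_map(n=64, period_px=16))
        with pytest.raises(ValueError):
            radial_average(ps, bin_width=0.0)
        with pytest.raises(ValueError):
            radial_average(ps, bin_width=1.0)  # far beyond Nyquist


class TestWavelengthMapping:
    def test_closed_form_values(self):
        assert frequency_to_wavelength(1 / 221, 1.2787) == pytest.approx(
            565.2, abs=0.1)
        assert frequency_to_wavelength(0.004, 1.28) == pytest.approx(640.0)

    def test_doubling_frequency_halves_wavelength(self):
        lam = frequency_to_wavelength(0.003, 1.3)
        assert frequency_to_wavelength(0.006, 1.3) == pytest.approx(lam / 2)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            frequency_to_wavelength(0.0, 1.28)

    def test_visible_band_frequencies(self):
        lo, hi = visible_frequency_band(1.28)
        assert lo == pytest.approx(2 * 1.28 / 700, rel=1e-12)
        assert hi == pytest.approx(2 * 1.28 / 350, rel=1e-12)
        assert (lo, hi) == (pytest.approx(0.003657, abs=1e-6),
                            pytest.approx(0.007314, abs=1e-6))


class TestPredictedSpectrum:
    def test_single_bin_profile_maps_exactly(self):
        f0 = 0.0045
        centers = np.array([0.003, f0, 0.006])
        power = np.array([0.0, 10.0, 0.0])
        prof = RadialProfile(bin_centers=centers, mean_power=power,
                             percent_power=power * 10, bin_width=0.0015,
                             n_bar=1.28)
        spec = predicted_reflectance(prof, interpolate_peak=False)
        assert spec.lambda_max == pytest.approx(2 * 1.28 / f0)

    def test_full_pipeline_basal_stack(self, basal_spec):
        spec = analyze_index_map(pipeline_index_map(basal_spec))
        assert spec.lambda_max == pytest.approx(565.2, abs=2.0)

    def test_lambda_max_monotone_in_period(self):
        peaks = []
        for hi, lo in [(80, 80), (95, 95), (110, 110), (125, 125)]:
            spec = analyze_index_map(pipeline_index_map(bilayer_spec(hi, lo)))
            peaks.append(spec.lambda_max_unrestricted)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_out_of_band_peak_reported_unrestricted(self):
        # 150/141 nm stack: fundamental at 750 nm lies outside 350-700
        spec = analyze_index_map(pipeline_index_map(bilayer_spec(150, 141)))
        assert spec.lambda_max_unrestricted == pytest.approx(750.0, abs=2.0)
        assert 350 <= spec.lambda_max <= 700

    def test_nbar_outside_physical_range_rejected(self):
        prof = RadialProfile(bin_centers=np.array([0.004]),
                             mean_power=np.array([1.0]),
                             percent_power=np.array([100.0]),
                             bin_width=0.001, n_bar=1.28)
        with pytest.raises(ValueError):
            predicted_reflectance(prof, n_bar=2.5)
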