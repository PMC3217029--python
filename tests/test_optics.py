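"""Perforation morphometrics, grating orders, and multilayer oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scalecolor.image_prep import PhaseMap
from scalecolor.optics import (
    GratingSpec,
    StackSpec,
    ideal_multilayer_peak,
    open_fraction,
    perforation_factor,
    propagating_orders,
    transfer_matrix_reflectance,
)
from scalecolor.synthetic import PerforatedLaminaSpec, generate_perforated_lamina

from conftest import bilayer_spec, pipeline_index_map
from scalecolor.fourier import analyze_index_map


class TestPerforation:
    def test_limits(self):
        assert open_fraction(np.ones((10, 10))) == 0.0
        assert open_fraction(np.zeros((10, 10))) == 1.0

    def test_distal_lamina_geometry(self):
        img = generate_perforated_lamina(PerforatedLaminaSpec(
            width_px=500, height_px=500, pitch_px=50, hole_radius_px=16))
        p = open_fraction(img.pixels)
        assert p == pytest.approx(math.pi * 16**2 / 50**2, abs=0.01)
        assert p == pytest.approx(0.32, abs=0.01)

    def test_proximal_lamina_geometry(self):
        img = generate_perforated_lamina(PerforatedLaminaSpec(
            width_px=504, height_px=504, pitch_px=63, hole_radius_px=8))
        assert open_fraction(img.pixels) == pytest.approx(0.05, abs=0.005)

    def test_phase_map_interface_and_invert(self):
        mask = np.ones((20, 20), dtype=np.uint8)
        mask[:4] = 0  # 20% open under the open=0 convention
        stats = perforation_factor(PhaseMap(mask, 1.0))
        assert stats.p == pytest.approx(0.2)
        assert stats.open_pixels == 80 and stats.total_pixels == 400
        inverted = perforation_factor(PhaseMap(mask, 1.0), invert=True)
        assert inverted.p == pytest.approx(0.8)


class TestGratingOrders:
    def test_subwavelength_microribs_are_zero_order(self):
        g = GratingSpec(period_d=140.0)
        for lam in range(350, 701, 10):
            assert propagating_orders(g, float(lam)) == 0

    def test_ridge_grating_order_count(self):
        # |m|*565/1800 <= 1 for |m| <= 3
        assert propagating_orders(GratingSpec(period_d=1800.0), 565.0) == 6

    def test_wavelength_exceeding_period_cuts_off(self):
        assert propagating_orders(GratingSpec(period_d=500.0), 600.0) == 0

    def test_oblique_incidence_breaks_symmetry(self):
        g = GratingSpec(period_d=1000.0, incidence_angle=30.0)
        # m=-1: |0.5-0.9|=0.4 ok; m=+1: |0.5+0.9|=1.4 cut off
        assert propagating_orders(g, 900.0) == 1

    @given(d=st.floats(min_value=100, max_value=4000),
           d2=st.floats(min_value=0, max_value=2000))
    @settings(deadline=None, max_examples=40)
    def test_order_count_nondecreasing_in_period(self, d, d2):
        lam = 565.0
        a = propagating_orders(GratingSpec(period_d=d), lam)
        b = propagating_orders(GratingSpec(period_d=d + d2), lam)
        assert b >= a


class TestIdealMultilayer:
    @pytest.mark.parametrize("d1,n1,d2,n2,expected", [
        (110, 1.56, 111, 1.0, 565.2),
        (86, 1.56, 86, 1.0, 440.32),
        (150, 1.56, 141, 1.0, 750.0),
        (107, 1.56, 108, 1.0, 549.84),
    ])
    def test_closed_form(self, d1, n1, d2, n2, expected):
        assert ideal_multilayer_peak(d1, n1, d2, n2) == pytest.approx(expected)

    def test_quarter_wave_identity(self):
        lam0 = 565.0
        assert ideal_multilayer_peak(lam0 / (4 * 1.56), 1.56,
                                     lam0 / 4, 1.0) == pytest.approx(lam0)


class TestTransferMatrix:
    def test_no_layers_no_interface(self):
        stack = StackSpec(layers=[], n_ambient=1.0, n_substrate=1.0)
        refl = transfer_matrix_reflectance(stack, np.arange(350, 701, 50))
        assert np.allclose(refl, 0.0)

    def test_energy_bound(self, rng):
        for _ in range(5):
            layers = [(float(rng.uniform(1.0, 2.0)), float(rng.uniform(40, 200)))
                      for _ in range(rng.integers(1, 9))]
            stack = StackSpec(layers=layers, n_substrate=1.5)
            refl = transfer_matrix_reflectance(stack, np.arange(350, 701, 10))
            assert np.all(refl >= 0) and np.all(refl <= 1 + 1e-12)

    def test_quarter_wave_stack_peaks_at_design_wavelength(self):
        lam0 = 565.0
        stack = StackSpec.bilayers(1.56, lam0 / (4 * 1.56), 1.0, lam0 / 4, 5)
        grid = np.arange(400.0, 701.0)
        refl = transfer_matrix_reflectance(stack, grid)
        assert grid[np.argmax(refl)] == pytest.approx(lam0, abs=2.0)
        assert refl.max() < 1.0  # a 5-bilayer chitin/air stack is non-ideal

    def test_peak_sharpens_and_grows_with_bilayer_count(self):
        lam0 = 565.0
        grid = np.arange(400.0, 701.0)
        peaks = []
        for count in range(2, 11, 2):
            stack = StackSpec.bilayers(1.56, lam0 / (4 * 1.56), 1.0, lam0 / 4,
                                       count)
            refl = transfer_matrix_reflectance(stack, grid)
            peaks.append(refl.max())
            assert grid[np.argmax(refl)] == pytest.approx(lam0, abs=3.0)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))


class TestCrossModuleOracle:
    def test_fourier_peak_matches_closed_form_on_randomized_stacks(self, rng):
        """The Fourier pipeline on exact periodic two-phase stacks must
        agree with 2*(n1*d1 + n2*d2) within one mapped frequency bin."""
        for _ in range(8):
            d1 = float(rng.integers(40, 161))
            d2 = float(rng.integers(40, 161))
            spec = bilayer_spec(d1, d2)
            out = analyze_index_map(pipeline_index_map(spec))
            ideal = ideal_multilayer_peak(d1, 1.56, d2, 1.0)
            f_peak = 2 * out.n_bar / ideal
            df = 1.0 / (spec.height_px * spec.pixel_size)
            tol = 2 * out.n_bar / (f_peak - df) - ideal
            assert abs(out.lambda_max_unrestricted - ideal) <= tol
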