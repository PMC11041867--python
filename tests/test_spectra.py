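import numpy as np
import pytest

from enfret.spectra import (
    Spectrum,
    StickSpectrum,
    broaden,
    fwhm_to_sigma,
    normalize_unit_area,
    read_spectrum,
    read_sticks,
    spectral_overlap,
    write_spectrum,
)


def gaussian_spectrum(center, sigma, lo, hi, step=0.5, normalized=True):
    grid = np.arange(lo, hi + step, step)
    intensity = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    spec = Spectrum(grid, intensity)
    return normalize_unit_area(spec) if normalized else spec


class TestSpectrumInvariants:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            Spectrum([1.0, 1.0, 2.0], [0, 0, 0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Spectrum([0.0, 1.0], [1.0, -0.1])

    def test_normalized_flag_checked(self):
        with pytest.raises(ValueError):
            Spectrum([0.0, 1.0], [5.0, 5.0], normalized=True)


class TestBroaden:
    def test_single_stick_area_equals_strength(self):
        grid = np.arange(0.0, 4000.0, 0.5)
        spec = broaden(StickSpectrum([2000.0], [3.2]), fwhm=150.0, grid=grid)
        assert spec.area == pytest.approx(3.2, abs=1e-6)
        assert grid[np.argmax(spec.intensity)] == pytest.approx(2000.0, abs=0.5)

    def test_resolved_doublet(self):
        grid = np.arange(0.0, 6000.0, 1.0)
        spec = broaden(StickSpectrum([2000.0, 4000.0], [1.0, 1.0]), 200.0, grid)
        interior = spec.intensity[1:-1]
        n_maxima = int(
            np.sum((interior > spec.intensity[:-2]) & (interior > spec.intensity[2:]))
        )
        assert n_maxima == 2

    def test_three_stick_progression_three_peaks(self):
        # Franck–Condon progression → the three-peaked band shape
        grid = np.arange(15000.0, 26000.0, 1.0)
        sticks = StickSpectrum([19000.0, 20400.0, 21800.0], [1.0, 1.0, 0.5])
        spec = broaden(sticks, 600.0, grid)
        interior = spec.intensity[1:-1]
        n_maxima = int(
            np.sum((interior > spec.intensity[:-2]) & (interior > spec.intensity[2:]))
        )
        assert n_maxima == 3

    def test_uncovered_sticks_error_lists_positions(self):
        grid = np.arange(0.0, 2100.0, 1.0)
        with pytest.raises(ValueError, match="3000"):
            broaden(StickSpectrum([1000.0, 3000.0], [1.0, 1.0]), 200.0, grid)

    def test_invalid_fwhm(self):
        with pytest.raises(ValueError):
            broaden(StickSpectrum([1.0], [1.0]), 0.0, np.arange(0, 10.0, 1.0))


class TestNormalize:
    def test_idempotent(self):
        spec = gaussian_spectrum(1000, 100, 0, 2000)
        again = normalize_unit_area(spec)
        np.testing.assert_allclose(again.intensity, spec.intensity, atol=1e-12)

    def test_scale_invariant(self):
        raw = gaussian_spectrum(1000, 100, 0, 2000, normalized=False)
        doubled = Spectrum(raw.grid, 2.0 * raw.intensity)
        np.testing.assert_allclose(
            normalize_unit_area(doubled).intensity,
            normalize_unit_area(raw).intensity,
            rtol=1e-12,
        )

    def test_uniform_density(self):
        spec = normalize_unit_area(Spectrum(np.linspace(0, 100, 201), np.ones(201)))
        np.testing.assert_allclose(spec.intensity, 0.01, rtol=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            normalize_unit_area(Spectrum([0.0, 1.0], [0.0, 0.0]))


class TestSpectralOverlap:
    def test_identical_gaussians_analytic(self):
        # self-overlap of a unit-area Gaussian: 1/(2σ√π)
        spec = gaussian_spectrum(20000, 100, 19000, 21000, step=0.5)
        expected = 1.0 / (2.0 * 100.0 * np.sqrt(np.pi))
        assert spectral_overlap(spec, spec) == pytest.approx(expected, rel=1e-4)

    def test_disjoint_spectra_zero(self):
        a = gaussian_spectrum(1000, 50, 500, 1500)
        b = gaussian_spectrum(9000, 50, 8500, 9500)
        assert spectral_overlap(a, b) == 0.0

    def test_symmetric_in_arguments(self):
        a = gaussian_spectrum(20000, 150, 18000, 22000)
        b = gaussian_spectrum(20500, 150, 18500, 22500)
        assert spectral_overlap(a, b) == pytest.approx(spectral_overlap(b, a), rel=1e-12)

    def test_cauchy_schwarz_self_overlap_dominates(self):
        a = gaussian_spectrum(20000, 150, 18000, 23000)
        for shift in (100, 400, 900):
            b = gaussian_spectrum(20000 + shift, 150, 18000, 23000)
            assert spectral_overlap(a, a) >= spectral_overlap(a, b)

    def test_monotone_decrease_with_displacement(self):
        a = gaussian_spectrum(20000, 150, 17000, 24000)
        overlaps = [
            spectral_overlap(a, gaussian_spectrum(20000 + s, 150, 17000, 24000))
            for s in (0, 100, 250, 500, 1000, 1500)
        ]
        assert all(x > y for x, y in zip(overlaps, overlaps[1:]))

    def test_grid_refinement_converged(self):
        coarse = gaussian_spectrum(20000, 100, 19000, 21000, step=1.0)
        fine = gaussian_spectrum(20000, 100, 19000, 21000, step=0.5)
        j1 = spectral_overlap(coarse, coarse)
        j2 = spectral_overlap(fine, fine)
        assert abs(j2 - j1) / j1 < 1e-4

    def test_unnormalized_inputs_normalized_internally(self):
        raw = gaussian_spectrum(20000, 100, 19000, 21000, normalized=False)
        norm = normalize_unit_area(raw)
        assert spectral_overlap(raw, raw) == pytest.approx(
            spectral_overlap(norm, norm), rel=1e-12
        )

    def test_unequal_grids_interpolated(self):
        a = gaussian_spectrum(20000, 200, 18000, 22000, step=0.5)
        b = gaussian_spectrum(20000, 200, 18100.3, 21900.7, step=1.7)
        expected = 1.0 / (2.0 * 200.0 * np.sqrt(np.pi))
        assert spectral_overlap(a, b) == pytest.approx(expected, rel=1e-3)


class TestSpectraIO:
    def test_round_trip(self, tmp_path):
        spec = gaussian_spectrum(1000, 100, 0, 2000)
        p = tmp_path / "spec.csv"
        write_spectrum(spec, p)
        back = read_spectrum(p)
        np.testing.assert_allclose(back.grid, spec.grid)
        np.testing.assert_allclose(back.intensity, spec.intensity, rtol=1e-12)

    def test_comments_and_tsv(self, tmp_path):
        p = tmp_path / "sticks.tsv"
        p.write_text("# vibronic sticks\nposition_cm-1\tstrength\n19000\t1.0\n20400\t0.8\n")
        sticks = read_sticks(p)
        np.testing.assert_allclose(sticks.positions, [19000, 20400])
        np.testing.assert_allclose(sticks.strengths, [1.0, 0.8])
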