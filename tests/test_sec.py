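"""SEC chromatogram simulation, peak deconvolution and CD unmixing."""

import numpy as np
import pytest

from tetraswap.sec import (
    Chromatogram,
    GaussianPeak,
    Spectrum,
    fit_peaks,
    read_chromatogram,
    simulate_chromatogram,
    unmix_two_state_spectra,
    write_chromatogram,
)

SQRT_2PI = np.sqrt(2.0 * np.pi)

# peak geometry of a light-chain monomer/tetramer separation: tetramer ~13.1 mL,
# monomer ~16.4 mL
TET = GaussianPeak(center=13.1, sigma=0.35, amplitude=1.0)
MONO = GaussianPeak(center=16.4, sigma=0.35, amplitude=1.0)


def peaks_for_areas(area_tet: float, area_mono: float) -> list[GaussianPeak]:
    return [
        GaussianPeak(TET.center, TET.sigma, area_tet / (TET.sigma * SQRT_2PI)),
        GaussianPeak(MONO.center, MONO.sigma, area_mono / (MONO.sigma * SQRT_2PI)),
    ]


class TestSimulate:
    def test_trapezoid_area_matches_gaussian_formula(self):
        grid = np.linspace(TET.center - 6 * TET.sigma, TET.center + 6 * TET.sigma, 2001)
        chrom = simulate_chromatogram([TET], noise_sd=0.0, volume_grid=grid)
        area = np.trapezoid(chrom.absorbance, chrom.volumes)
        assert area == pytest.approx(TET.area, rel=1e-3)

    def test_same_seed_is_bitwise_identical(self):
        a = simulate_chromatogram([TET, MONO], noise_sd=0.01, seed=42)
        b = simulate_chromatogram([TET, MONO], noise_sd=0.01, seed=42)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_chromatogram([TET], volume_grid=np.array([]))

    def test_chromatogram_validates_monotone_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            Chromatogram(volumes=np.array([1.0, 1.0, 2.0]), absorbance=np.zeros(3))


class TestFitPeaks:
    def test_noise_free_exact_recovery(self):
        chrom = simulate_chromatogram([TET, MONO], baseline=(0.05, 0.001), noise_sd=0.0)
        fit = fit_peaks(chrom, 2)
        assert fit.success
        for got, want in zip(fit.peaks, [TET, MONO]):
            assert got.center == pytest.approx(want.center, rel=1e-6)
            assert got.sigma == pytest.approx(want.sigma, rel=1e-6)
            assert got.amplitude == pytest.approx(want.amplitude, rel=1e-6)
        assert fit.baseline[0] == pytest.approx(0.05, abs=1e-6)
        assert fit.baseline[1] == pytest.approx(0.001, abs=1e-7)

    def test_4_96_ratio_yields_f_mono(self):
        chrom = simulate_chromatogram(peaks_for_areas(96.0, 4.0), noise_sd=0.0)
        fit = fit_peaks(chrom, 2)
        # monomer elutes last: f_mono is the relative area of the last peak
        assert fit.f_mono == pytest.approx(0.04, abs=1e-4)

    def test_area_ratio_recovered_within_one_percent(self):
        chrom = simulate_chromatogram(peaks_for_areas(96.0, 4.0), noise_sd=0.0)
        fit = fit_peaks(chrom, 2)
        ratio = fit.peaks[0].area / fit.peaks[-1].area
        assert ratio == pytest.approx(96.0 / 4.0, rel=0.01)

    def test_total_area_invariant_to_constant_baseline_shift(self):
        base = simulate_chromatogram([TET, MONO], noise_sd=0.0)
        shifted = Chromatogram(base.volumes, base.absorbance + 0.5)
        area0 = sum(p.area for p in fit_peaks(base, 2).peaks)
        area1 = sum(p.area for p in fit_peaks(shifted, 2).peaks)
        assert area1 == pytest.approx(area0, rel=1e-6)

    def test_noisy_replicates_recover_fraction(self):
        """At SNR 50, f_mono lands within ±0.02 of truth in >=95% of replicates."""
        f_true = 0.3
        peaks = peaks_for_areas(1.0 - f_true, f_true)
        noise_sd = max(p.amplitude for p in peaks) / 50.0
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            chrom = simulate_chromatogram(peaks, noise_sd=noise_sd, seed=5000 + i)
            fit = fit_peaks(chrom, 2)
            if abs(fit.f_mono - f_true) <= 0.02:
                hits += 1
        assert hits >= 95

    def test_too_short_trace_rejected(self):
        chrom = Chromatogram(np.linspace(10, 20, 30), np.zeros(30))
        with pytest.raises(ValueError, match="too short"):
            fit_peaks(chrom, 2)

    def test_coincident_init_centers_rejected(self):
        chrom = simulate_chromatogram([TET, MONO], noise_sd=0.0)
        with pytest.raises(ValueError, match="coincident"):
            fit_peaks(chrom, 2, init=[TET, GaussianPeak(TET.center, 0.3, 0.5)])


class TestUnmix:
    wavelengths = np.linspace(200.0, 260.0, 121)

    def _bases(self):
        # toy monomer/tetramer ellipticity bases; the tetramer has the deeper
        # beta-sheet band near 215 nm
        w = self.wavelengths
        mono = -2.0 * np.exp(-0.5 * ((w - 215.0) / 12.0) ** 2)
        tet = -5.0 * np.exp(-0.5 * ((w - 215.0) / 8.0) ** 2)
        return Spectrum(w, mono), Spectrum(w, tet)

    def test_pure_states_pass_through(self):
        mono, tet = self._bases()
        got_m, got_t = unmix_two_state_spectra(mono, 1.0, tet, 0.0)
        assert np.allclose(got_m.signal, mono.signal)
        assert np.allclose(got_t.signal, tet.signal)

    def test_roundtrip_with_sec_fractions(self):
        """Mix at the 61:39 / 14:86 compositions, then unmix exactly."""
        mono, tet = self._bases()
        f_a, f_b = 0.61, 0.14
        spec_a = Spectrum(self.wavelengths, f_a * mono.signal + (1 - f_a) * tet.signal)
        spec_b = Spectrum(self.wavelengths, f_b * mono.signal + (1 - f_b) * tet.signal)
        got_m, got_t = unmix_two_state_spectra(spec_a, f_a, spec_b, f_b)
        assert np.allclose(got_m.signal, mono.signal, atol=1e-10)
        assert np.allclose(got_t.signal, tet.signal, atol=1e-10)
        # remix reproduces the observations
        remix = f_a * got_m.signal + (1 - f_a) * got_t.signal
        assert np.allclose(remix, spec_a.signal, atol=1e-10)

    def test_equal_fractions_singular(self):
        mono, tet = self._bases()
        with pytest.raises(ValueError, match="singular|close"):
            unmix_two_state_spectra(mono, 0.5, tet, 0.5)

    def test_mismatched_grids_rejected(self):
        mono, tet = self._bases()
        other = Spectrum(self.wavelengths + 1.0, tet.signal)
        with pytest.raises(ValueError, match="grid"):
            unmix_two_state_spectra(mono, 0.61, other, 0.14)


def test_chromatogram_csv_roundtrip(tmp_path):
    chrom = simulate_chromatogram([TET], noise_sd=0.001, seed=9)
    path = tmp_path / "chrom.csv"
    write_chromatogram(chrom, path)
    back = read_chromatogram(path)
    assert np.allclose(back.volumes, chrom.volumes)
    assert np.allclose(back.absorbance, chrom.absorbance)
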