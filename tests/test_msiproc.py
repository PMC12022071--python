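"""Spectral chain oracles: Savitzky-Golay, SNIP, MAD, TIC, peaks, AUC."""

import numpy as np
import pytest

from plaquemap import synthio
from plaquemap.containers import MSIDataset, Spectrum, read_imzml, write_imzml
from plaquemap.msiproc import (
    PreprocessParams,
    detect_peaks,
    estimate_noise_mad,
    peak_auc,
    preprocess_roi_spectra,
    smooth_savgol,
    snip_baseline,
    tic_normalize,
)
from plaquemap.panel import build_abeta_panel
from plaquemap.synthio import CohortSpec, simulate_roi_spectra


def _spec(intensity, mz=None):
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = 1500.0 + np.arange(intensity.size)
    return Spectrum(mz, intensity)


def _snip_reference(values, iterations):
    """Textbook SNIP (LLS transform + decreasing clipping window), looped."""
    y = np.log(np.log(np.sqrt(values + 1.0) + 1.0) + 1.0)
    n = y.size
    for m in range(min(iterations, n - 1), 0, -1):
        z = y.copy()
        for i in range(n):
            lo = y[max(i - m, 0)]
            hi = y[min(i + m, n - 1)]
            z[i] = min(y[i], 0.5 * (lo + hi))
        y = z
    base = (np.exp(np.exp(y) - 1.0) - 1.0) ** 2 - 1.0
    return np.minimum(np.clip(base, 0, None), values)


class TestSavgol:
    def test_cubic_polynomial_reproduced(self):
        x = np.arange(200, dtype=float)
        vals = 1e-4 * x**3 - 0.02 * x**2 + x + 5
        out = smooth_savgol(_spec(vals), half_window=10, poly_order=3)
        np.testing.assert_allclose(out.intensity, vals, rtol=1e-8, atol=1e-8)

    def test_quadratic_kernel_from_impulse(self):
        """Window 5, order 2: impulse response reads (-3,12,17,12,-3)/35."""
        vals = np.zeros(51)
        vals[25] = 1.0
        out = smooth_savgol(_spec(vals), half_window=2, poly_order=2)
        expected = np.array([-3, 12, 17, 12, -3]) / 35.0
        np.testing.assert_allclose(out.intensity[23:28], expected, atol=1e-12)

    def test_constant_unchanged(self):
        out = smooth_savgol(_spec(np.full(64, 4.2)))
        np.testing.assert_allclose(out.intensity, 4.2)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_savgol(_spec(np.ones(10)), half_window=10)


class TestSnip:
    def test_zero_spectrum_gives_zero_baseline(self):
        out = snip_baseline(_spec(np.zeros(128)))
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_flat_baseline_under_gaussian_peak(self):
        """Flat baseline c + narrow Gaussian: SNIP recovers c within 5%."""
        c = 2.0
        x = np.arange(400, dtype=float)
        peak = 50 * c * np.exp(-((x - 200) ** 2) / (2 * (5 / 2.355) ** 2))
        out = snip_baseline(_spec(c + peak), iterations=100)
        under_peak = out.intensity[195:206]
        assert np.all(np.abs(under_peak - c) < 0.05 * c)

    def test_matches_reference_implementation(self, rng):
        vals = np.clip(
            5 + 3 * np.sin(np.linspace(0, 3, 300))
            + 40 * np.exp(-((np.arange(300) - 120) ** 2) / 18.0)
            + rng.normal(0, 0.2, 300),
            0, None)
        ours = snip_baseline(_spec(vals), iterations=40).intensity
        ref = _snip_reference(vals, 40)
        np.testing.assert_allclose(ours, ref, rtol=1e-10, atol=1e-10)

    def test_baseline_monotone_in_iterations(self):
        c = 1.0
        x = np.arange(600, dtype=float)
        vals = c + 30 * np.exp(-((x - 300) ** 2) / 50.0)
        under = []
        for n_it in (25, 50, 100):
            base = snip_baseline(_spec(vals), iterations=n_it).intensity
            under.append(base[295:306].mean())
        assert under[0] >= under[1] >= under[2] - 1e-12

    def test_negative_intensities_rejected(self):
        s = Spectrum(np.arange(10, dtype=float) + 1500, np.zeros(10))
        s.intensity[3] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            snip_baseline(s)


class TestNoiseMad:
    def test_constant_spectrum_zero(self):
        assert estimate_noise_mad(_spec(np.full(32, 5.0))) == 0.0

    def test_alternating_unit_deviation(self):
        vals = np.tile([1.0, -1.0], 50)
        assert estimate_noise_mad(_spec(vals)) == pytest.approx(1.4826)

    def test_consistency_for_gaussian_noise(self, rng):
        vals = rng.normal(0.0, 2.0, 100_000)
        est = estimate_noise_mad(_spec(vals))
        assert est == pytest.approx(2.0, rel=0.02)


class TestTic:
    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.1, 5, 100)
        a = tic_normalize(_spec(vals)).intensity
        b = tic_normalize(_spec(5 * vals)).intensity
        np.testing.assert_allclose(a, b)

    def test_sum_equals_target(self, rng):
        out = tic_normalize(_spec(rng.uniform(0, 2, 64)), target=3.5)
        assert out.intensity.sum() == pytest.approx(3.5)

    def test_zero_spectrum_raises(self):
        with pytest.raises(ValueError, match="zero-TIC"):
            tic_normalize(_spec(np.zeros(16)))


class TestDetectPeaks:
    def _gauss(self, x, mu, height, fwhm=4.0):
        return height * np.exp(-((x - mu) ** 2) / (2 * (fwhm / 2.355) ** 2))

    def test_single_strong_peak_found_at_apex(self, rng):
        x = 1500.0 + np.arange(500)
        noise = rng.normal(0, 1.0, 500)
        vals = self._gauss(x, 1750, 10 * 1.4826) + noise
        peaks = detect_peaks(_spec(vals, x), snr_threshold=2.0, noise=1.4826)
        strong = [p for p in peaks if abs(p[0] - 1750) < 3]
        assert len(strong) == 1

    def test_subthreshold_peak_ignored(self):
        x = 1500.0 + np.arange(300)
        vals = self._gauss(x, 1650, 1.5)
        peaks = detect_peaks(_spec(vals, x), snr_threshold=2.0, noise=1.0)
        assert peaks == []

    def test_two_separated_gaussians(self):
        x = 1500.0 + np.arange(400)
        fwhm = 4.0
        vals = self._gauss(x, 1600, 50, fwhm) + self._gauss(x, 1600 + 3 * fwhm, 40, fwhm)
        peaks = detect_peaks(_spec(vals, x), noise=1.0)
        assert len(peaks) == 2
        assert abs(peaks[0][0] - 1600) <= 1
        assert abs(peaks[1][0] - 1612) <= 1

    def test_count_monotone_in_threshold(self, rng):
        x = 1500.0 + np.arange(1000)
        vals = np.clip(rng.normal(2, 1.0, 1000), 0, None)
        for mu, h in [(1600, 5), (1700, 10), (1800, 20), (1900, 3)]:
            vals += self._gauss(x, mu, h)
        counts = [len(detect_peaks(_spec(vals, x), snr_threshold=t, noise=1.0))
                  for t in (1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts, reverse=True)


class TestPeakAuc:
    def test_constant_rectangle(self):
        s = _spec(np.full(100, 3.0))
        # window [1520, 1540] -> width 20, AUC 60
        assert peak_auc(s, 1530.0, 10.0) == pytest.approx(60.0)

    def test_triangle_closed_form(self):
        x = 1500.0 + np.arange(101, dtype=float)
        h, half_base = 10.0, 20.0
        vals = np.clip(h * (1 - np.abs(x - 1550) / half_base), 0, None)
        auc = peak_auc(_spec(vals, x), 1550.0, half_base)
        assert auc == pytest.approx(h * half_base, rel=0.02)

    def test_too_narrow_window_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            peak_auc(_spec(np.ones(50)), 1525.0, 0.2)


class TestRoiChain:
    def test_noise_free_cp_roi_all_peptides_detected(self, panel):
        spec = CohortSpec(groups={"sAD": 1}, technical_cv=0,
                          intra_patient_cv=0, inter_patient_cv=0, seed=0)
        spectra, meta = simulate_roi_spectra(spec, plaque_types=("CP",),
                                             n_plaques_per_type=1)
        table = preprocess_roi_spectra(spectra, panel=panel, roi_meta=meta)
        for pep in panel:
            assert table.loc[0, pep.name] > 0
            assert not table.loc[0, f"below_noise_{pep.name}"]

    def test_fold_change_recovery_through_full_chain(self, panel):
        """Planted CP:DP fold 3 at 10% technical CV, 15 ROIs each:
        median AUC ratio lands in [2.2, 3.8]."""
        spec = CohortSpec(groups={"sAD": 5}, technical_cv=0.10,
                          intra_patient_cv=0.0, inter_patient_cv=0.0, seed=31)
        spectra, meta = simulate_roi_spectra(spec, plaque_types=("DP", "CP"),
                                             n_plaques_per_type=3)
        table = preprocess_roi_spectra(spectra, panel=panel, roi_meta=meta)
        med = table.groupby("plaque_type")["Abeta1-40"].median()
        ratio = med["CP"] / med["DP"]
        assert 2.2 <= ratio <= 3.8

    def test_snip_auc_recovers_ratios_noise_free(self, panel):
        """SNIP subtraction + trapezoid AUC on raw-scale noise-free spectra
        recovers planted amplitude ratios to < 1%."""
        spec = CohortSpec(groups={"sAD": 1}, technical_cv=0,
                          intra_patient_cv=0, inter_patient_cv=0, seed=0)
        spectra, _ = simulate_roi_spectra(spec, plaque_types=("DP", "CP"),
                                          n_plaques_per_type=1,
                                          detector_sigma=0.0)
        by_type = {s.meta["plaque_type"]: s for s in spectra}
        pep = next(p for p in panel if p.name == "Abeta3pE-42")
        aucs = {}
        for kind, s in by_type.items():
            base = snip_baseline(s, 100)
            resid = s.copy_with(s.intensity - base.intensity)
            aucs[kind] = peak_auc(resid, pep.mz_obs, pep.mz_obs / 1000)
        assert aucs["CP"] / aucs["DP"] == pytest.approx(3.0, rel=0.01)

    def test_pixel_order_invariance(self, panel):
        """Permuting pixels inside an ROI leaves its PeakTable row unchanged."""
        scene, truth = synthio.make_microscopy_scene(
            counts={"CP": 1}, field_um=(200, 200), rng_seed=2)
        msi, truth = synthio.make_msi_dataset(truth, panel, noise_cv=0.05,
                                              rng_seed=3, mz_step=2.0)
        mask = truth.msi_instance_map == 1
        t1 = preprocess_roi_spectra(msi, {1: mask}, panel)
        # swap the contents of two ROI pixels: same multiset of spectra
        iy, ix = np.argwhere(mask)[:2].T
        cube = msi.cube.copy()
        cube[iy[0], ix[0]], cube[iy[1], ix[1]] = \
            msi.cube[iy[1], ix[1]].copy(), msi.cube[iy[0], ix[0]].copy()
        msi2 = MSIDataset(msi.mz, cube, msi.pitch_um)
        t2 = preprocess_roi_spectra(msi2, {1: mask}, panel)
        for pep in panel:
            assert t1.loc[0, pep.name] == pytest.approx(t2.loc[0, pep.name],
                                                        rel=1e-6)

    def test_empty_roi_rejected(self, panel):
        scene, truth = synthio.make_microscopy_scene(
            counts={"CP": 1}, field_um=(200, 200), rng_seed=2)
        msi, truth = synthio.make_msi_dataset(truth, panel, rng_seed=3,
                                              mz_step=2.0)
        empty = np.zeros(msi.shape, dtype=bool)
        with pytest.raises(ValueError, match="no MSI pixels"):
            preprocess_roi_spectra(msi, {"bad": empty}, panel)


def test_imzml_roundtrip(tmp_path, panel):
    """Continuous-mode imzML write/read preserves the cube."""
    scene, truth = synthio.make_microscopy_scene(
        counts={"CP": 1}, field_um=(150, 150), rng_seed=4)
    msi, _ = synthio.make_msi_dataset(truth, panel, rng_seed=5, mz_step=10.0)
    path = write_imzml(msi, tmp_path / "test.imzML")
    back = read_imzml(path)
    np.testing.assert_allclose(back.cube, msi.cube, rtol=1e-6)
    np.testing.assert_allclose(back.mz, msi.mz)


def test_preprocess_params_validation():
    with pytest.raises(ValueError):
        PreprocessParams(sg_half_window=0)
    with pytest.raises(ValueError):
        PreprocessParams(snr_threshold=0)
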