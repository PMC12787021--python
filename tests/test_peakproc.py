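"""Baseline correction, denoising, peak picking, pseudo-Voigt fitting,
lineshape QC."""

import math

import numpy as np
import pytest

from qnmr1d import peakproc as pk
from qnmr1d import simulate as sim

from conftest import FREQ, make_simspec, singlet


def lorentz(x, c, w, a=1.0):
    return a / (1.0 + 4.0 * ((x - c) / w) ** 2)


class TestAirpls:
    def test_zero_signal_zero_baseline(self):
        base, corr = pk.baseline_airpls(np.zeros(100))
        assert np.allclose(base, 0.0)
        assert np.allclose(corr, 0.0)

    def test_linear_ramp_recovered_under_peak(self):
        x = np.arange(800, dtype=float)
        ramp = 0.5 + 0.002 * x
        y = ramp + 50.0 * lorentz(x, 400.0, 8.0)
        base, _ = pk.baseline_airpls(y, lam=1e5)
        rms = np.sqrt(np.mean((base - ramp) ** 2))
        assert rms < 0.01 * (ramp.max() - ramp.min())

    def test_peak_free_flanks_preserved(self):
        x = np.arange(600, dtype=float)
        y = 10.0 * lorentz(x, 300.0, 6.0) + 2.0
        _, corr = pk.baseline_airpls(y, lam=1e5)
        flanks = np.r_[corr[:50], corr[-50:]]
        assert abs(flanks.mean()) < 0.01 * y.max()

    def test_baseline_below_signal_at_peak(self):
        x = np.arange(500, dtype=float)
        y = 20.0 * lorentz(x, 250.0, 5.0) + 0.001 * x
        base, _ = pk.baseline_airpls(y, lam=1e5)
        assert base[250] < y[250]

    def test_non_finite_rejected(self):
        y = np.zeros(50)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pk.baseline_airpls(y)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pk.baseline_airpls(np.zeros(5))


class TestDenoise:
    def test_smooth_signal_almost_unchanged(self):
        x = np.linspace(0, 1, 1024)
        y = np.exp(-0.5 * ((x - 0.5) / 0.05) ** 2)
        out = pk.denoise_wavelet(y)
        assert np.sqrt(np.mean((out - y) ** 2)) < 1e-3 * np.sqrt(
            np.mean(y ** 2))

    def test_zero_in_zero_out(self):
        assert np.allclose(pk.denoise_wavelet(np.zeros(256)), 0.0)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=2048)
        out = pk.denoise_wavelet(y)
        assert np.var(out) < np.var(y)

    def test_peak_maximum_not_moved(self):
        x = np.arange(1024, dtype=float)
        y = lorentz(x, 512.0, 12.0)
        out = pk.denoise_wavelet(y)
        assert abs(int(np.argmax(out)) - 512) < 1

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            pk.denoise_wavelet(np.zeros(128), family="nope42")


class TestPickPeaks:
    def test_flat_signal_no_candidates(self):
        assert pk.pick_peaks(np.zeros(200), noise_sd=0.0).size == 0
        assert pk.pick_peaks(np.full(200, 3.0), noise_sd=0.0).size == 0

    def test_second_derivative_resolves_close_doublet(self):
        """Two equal Lorentzians 1.2 FWHM apart give two second-derivative
        minima; at 0.5 FWHM, where plain intensity maxima have merged into
        one, the second derivative still resolves both lines."""
        w = 20.0
        x = np.arange(1000, dtype=float)
        y = lorentz(x, 488.0, w) + lorentz(x, 488.0 + 1.2 * w, w)
        assert pk.pick_peaks(y, noise_sd=0.0).size == 2
        y2 = lorentz(x, 480.0, w) + lorentz(x, 480.0 + 0.5 * w, w)
        maxima = [i for i in range(1, 999)
                  if y2[i] > y2[i - 1] and y2[i] > y2[i + 1]]
        assert len(maxima) == 1
        assert pk.pick_peaks(y2, noise_sd=0.0).size == 2

    def test_low_snr_candidates_suppressed(self):
        rng = np.random.default_rng(5)
        noise_sd = 1.0
        x = np.arange(512, dtype=float)
        y = 2.0 * lorentz(x, 256.0, 10.0) + rng.normal(0, noise_sd, 512)
        y = pk.denoise_wavelet(y)
        cand = pk.pick_peaks(y, noise_sd=noise_sd, snr_min=3.0)
        assert cand.size == 0  # peak is at S/N 2

    def test_snr_floor_is_three(self):
        """Even snr_min < 3 never returns sub-S/N-3 features."""
        rng = np.random.default_rng(6)
        noise_sd = 1.0
        x = np.arange(512, dtype=float)
        y = 2.0 * lorentz(x, 256.0, 10.0) + rng.normal(0, noise_sd, 512)
        cand = pk.pick_peaks(pk.denoise_wavelet(y), noise_sd=noise_sd,
                             snr_min=0.5)
        assert cand.size == 0

    def test_noise_estimate_required(self):
        with pytest.raises(ValueError, match="noise"):
            pk.pick_peaks(np.zeros(100), noise_sd=None)

    def test_repeatable_on_noisy_replicates(self):
        """Pick+denoise finds exactly 3 peaks in >= 95% of seeded noisy
        replicates of a 3-peak region at S/N 10."""
        x = np.arange(1500, dtype=float)
        clean = (10.0 * lorentz(x, 300.0, 12.0)
                 + 10.0 * lorentz(x, 750.0, 12.0)
                 + 10.0 * lorentz(x, 1150.0, 12.0))
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 1.0, clean.size)
            cand = pk.pick_peaks(pk.denoise_wavelet(y), noise_sd=1.0)
            if cand.size == 3:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestFitPeaks:
    def test_symmetric_lorentzian_self_consistency(self):
        x_ppm = np.linspace(9.3, 9.0, 1600)
        truth = dict(amplitude=50.0, center_hz=9.14 * FREQ, fwhm_hz=1.0,
                     eta=1.0)
        y = pk.pseudo_voigt(x_ppm * FREQ, truth["amplitude"],
                            truth["center_hz"], truth["fwhm_hz"],
                            truth["eta"])
        rep = pk.fit_peaks(x_ppm, y, np.array([int(np.argmax(y))]), FREQ,
                           fit_asym=False)
        p = rep.peaks[0]
        assert rep.converged
        assert p.amplitude == pytest.approx(50.0, rel=1e-6)
        assert p.center_ppm * FREQ == pytest.approx(truth["center_hz"],
                                                    rel=1e-6)
        assert p.fwhm_hz == pytest.approx(1.0, rel=1e-6)
        assert p.eta == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_pseudo_voigt_recovery(self):
        x_ppm = np.linspace(5.1, 4.9, 2000)
        y = pk.pseudo_voigt(x_ppm * FREQ, 20.0, 5.0 * FREQ, 1.5, 0.6, 0.2)
        rep = pk.fit_peaks(x_ppm, y, np.array([int(np.argmax(y))]), FREQ)
        p = rep.peaks[0]
        assert p.amplitude == pytest.approx(20.0, rel=1e-4)
        assert p.fwhm_hz == pytest.approx(1.5, rel=1e-4)
        assert p.eta == pytest.approx(0.6, abs=1e-4)
        assert p.asym == pytest.approx(0.2, rel=1e-3)

    def test_overlapped_doublet_total_area_conserved(self):
        x_ppm = np.linspace(2.95, 2.80, 2400)
        x_hz = x_ppm * FREQ
        c = 2.871 * FREQ
        y = (pk.pseudo_voigt(x_hz, 30.0, c - 2.25, 1.0, 1.0)
             + pk.pseudo_voigt(x_hz, 30.0, c + 2.25, 1.0, 1.0))
        gen_area = 2 * 30.0 * 1.0 * math.pi / 2
        cand = pk.pick_peaks(y, noise_sd=0.0)
        rep = pk.fit_peaks(x_ppm, y, cand, FREQ, fit_asym=False)
        assert len(rep.peaks) == 2
        assert sum(p.area for p in rep.peaks) == pytest.approx(
            gen_area, rel=5e-3)

    def test_candidates_outside_roi_dropped(self):
        x_ppm = np.linspace(1.1, 0.9, 500)
        y = pk.pseudo_voigt(x_ppm * FREQ, 5.0, 1.0 * FREQ, 1.0, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            rep = pk.fit_peaks(x_ppm, y,
                               np.array([int(np.argmax(y)), 9999]), FREQ)
        assert len(rep.peaks) == 1

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            pk.fit_peaks(np.linspace(1, 0, 50), np.zeros(50),
                         np.array([], dtype=int), FREQ)


class TestPeakArea:
    def test_lorentzian_closed_form(self):
        p = pk.PeakModel(center_ppm=0, amplitude=1.0, fwhm_hz=1.0, eta=1.0)
        assert p.area == pytest.approx(math.pi / 2)

    def test_gaussian_closed_form(self):
        p = pk.PeakModel(center_ppm=0, amplitude=1.0, fwhm_hz=1.0, eta=0.0)
        assert p.area == pytest.approx(0.5 * math.sqrt(math.pi / math.log(2)))

    @pytest.mark.parametrize("eta", [0.0, 0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("fwhm", [0.5, 1.0, 2.0])
    def test_closed_form_matches_quadrature(self, eta, fwhm):
        from scipy.integrate import quad
        p = pk.PeakModel(center_ppm=0, amplitude=2.0, fwhm_hz=fwhm, eta=eta)
        num, _ = quad(lambda f: 2.0 * (
            eta / (1 + 4 * (f / fwhm) ** 2)
            + (1 - eta) * math.exp(-4 * math.log(2) * (f / fwhm) ** 2)),
            -200 * fwhm, 200 * fwhm, limit=400)
        # closed form carries the Lorentzian tail beyond any finite window:
        # 2 * integral_{200w}^{inf} A*eta / (1 + (2f/w)^2) df
        tail = eta * 2.0 * fwhm * (math.pi / 2 - math.atan(400.0))
        assert p.area == pytest.approx(num + tail, rel=1e-6)

    def test_asymmetric_area_against_trapezoid(self):
        """Adaptive quadrature agrees with a high-resolution trapezoid
        oracle over the same +-50 FWHM window."""
        p = pk.PeakModel(center_ppm=0, amplitude=1.0, fwhm_hz=1.0, eta=0.5,
                         asym=0.2)
        f = np.linspace(-50, 50, 2_000_001)
        num = np.trapezoid(pk.pseudo_voigt(f, 1.0, 0.0, 1.0, 0.5, 0.2), f)
        assert p.area == pytest.approx(num, rel=1e-6)


class TestLinewidthQC:
    def tmsp_spectrum(self, fwhm):
        spec = make_simspec([(sim.tmsp_pattern(500.0).pattern, 500.0)],
                            fwhm_hz=fwhm, points=65536)
        return sim.render_spectrum(spec)

    def test_narrow_tmsp_passes(self):
        out = pk.qc_linewidth(self.tmsp_spectrum(0.6))
        assert out["passed"]
        assert out["fwhm_hz"] == pytest.approx(0.6, rel=0.02)

    def test_broad_tmsp_fails(self):
        out = pk.qc_linewidth(self.tmsp_spectrum(1.4))
        assert not out["passed"]
        assert out["fwhm_hz"] == pytest.approx(1.4, rel=0.02)

    def test_missing_peak_reported(self):
        s = sim.render_spectrum(make_simspec([], points=16384))
        out = pk.qc_linewidth(s)
        assert not out["passed"]
        assert out["reason"]
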