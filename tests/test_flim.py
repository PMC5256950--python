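"""Decay model, per-pixel fitting, quality filters, FRET and IPS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.integrate import quad

from nanoflim.containers import GaussianIRF
from nanoflim.flim import (
    CHI2_MAX,
    DecayModel,
    FlimImageFit,
    LifetimeImage,
    apply_filters,
    cluster_lifetime_distribution,
    fit_pixel,
    fret_efficiency,
    fret_percent,
    ips_fraction,
    model_decay,
)

WIDTH = 25000.0 / 256.0
IRF = GaussianIRF(center_ps=10 * WIDTH, fwhm_ps=300.0)
DELTA_IRF = GaussianIRF(center_ps=0.0, fwhm_ps=0.0)


class TestModelDecay:
    def test_delta_irf_is_pure_exponential(self):
        m = model_decay(DecayModel("mono", (2000.0,), (1e5,)), DELTA_IRF, 256, WIDTH)
        ratios = m[1:200] / m[:199]
        assert np.allclose(ratios, np.exp(-WIDTH / 2000.0), rtol=1e-9)

    def test_bi_with_zero_amplitude_reduces_to_mono(self):
        mono = model_decay(DecayModel("mono", (2000.0,), (1e4,)), IRF, 256, WIDTH)
        bi = model_decay(DecayModel("bi", (1000.0, 2000.0), (0.0, 1e4)),
                         IRF, 256, WIDTH)
        assert np.allclose(mono, bi, rtol=1e-12)

    def test_baseline_adds_flat_offset(self):
        m0 = model_decay(DecayModel("mono", (2000.0,), (1e4,)), IRF, 256, WIDTH)
        m1 = model_decay(DecayModel("mono", (2000.0,), (1e4,), baseline=3.0),
                         IRF, 256, WIDTH)
        assert np.allclose(m1 - m0, 3.0)

    def test_convolution_matches_quadrature(self):
        # independent oracle: direct numeric integration of the wrapped
        # IRF (x) exponential over each channel
        tau, period, sigma, mu = 2402.0, 25000.0, IRF.sigma_ps, IRF.center_ps
        norm = 1.0 / (np.sqrt(2 * np.pi) * sigma)

        def pdf(t):
            def integrand(s):
                return (np.exp(-s / tau) / tau
                        * norm * np.exp(-((t - s - mu) ** 2) / (2 * sigma**2)))
            # the Gaussian factor confines the integrand to t - mu +/- 10 sigma
            lo = max(0.0, t - mu - 10 * sigma)
            hi = max(t - mu + 10 * sigma, 0.0)
            if hi <= lo:
                return 0.0
            val, _ = quad(integrand, lo, hi, limit=500,
                          epsabs=1e-16, epsrel=1e-12)
            return val

        m = model_decay(DecayModel("mono", (2402.0,), (1.0,)), IRF, 256, WIDTH)
        for ch in (5, 10, 12, 40, 120):
            target, _ = quad(
                lambda t: pdf(t) + pdf(t + period) + pdf(t + 2 * period),
                ch * WIDTH, (ch + 1) * WIDTH, limit=500,
                epsabs=1e-16, epsrel=1e-10,
            )
            assert m[ch] == pytest.approx(target, rel=1e-6)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            DecayModel("mono", (1000.0, 2000.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            DecayModel("bi", (2000.0, 1000.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            DecayModel("tri", (1000.0,), (1.0,))


class TestFitPixel:
    def test_noise_free_mono_recovery(self):
        hist = model_decay(DecayModel("mono", (2000.0,), (1e5,)), IRF, 256, WIDTH)
        fit = fit_pixel(hist, IRF, WIDTH)
        assert fit.converged
        assert fit.tau_mean_ps == pytest.approx(2000.0, rel=0.005)

    def test_neyman_objective_also_recovers(self):
        hist = model_decay(DecayModel("mono", (2000.0,), (1e5,)), IRF, 256, WIDTH)
        fit = fit_pixel(hist, IRF, WIDTH, objective="neyman")
        assert fit.tau_mean_ps == pytest.approx(2000.0, rel=0.005)

    def test_measured_irf_histogram_supported(self):
        centers = (np.arange(256) + 0.5) * WIDTH
        irf_hist = np.exp(-((centers - IRF.center_ps) ** 2)
                          / (2 * IRF.sigma_ps**2))
        hist = model_decay(DecayModel("mono", (2000.0,), (1e5,)), IRF, 256, WIDTH)
        fit = fit_pixel(hist, irf_hist, WIDTH)
        assert fit.tau_mean_ps == pytest.approx(2000.0, rel=0.01)

    def test_empty_histogram_not_converged(self):
        fit = fit_pixel(np.zeros(256), IRF, WIDTH)
        assert not fit.converged

    def test_pure_baseline_pixel_rejected_by_filters(self):
        fit = fit_pixel(np.full(256, 10.0), IRF, WIDTH)
        image = apply_filters(FlimImageFit(
            np.array([[fit.tau_mean_ps]]), np.array([[fit.chi2]]),
            np.array([[fit.chi2_pearson]]), np.array([[fit.photons]]),
            np.array([[fit.converged]]), np.array([[0.8]])))
        assert image.n_accepted == 0

    def test_bias_small_at_high_and_low_photons(self):
        from nanoflim.simulate import FlimSimParams, simulate_decay_cube
        from nanoflim.flim import fit_image

        for photons, tol in ((10000, 0.01), (1200, 0.05)):
            cube, _ = simulate_decay_cube(FlimSimParams(
                shape=(8, 8), f_interacting=0.0, photons_mean=photons,
                photons_min=50, seed=21))
            fits = fit_image(cube)
            tau = fits.tau_map_ps[fits.converged]
            assert abs(tau.mean() - 2402.0) / 2402.0 < tol


class TestFilters:
    def _fits(self, tau, chi2, photons):
        one = np.ones((1, 1))
        return FlimImageFit(one * tau, one * chi2, one, (one * photons).astype(int),
                            one.astype(bool), one * 0.02)

    def test_photon_boundary_strict(self):
        assert apply_filters(self._fits(2000, 1.0, 1199)).n_accepted == 0
        assert apply_filters(self._fits(2000, 1.0, 1200)).n_accepted == 1

    def test_chi2_boundary_strict(self):
        assert apply_filters(self._fits(2000, 2.0, 5000)).n_accepted == 0
        assert apply_filters(self._fits(2000, 1.999, 5000)).n_accepted == 1

    def test_tau_range_inclusive(self):
        assert apply_filters(self._fits(1500, 1.0, 5000)).n_accepted == 1
        assert apply_filters(self._fits(2500, 1.0, 5000)).n_accepted == 1
        assert apply_filters(self._fits(1499.9, 1.0, 5000)).n_accepted == 0

    def test_zero_accepted_flagged_empty(self):
        image = apply_filters(self._fits(900, 1.0, 5000))
        assert image.empty
        assert np.isnan(image.mean_tau_ps)

    def test_donor_only_acceptance_rate(self, donor_fits):
        fits, _ = donor_fits
        image = apply_filters(fits)
        assert image.n_accepted / fits.tau_map_ps.size >= 0.95

    def test_chi2_calibration_pearson(self, donor_fits):
        # correctly specified fits: Pearson reduced chi-square averages 1
        fits, _ = donor_fits
        vals = fits.chi2_pearson_map[fits.converged]
        assert vals.size >= 200
        assert abs(vals.mean() - 1.0) < 0.1

    def test_donor_lifetime_recovered_within_sem(self, donor_image):
        image, gt = donor_image
        assert abs(image.mean_tau_ps - gt.tau_donor_ps) < 3 * image.sem_tau_ps + 5


class TestFret:
    def test_printed_lifetime_pairs(self):
        assert fret_efficiency(2227.0, 2402.0) == pytest.approx(0.0729, abs=2e-4)
        assert fret_percent(2227.0, 2402.0) == 7
        assert fret_percent(2241.0, 2402.0) == 7

    def test_equal_lifetimes_zero(self):
        assert fret_efficiency(2402.0, 2402.0) == 0.0

    def test_half_lifetime(self):
        assert fret_efficiency(1201.0, 2402.0) == pytest.approx(0.500, abs=1e-3)

    def test_no_fret_flagged_negative(self):
        assert fret_efficiency(2500.0, 2402.0) < 0

    @given(st_.floats(min_value=100.0, max_value=2402.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotone_in_tau_da(self, tau_da):
        e = fret_efficiency(tau_da, 2402.0)
        assert 0.0 <= e < 1.0
        assert fret_efficiency(tau_da * 0.99, 2402.0) > e


class TestIPS:
    def _image(self, tau_map, accepted=None):
        tau_map = np.asarray(tau_map, dtype=float)
        if accepted is None:
            accepted = np.ones_like(tau_map, dtype=bool)
        vals = tau_map[accepted]
        mean = float(vals.mean()) if vals.size else float("nan")
        return LifetimeImage(tau_map, accepted,
                             np.full(tau_map.shape, 3000, dtype=int),
                             mean, 0.0, int(accepted.sum()))

    def test_donor_only_zero_percent(self):
        image = self._image(np.full((10, 10), 2402.0))
        assert ips_fraction(image, 2402.0).ips_percent == 0.0

    def test_strong_quench_hundred_percent(self):
        image = self._image(np.full((10, 10), 1201.0))
        assert ips_fraction(image, 2402.0).ips_percent == 100.0

    def test_threshold_value(self):
        res = ips_fraction(self._image(np.full((2, 2), 2402.0)), 2402.0, 0.13)
        assert res.tau_threshold_ps == pytest.approx(2402.0 * 0.87)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        tau = np.where(rng.random((20, 20)) < 0.15, 1800.0, 2402.0)
        a = ips_fraction(self._image(tau), 2402.0).ips_percent
        flat = tau.ravel()
        rng.shuffle(flat)
        b = ips_fraction(self._image(flat.reshape(20, 20)), 2402.0).ips_percent
        assert a == b

    def test_known_fraction_recovered_exactly(self):
        rng = np.random.default_rng(5)
        labels = rng.random((40, 40)) < 0.15
        tau = np.where(labels, 1801.5, 2402.0)
        res = ips_fraction(self._image(tau), 2402.0)
        assert res.ips_percent == pytest.approx(100.0 * labels.mean())

    def test_no_accepted_pixels_undefined(self):
        image = self._image(np.full((4, 4), 2000.0),
                            accepted=np.zeros((4, 4), dtype=bool))
        assert np.isnan(ips_fraction(image, 2402.0).ips_percent)


class TestClusterLifetimes:
    def _image(self, tau_map, photons):
        return LifetimeImage(np.asarray(tau_map, float),
                             np.ones_like(np.asarray(tau_map), dtype=bool),
                             np.asarray(photons, int), 0.0, 0.0,
                             int(np.asarray(tau_map).size))

    def test_no_bright_pixels_gives_empty_list(self):
        image = self._image(np.full((8, 8), 2400.0), np.full((8, 8), 100))
        assert cluster_lifetime_distribution(image, min_photons=2000).size == 0

    def test_two_cluster_mixture_is_bimodal(self):
        tau = np.full((20, 20), 2400.0)
        photons = np.full((20, 20), 100)
        tau[2:5, 2:5] = 2400.0
        tau[12:15, 12:15] = 1800.0
        photons[2:5, 2:5] = 2500
        photons[12:15, 12:15] = 2500
        taus = np.sort(cluster_lifetime_distribution(self._image(tau, photons)))
        assert taus.size == 2
        assert taus[0] == pytest.approx(1800.0)
        assert taus[1] == pytest.approx(2400.0)
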