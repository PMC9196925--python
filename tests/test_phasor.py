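"""Frequency-domain deconvolution, phasor geometry, and the 36-feature pool."""

import time

import numpy as np
import pytest

from maflim.core import AcquisitionConfig, harmonic_label
from maflim import simulate as sim
from maflim.preprocess import concat_irf, pad_and_concatenate, preprocess_image
from maflim.phasor import (
    PHASOR_POOL,
    extract_phasor_pool,
    fit_phasor_gaussian,
    frequency_deconvolve,
    harmonic_frequencies,
    normalize_concat,
    phasor_pair_features,
)
from maflim.timedomain import fit_biexponential_image


def _mono_concat(config, irf, tau, intensity=500.0):
    """Concatenated decay with one lifetime and equal intensity in all channels."""
    params = sim.RegionDecayParams(
        {ch: sim.DecayParams(1.0, tau, tau, intensity) for ch in (390, 452, 500)}
    )
    scene = sim.SceneSpec(region1_params=params, region2_params=params,
                          noise_model=None, offset=0.0, seed=0)
    img = sim.generate_lesion_image(scene, config, irf)
    return pad_and_concatenate(img).data[0, 0]


class TestNormalize:
    def test_unit_sum_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        sig = rng.random((5, 40)) + 0.1
        out = normalize_concat(sig)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose(normalize_concat(100.0 * sig), out)

    def test_zero_sum_flagged(self):
        out = normalize_concat(np.zeros(10))
        assert np.isnan(out).all()

    def test_deconvolution_invariant_to_normalisation(self, config, irf):
        y = _mono_concat(config, irf, 2.0)
        u = concat_irf(irf, config.n_samples_per_channel)
        P1 = frequency_deconvolve(y, u)
        P2 = frequency_deconvolve(normalize_concat(y), u)
        np.testing.assert_allclose(P1, P2, atol=1e-12)


class TestHarmonics:
    def test_frequency_resolution(self, config):
        freqs = harmonic_frequencies(config)
        assert len(freqs) == 9
        assert freqs[0] == pytest.approx(2.5e9 / 447)
        assert round(freqs[0] / 1e6, 1) == 5.6
        assert freqs[8] == pytest.approx(9 * freqs[0])
        assert freqs[8] < 60e6

    def test_nominal_labels(self):
        assert harmonic_label(1) == "5.6"
        assert harmonic_label(7) == "39.2"
        assert harmonic_label(9) == "50.4"


class TestFrequencyDeconvolve:
    def test_signal_equal_irf_gives_unity(self, config, irf):
        u = concat_irf(irf, config.n_samples_per_channel)
        P = frequency_deconvolve(u, u)
        np.testing.assert_allclose(P, 1.0 + 0.0j, atol=1e-12)

    def test_identical_channel_irfs_are_ill_posed(self, config):
        """Identical per-channel pulses null every harmonic not divisible by 3."""
        irf_same = sim.generate_irf(config, fwhm_ns=1.0, t0_ns=4.0)
        u = concat_irf(irf_same, config.n_samples_per_channel)
        with pytest.raises(ValueError, match="ill-posed"):
            frequency_deconvolve(u.copy(), u)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 3.0])
    def test_monoexponential_on_universal_semicircle(self, config, irf, tau):
        y = _mono_concat(config, irf, tau)
        u = concat_irf(irf, config.n_samples_per_channel)
        P = frequency_deconvolve(y, u)
        G, S = P.real, P.imag
        assert np.all(S > 0)
        np.testing.assert_allclose((G - 0.5) ** 2 + S**2, 0.25, atol=5e-3)

    def test_recovers_analytic_normalized_response(self, config, irf):
        """Forward-convolved biexponential deconvolves to its continuous
        normalised frequency response (tau small enough that the acquisition
        window truncates nothing)."""
        a, tf, ts = 0.6, 0.5, 2.2
        params = sim.RegionDecayParams(
            {ch: sim.DecayParams(a, tf, ts, 400.0) for ch in (390, 452, 500)}
        )
        scene = sim.SceneSpec(region1_params=params, region2_params=params,
                              noise_model=None, offset=0.0, seed=0)
        img = sim.generate_lesion_image(scene, config, irf)
        y = pad_and_concatenate(img).data[0, 0]
        u = concat_irf(irf, config.n_samples_per_channel)
        P = frequency_deconvolve(y, u)
        w = 2 * np.pi * harmonic_frequencies(config) * 1e-9  # rad/ns
        H = a * tf / (1 + 1j * w * tf) + (1 - a) * ts / (1 + 1j * w * ts)
        H0 = a * tf + (1 - a) * ts
        np.testing.assert_allclose(P, np.conj(H / H0), atol=1e-6)

    def test_biexponential_is_phasor_mixture(self, config, irf):
        """Biexponential phasor = intensity-weighted mix of the two mono phasors."""
        a, tf, ts = 0.7, 0.6, 2.5
        u = concat_irf(irf, config.n_samples_per_channel)
        params = sim.RegionDecayParams(
            {ch: sim.DecayParams(a, tf, ts, 400.0) for ch in (390, 452, 500)}
        )
        scene = sim.SceneSpec(region1_params=params, region2_params=params,
                              noise_model=None, offset=0.0, seed=0)
        img = sim.generate_lesion_image(scene, config, irf)
        P = frequency_deconvolve(pad_and_concatenate(img).data[0, 0], u)
        P_f = frequency_deconvolve(_mono_concat(config, irf, tf), u)
        P_s = frequency_deconvolve(_mono_concat(config, irf, ts), u)
        frac_fast = a * tf / (a * tf + (1 - a) * ts)
        np.testing.assert_allclose(
            P, frac_fast * P_f + (1 - frac_fast) * P_s, atol=1e-6
        )

    def test_lifetime_agrees_with_time_domain_fit(self, config, irf):
        """Phasor-derived lifetime matches the reconvolution fit within 1%."""
        tau = 2.8
        params = sim.RegionDecayParams(
            {ch: sim.DecayParams(1.0, tau, tau, 500.0) for ch in (390, 452, 500)}
        )
        scene = sim.SceneSpec(region1_params=params, region2_params=params,
                              noise_model=None, offset=0.0, seed=0)
        img = sim.generate_lesion_image(scene, config, irf)
        P = frequency_deconvolve(
            pad_and_concatenate(img).data[0, 0],
            concat_irf(irf, config.n_samples_per_channel),
        )
        w = 2 * np.pi * harmonic_frequencies(config) * 1e-9
        tau_phasor = P.imag / (w * P.real)
        maps = fit_biexponential_image(img, irf).channels[452]
        tau_fit = maps.tau_avg[0, 0]
        np.testing.assert_allclose(tau_phasor, tau_fit, rtol=0.01)


class TestPhasorGaussian:
    def test_identical_points(self):
        pts = np.tile([0.3, 0.2], (5, 1))
        mean, cov = fit_phasor_gaussian(pts)
        np.testing.assert_allclose(mean, [0.3, 0.2])
        np.testing.assert_allclose(cov, 0.0, atol=1e-15)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(5)
        mu = np.array([0.4, 0.3])
        Sigma = np.array([[0.04, 0.015], [0.015, 0.01]])
        pts = rng.multivariate_normal(mu, Sigma, size=10_000)
        mean, cov = fit_phasor_gaussian(pts)
        np.testing.assert_allclose(mean, mu, rtol=0.05, atol=0.01)
        np.testing.assert_allclose(cov, Sigma, rtol=0.05)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(300, 2)) @ np.diag([2.0, 0.5]) + [1.0, -1.0]
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m1, c1 = fit_phasor_gaussian(pts)
        m2, c2 = fit_phasor_gaussian(pts @ R.T)
        np.testing.assert_allclose(m2, R @ m1, atol=1e-12)
        np.testing.assert_allclose(c2, R @ c1 @ R.T, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_phasor_gaussian(np.array([[0.1, 0.2], [0.3, 0.4]]))


class TestPairFeatures:
    def test_identical_distributions_all_zero(self):
        m = np.array([0.3, 0.3])
        c = np.array([[0.02, 0.0], [0.0, 0.01]])
        d, sp, ang, sym = phasor_pair_features(m, c, m, c)
        assert (d, sp, ang, sym) == (0.0, 0.0, 0.0, 0.0)

    def test_three_four_five_distance(self):
        c = np.eye(2) * 0.01
        d, *_ = phasor_pair_features([0.2, 0.1], c, [0.5, 0.5], c)
        assert d == pytest.approx(0.5)

    def test_rotated_anisotropic_covariances(self):
        c1 = np.diag([4.0, 1.0])
        c2 = np.diag([1.0, 4.0])  # c1 rotated by 90 degrees
        d, sp, ang, sym = phasor_pair_features([0, 0], c1, [0, 0], c2)
        assert d == 0.0
        assert sp == pytest.approx(0.0, abs=1e-12)
        assert ang == pytest.approx(90.0)
        assert sym == pytest.approx(0.0, abs=1e-12)

    def test_region_swap_symmetry(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(2, 2))
        B = rng.normal(size=(2, 2))
        c1, c2 = A @ A.T, B @ B.T
        m1, m2 = rng.normal(size=2), rng.normal(size=2)
        assert phasor_pair_features(m1, c1, m2, c2) == phasor_pair_features(
            m2, c2, m1, c1
        )

    def test_degenerate_minor_axis_flags_symmetry(self):
        c1 = np.diag([1.0, 0.0])
        c2 = np.diag([2.0, 1.0])
        *_, sym = phasor_pair_features([0, 0], c1, [0, 0], c2)
        assert np.isnan(sym)

    def test_spread_frobenius_option(self):
        c1 = np.diag([2.0, 1.0])
        c2 = np.diag([1.0, 1.0])
        _, sp, *_ = phasor_pair_features([0, 0], c1, [0, 0], c2,
                                         spread_mode="frobenius")
        assert sp == pytest.approx(1.0)


class TestExtractPhasorPool:
    def test_pool_has_36_named_features(self, processed_noiseless, irf, config):
        feats = extract_phasor_pool(
            processed_noiseless.concat, irf, processed_noiseless.masks, config
        )
        assert len(feats) == 36
        assert tuple(feats) == PHASOR_POOL
        for name in ("symmetry_39.2MHz", "spread_33.6MHz", "distance_50.4MHz"):
            assert name in feats

    def test_identical_regions_all_zero(self, identical_image, irf, config, disc_masks):
        concat = pad_and_concatenate(identical_image)
        feats = extract_phasor_pool(concat, irf, disc_masks, config)
        for name, value in feats.items():
            assert value == pytest.approx(0.0, abs=1e-9), name

    def test_region_relabel_invariance(self, processed_noiseless, irf, config):
        masks = processed_noiseless.masks
        a = extract_phasor_pool(processed_noiseless.concat, irf, masks, config)
        b = extract_phasor_pool(processed_noiseless.concat, irf, masks.swapped(), config)
        for name in a:
            assert a[name] == pytest.approx(b[name], abs=1e-12, nan_ok=True), name

    def test_faster_than_biexponential_fitting(self, noisy_image, irf, config):
        """The fitting-free frequency path beats iterative reconvolution."""
        proc = preprocess_image(noisy_image, seed=0)
        t0 = time.perf_counter()
        extract_phasor_pool(proc.concat, irf, proc.masks, config)
        t_phasor = time.perf_counter() - t0
        t0 = time.perf_counter()
        fit_biexponential_image(proc.image, irf, valid=proc.masks.valid)
        t_fit = time.perf_counter() - t0
        assert t_phasor < t_fit


def test_phasor_histogram_counts_all_points():
    from maflim.phasor import phasor_histogram

    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0.1, 0.9, 500), rng.uniform(0.05, 0.5, 500)])
    counts, ge, se = phasor_histogram(pts, bins=32)
    assert counts.sum() == 500
    assert counts.shape == (32, 32)
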