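"""Demodulator tests: spiral filter, HST quadrature, FT and PCA-TPS baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcqpm as L
import lcqpm.simulator as sim
from conftest import make_scene


class TestSpiralFilter:
    def test_axis_values_and_dc(self):
        vals = L.spiral_filter((16, 16)).values
        cy, cx = 8, 8
        assert vals[cy, cx] == 0.0
        assert vals[cy, cx + 1] == pytest.approx(1.0)
        assert vals[cy + 1, cx] == pytest.approx(1j)

    @given(st.integers(4, 64), st.integers(4, 64))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_unit_magnitude_and_antisymmetry(self, rows, cols):
        vals = L.spiral_filter((rows, cols)).values
        cy, cx = rows // 2, cols // 2
        mag = np.abs(vals)
        assert mag[cy, cx] == 0.0
        mag[cy, cx] = 1.0
        np.testing.assert_allclose(mag, 1.0, atol=1e-12)
        # P(-z) = -P(z) on the symmetric part of the grid
        sub = vals[cy - 1 : cy + 2, cx - 1 : cx + 2]
        np.testing.assert_allclose(sub[::-1, ::-1], -sub, atol=1e-12)


class TestHSTQuadrature:
    def test_cosine_maps_to_sine(self, tilt_cosine):
        pair = L.hst_quadrature(tilt_cosine, 0.0)
        x = np.arange(256)
        true = np.sin(2 * np.pi * x[None, :] / 8.0) * np.ones((256, 1))
        err = (pair.s_H - true)[16:-16, 16:-16]
        assert np.sqrt(np.mean(err**2)) < 0.01  # amplitude is 1

    def test_circular_fringes_quadrature(self, circular_fringes):
        img, arg = circular_fringes
        _, dm = L.fringe_direction(img, 1.0, 4.0)
        pair = L.hst_quadrature(img, dm)
        true = np.sin(arg)
        inner = (slice(16, -16), slice(16, -16))
        err = np.minimum(np.abs(pair.s_H - true),
                         np.abs(pair.s_H + true))[inner]
        assert np.sqrt(np.mean(err**2)) < 0.02 * 1.0 + 0.02

    def test_linearity(self, tilt_cosine):
        s1 = tilt_cosine
        rng = np.random.default_rng(0)
        s2 = rng.normal(size=s1.shape)
        s2 -= s2.mean()
        h = lambda s: L.hst_quadrature(s, 0.3).s_H
        lhs = h(2.0 * s1 + 0.5 * s2)
        rhs = 2.0 * h(s1) + 0.5 * h(s2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_quadrature_energy_on_constant_amplitude_fringes(self, tilt_cosine):
        pair = L.hst_quadrature(tilt_cosine, 0.0)
        e = (pair.s**2 + pair.s_H**2)[16:-16, 16:-16]
        assert abs(np.median(e) - 1.0) < 0.02

    def test_nonzero_mean_input_rejected(self, tilt_cosine):
        with pytest.raises(ValueError, match="zero-mean"):
            L.hst_quadrature(tilt_cosine + 0.5, 0.0)

    def test_beta_flip_flips_phase_sign(self, tilt_cosine):
        phi_a = L.hst_demodulate(tilt_cosine, 0.0).phi
        phi_b = L.hst_demodulate(tilt_cosine, np.pi).phi
        inner = (slice(16, -16), slice(16, -16))
        d = L.wrap_phase(phi_a + phi_b)[inner]
        assert np.sqrt(np.mean(d**2)) < 0.05


class TestWrappedPhase:
    def test_quadrant_conventions(self):
        ones = np.ones((4, 4))
        zero = np.zeros((4, 4))
        assert np.all(L.hst_wrapped_phase(L.QuadraturePair(ones, zero)).phi == 0.0)
        assert np.all(L.hst_wrapped_phase(L.QuadraturePair(zero, ones)).phi
                      == pytest.approx(np.pi / 2))

    def test_degenerate_pixels_flagged(self):
        s = np.ones((8, 8))
        s_h = np.zeros((8, 8))
        s[0, 0] = 0.0
        wp = L.hst_wrapped_phase(L.QuadraturePair(s, s_h))
        assert not wp.validity[0, 0]
        assert wp.phi[0, 0] == 0.0

    @staticmethod
    def _wrapped_error(scene):
        obj, phase, car, spec, acq, ig = scene
        fc, pm = L.extract_fringe_component(ig.intensity)
        _, dm = L.fringe_direction(fc.image,
                                   sigma_window=float(np.median(pm.local_period)))
        wp = L.hst_demodulate(fc, dm)
        carrier_phi = 2 * np.pi * sim.carrier_opd_map(car, phase.shape,
                                                      632.0) / 632.0
        target = L.wrap_phase(carrier_phi + phase)
        best = None
        for sgn in (1.0, -1.0):  # global sign is free at this stage
            err = L.wrap_phase(sgn * wp.phi - target)
            err = L.wrap_phase(err - np.median(err))[16:-16, 16:-16]
            if best is None or np.sqrt(np.mean(err**2)) < np.sqrt(
                    np.mean(best**2)):
                best = err
        return obj, best

    def test_tilt_fixture_wrapped_phase_matches_truth(self):
        _, err = self._wrapped_error(make_scene(obj="blobs", snr_db=np.inf,
                                                seed=1))
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_step_fixture_accurate_away_from_edges(self, step_scene):
        # phase discontinuities leave localized edge artifacts (a known
        # limitation of the transform); away from them the error is small
        from scipy.ndimage import binary_dilation
        obj, err = self._wrapped_error(step_scene)
        near = binary_dilation(obj.mask, iterations=4)[16:-16, 16:-16]
        assert np.sqrt(np.mean(err[~near] ** 2)) < 0.05


class TestFTMethod:
    def test_dense_fringes_accurate(self):
        obj, phase, car, spec, acq, ig = make_scene(
            shape=(256, 256), obj="blobs", period=4.0, bandwidth=0.001)
        wp = L.ft_method(ig)
        uw = L.unwrap(wp)
        from scipy.ndimage import binary_dilation
        bg = ~binary_dilation(obj.mask, iterations=3)
        corrected, _ = L.remove_aberration(uw, background_mask=bg)
        from lcqpm.pipeline import rmse_interior
        assert rmse_interior(corrected, phase) < 0.05

    def test_shrinking_window_smooths_phase(self, step_scene):
        obj, phase, car, spec, acq, ig = step_scene
        spec_img = np.fft.fftshift(np.fft.fft2(ig.intensity
                                               - ig.intensity.mean()))
        from lcqpm.phase_recovery import _find_carrier_peak
        peak = _find_carrier_peak(np.abs(spec_img))
        lap_rms = []
        for radius in (24.0, 12.0, 6.0, 3.0):
            wp = L.ft_method(ig, L.SpectralWindow(peak, radius))
            lap = np.abs(np.diff(np.sin(wp.phi), n=2, axis=1))
            lap_rms.append(np.sqrt(np.mean(lap[8:-8, 8:-8] ** 2)))
        assert all(np.diff(lap_rms) < 0)

    def test_no_carrier_raises(self):
        ig = L.Interferogram(np.ones((64, 64)))
        with pytest.raises(ValueError, match="no carrier"):
            L.ft_method(ig)


class TestTPSPCA:
    def test_matches_least_squares_demodulation(self):
        # oracle: closed-form four-step demodulation with known k*pi/2 shifts
        obj, phase, car, spec, acq, _ = make_scene(shape=(256, 256),
                                                   obj="blobs", period=8.0,
                                                   bandwidth=0.001)
        frames = L.phase_shifted_series(phase, car, spec, acq,
                                        [0, np.pi / 2, np.pi, 3 * np.pi / 2])
        wp = L.tps_pca(frames)
        I = [f.intensity for f in frames]
        ls = np.arctan2(I[3] - I[1], I[0] - I[2])
        d = L.wrap_phase(wp.phi - ls)
        d = L.wrap_phase(d - np.median(d))
        assert np.sqrt(np.mean(d[16:-16, 16:-16] ** 2)) < 1e-3

    def test_random_shifts_with_noise(self):
        rng = np.random.default_rng(5)
        obj, phase, car, spec, acq, _ = make_scene(shape=(128, 128),
                                                   obj="blobs", period=8.0,
                                                   bandwidth=0.001,
                                                   snr_db=30.0, seed=5)
        shifts = rng.uniform(0, 2 * np.pi, 8)
        frames = L.phase_shifted_series(phase, car, spec, acq, shifts)
        wp = L.tps_pca(frames)
        carrier_phi = 2 * np.pi * sim.carrier_opd_map(car, phase.shape,
                                                      632.0) / 632.0
        target = L.wrap_phase(carrier_phi + phase)
        d = L.wrap_phase(wp.phi - target)
        d = L.wrap_phase(d - np.median(d))
        assert np.sqrt(np.mean(d[16:-16, 16:-16] ** 2)) < 0.05

    def test_identical_frames_rejected(self):
        obj, phase, car, spec, acq, ig = make_scene(shape=(64, 64))
        with pytest.raises(ValueError, match="rank-deficient"):
            L.tps_pca([ig, ig, ig, ig])

    def test_too_few_frames_rejected(self):
        obj, phase, car, spec, acq, ig = make_scene(shape=(64, 64))
        with pytest.raises(ValueError, match="3 frames"):
            L.tps_pca([ig, ig])
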