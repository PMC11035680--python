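"""Forward-model tests: object phase, coherence envelope, carriers, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcqpm as L
import lcqpm.simulator as sim
from conftest import make_scene


class TestObjectPhase:
    def test_flat_object_has_zero_phase(self):
        spec = L.SpectrumModel(632.0, 10.0)
        obj = L.flat_object((64, 64))
        assert np.all(L.object_phase(obj, spec) == 0.0)

    def test_reflection_step_phase_matches_hand_computation(self):
        # 4 pi H / lambda0 with H = 110 nm, lambda0 = 632 nm
        spec = L.SpectrumModel(632.0, 10.0)
        obj = L.step_text_object((128, 128), 110.0)
        phi = L.object_phase(obj, spec)
        levels = np.unique(phi)
        assert levels[0] == 0.0
        assert levels[-1] == pytest.approx(2.1872, abs=1e-3)

    def test_step_phase_linear_in_height(self):
        spec = L.SpectrumModel(632.0, 10.0)
        a = L.object_phase(L.step_text_object((64, 64), 55.0), spec)
        b = L.object_phase(L.step_text_object((64, 64), 110.0), spec)
        np.testing.assert_allclose(2 * a, b, rtol=1e-12)

    def test_invalid_wavelength_rejected(self):
        with pytest.raises(ValueError):
            L.SpectrumModel(-5.0, 1.0)


class TestVisibilityEnvelope:
    def test_unit_visibility_at_zero_opd(self):
        for shape in ("gaussian", "rect"):
            spec = L.SpectrumModel(550.0, 40.0, shape)
            assert L.visibility_envelope(spec, 0.0) == pytest.approx(1.0)

    def test_laser_keeps_contrast_over_millimetre_opd(self):
        spec = L.SpectrumModel(550.0, 0.001)
        opd = np.linspace(-1e6, 1e6, 101)  # +/- 1 mm in nm
        assert np.all(L.visibility_envelope(spec, opd) > 0.999)

    def test_half_visibility_opd_matches_spectral_superposition(self):
        # oracle: direct 401-wavelength superposition of 1 + cos(2 pi opd/lam),
        # envelope measured as the modulus of the complex coherence sum
        spec = L.SpectrumModel(550.0, 40.0)
        lams, w = spec.sample(401)
        opd = np.linspace(0.0, 8000.0, 4001)
        envelope = np.abs(np.sum(w[:, None] * np.exp(2j * np.pi
                                                     * opd[None, :] / lams[:, None]),
                                 axis=0))
        oracle_half = opd[np.argmin(np.abs(envelope - 0.5))]
        model = L.visibility_envelope(spec, opd)
        model_half = opd[np.argmin(np.abs(model - 0.5))]
        assert model_half == pytest.approx(oracle_half, rel=0.02)

    @given(st.floats(-1e5, 1e5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_even_in_opd(self, opd):
        spec = L.SpectrumModel(550.0, 40.0)
        assert L.visibility_envelope(spec, opd) == \
            pytest.approx(L.visibility_envelope(spec, -opd), abs=1e-14)

    def test_monotone_decay_for_gaussian(self):
        spec = L.SpectrumModel(550.0, 40.0)
        v = L.visibility_envelope(spec, np.linspace(0, 2e4, 200))
        assert np.all(np.diff(v) <= 1e-15)


class TestCarrier:
    def test_tilt_gives_one_fringe_per_period(self):
        car = L.CarrierModel("tilt", 8.0)
        opd = L.carrier_opd_map(car, (64, 64), 550.0)
        dx = np.diff(opd, axis=1)
        np.testing.assert_allclose(dx, 550.0 / 8.0, rtol=1e-12)
        assert np.allclose(np.diff(opd, axis=0), 0.0)

    def test_circular_iso_opd_contours_are_centred_circles(self):
        car = L.CarrierModel("circular", 8.0, center=(32.0, 32.0))
        opd = L.carrier_opd_map(car, (65, 65), 550.0)
        yy, xx = np.mgrid[0:65, 0:65].astype(float)
        rr = (yy - 32.0) ** 2 + (xx - 32.0) ** 2
        # OPD must be a function of radius only
        coeffs = np.polyfit(rr.ravel(), opd.ravel(), 1)
        resid = opd - np.polyval(coeffs, rr)
        assert np.max(np.abs(resid)) < 1e-9 * np.max(np.abs(opd))

    def test_curved_local_period_shrinks_with_radius(self):
        # oracle: numerical gradient of the OPD map along the tilt axis
        car = L.CarrierModel("curved", 12.0)
        opd = L.carrier_opd_map(car, (129, 129), 550.0)
        gx = np.gradient(opd, axis=1)[64]  # central row, nm per px
        local_period = 550.0 / gx[gx > 0]
        assert np.all(np.diff(local_period) < 0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            L.CarrierModel("tilt", 1.5)


class TestSynthesize:
    def test_no_fringes_without_modulation(self):
        spec = L.SpectrumModel(632.0, 10.0)
        car = L.CarrierModel("tilt", 8.0)
        acq = L.AcquisitionModel((64, 64), 1.0, 0.0)
        ig = L.synthesize(np.zeros((64, 64)), car, spec, acq)
        np.testing.assert_allclose(ig.intensity, 1.0)

    def test_laser_tilt_gives_uniform_contrast_everywhere(self):
        _, _, _, _, _, ig = make_scene(shape=(128, 128), obj="flat",
                                       bandwidth=0.001, period=4.0, amp=0.8)
        assert L.usable_fov_fraction(ig, 0.5) > 0.98

    def test_envelope_model_matches_spectral_superposition(self):
        # oracle: direct 201-wavelength sum, up to dl/l0 = 0.2
        for bw in (40.0, 110.0):
            spec = L.SpectrumModel(550.0, bw)
            car = L.CarrierModel("tilt", 6.0)
            acq = L.AcquisitionModel((128, 128), 1.0, 0.5)
            ig = L.synthesize(np.zeros((128, 128)), car, spec, acq)
            lams, w = spec.sample(201)
            opd = sim.carrier_opd_map(car, (128, 128), 550.0)
            direct = 1.0 + 0.5 * np.sum(
                w[:, None, None] * np.cos(2 * np.pi * opd[None] / lams[:, None, None]),
                axis=0)
            rms = np.sqrt(np.mean((ig.intensity - direct) ** 2))
            assert rms < 0.01 * 0.5

    def test_intensities_non_negative_even_at_low_snr(self):
        _, _, _, _, _, ig = make_scene(shape=(64, 64), snr_db=3.0, seed=7)
        assert np.all(ig.intensity >= 0)

    def test_seed_determinism(self):
        a = make_scene(shape=(64, 64), snr_db=20.0, seed=3)[-1]
        b = make_scene(shape=(64, 64), snr_db=20.0, seed=3)[-1]
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_shape_mismatch_rejected(self):
        spec = L.SpectrumModel(632.0, 10.0)
        car = L.CarrierModel("tilt", 8.0)
        acq = L.AcquisitionModel((64, 64), 1.0, 0.5)
        with pytest.raises(ValueError):
            L.synthesize(np.zeros((32, 32)), car, spec, acq)


class TestPhaseShiftedSeries:
    def test_zero_shift_reproduces_single_frame(self):
        obj, phase, car, spec, acq, ig = make_scene(shape=(64, 64))
        frames = L.phase_shifted_series(phase, car, spec, acq, [0.0])
        np.testing.assert_array_equal(frames[0].intensity, ig.intensity)

    def test_antiphase_frames_sum_to_twice_background(self):
        obj, phase, car, spec, acq, _ = make_scene(shape=(64, 64))
        frames = L.phase_shifted_series(phase, car, spec, acq, [0.0, np.pi])
        total = frames[0].intensity + frames[1].intensity
        np.testing.assert_allclose(total, 2.0, atol=1e-10)

    def test_empty_shift_list_rejected(self):
        obj, phase, car, spec, acq, _ = make_scene(shape=(64, 64))
        with pytest.raises(ValueError):
            L.phase_shifted_series(phase, car, spec, acq, [])


class TestUsableFov:
    def test_flat_image_warns_and_returns_zero(self):
        ig = L.Interferogram(np.ones((64, 64)))
        with pytest.warns(UserWarning):
            assert L.usable_fov_fraction(ig, 0.5) == 0.0

    @pytest.mark.parametrize("periods,bandwidths", [
        ((4.0, 6.0, 8.0, 12.0, 24.0), (0.001, 10.0, 25.0, 40.0, 100.0)),
    ])
    def test_fov_fraction_monotone_in_bandwidth_and_carrier(self, periods,
                                                            bandwidths):
        # the low-coherence trade-off: denser fringes or wider spectra shrink
        # the usable field of view
        fracs = np.empty((len(bandwidths), len(periods)))
        for i, bw in enumerate(bandwidths):
            for j, p in enumerate(periods):
                _, _, _, _, _, ig = make_scene(shape=(128, 128), obj="flat",
                                               bandwidth=bw, period=p, amp=0.8)
                fracs[i, j] = L.usable_fov_fraction(ig, 0.5)
        assert np.all(np.diff(fracs, axis=0) <= 0.02)   # bandwidth up -> FoV down
        assert np.all(np.diff(fracs, axis=1) >= -0.02)  # period up -> FoV up
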