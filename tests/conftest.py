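"""Shared fixtures: small simulated scenes with known ground truth."""

import numpy as np
import pytest

import lcqpm as L


def make_scene(shape=(256, 256), obj="step_text", carrier="tilt", period=6.0,
               lambda0=632.0, bandwidth=10.0, snr_db=np.inf, seed=0,
               height_nm=110.0, amp=0.5):
    """Build (object, truth phase, carrier, spectrum, acquisition, frame)."""
    spec = L.SpectrumModel(lambda0, bandwidth)
    car = L.CarrierModel(carrier, period)
    acq = L.AcquisitionModel(shape, 1.0, amp, snr_db=snr_db, rng_seed=seed)
    if obj == "step_text":
        o = L.step_text_object(shape, height_nm)
    elif obj == "blobs":
        o = L.blobs_object(shape, seed=seed)
    else:
        o = L.flat_object(shape)
    phase = L.object_phase(o, spec)
    ig = L.synthesize(phase, car, spec, acq)
    return o, phase, car, spec, acq, ig


@pytest.fixture(scope="session")
def tilt_cosine():
    """Pure vertical fringes cos(2 pi x / 8), zero mean, 256x256."""
    x = np.arange(256)
    s = np.cos(2 * np.pi * x[None, :] / 8.0) * np.ones((256, 1))
    return s - s.mean()


@pytest.fixture(scope="session")
def circular_fringes():
    """Concentric fringe pattern with known quadratic argument, 128x128."""
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    arg = 2 * np.pi * ((yy - 63.5) ** 2 + (xx - 63.5) ** 2) / 512.0
    return np.cos(arg) - np.cos(arg).mean(), arg


@pytest.fixture(scope="session")
def step_scene():
    """Noise-free low-coherence tilt-carrier scene with the glyph step object."""
    return make_scene(snr_db=np.inf, seed=1)
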