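"""Forward model for low-coherence off-axis interferograms.

Synthesizes two-beam reflection interferograms with a known ground-truth
phase, a configurable carrier geometry (tilt / curved / circular fringes)
and a partially coherent light source whose finite spectral bandwidth
modulates fringe visibility through the temporal-coherence envelope.

Model
-----
A pixel records

    I(x, y) = a m(x, y) + b m(x, y) V(Delta) cos(2 pi Delta / lambda0 + delta)

where ``Delta`` is the total optical path difference (carrier OPD plus the
object contribution ``lambda0 * phi / (2 pi)``), ``V`` the visibility
envelope (normalized magnitude of the Fourier transform of the source power
spectrum evaluated at the OPD), ``a``/``b`` background and fringe amplitude,
``m`` a slowly varying multiplicative modulation and ``delta`` an optional
temporal phase shift.  Reflection geometry doubles the path, so a surface
step of height H produces a phase step of ``4 pi H / lambda0``.

All lengths are in nanometres, all transverse coordinates in pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

__all__ = [
    "SpectrumModel",
    "CarrierModel",
    "TestObject",
    "AcquisitionModel",
    "Interferogram",
    "step_text_object",
    "blobs_object",
    "flat_object",
    "glyph_mask",
    "object_phase",
    "visibility_envelope",
    "carrier_opd_map",
    "synthesize",
    "phase_shifted_series",
    "usable_fov_fraction",
]

_LN2 = float(np.log(2.0))


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumModel:
    """Light-source spectrum: peak wavelength and FWHM bandwidth in nm.

    The spectral density is modelled in the wavenumber domain (nu = 1/lambda)
    with the FWHM converted via ``dnu = fwhm_bandwidth / center_wavelength**2``
    — the standard narrow-band mapping — so the coherence envelope is the
    exact Fourier transform of the line shape.
    """

    center_wavelength: float
    fwhm_bandwidth: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.center_wavelength <= 0:
            raise InvalidParameterError("center_wavelength must be positive")
        if self.fwhm_bandwidth < 0:
            raise InvalidParameterError("fwhm_bandwidth must be non-negative")
        if self.shape not in ("gaussian", "rect"):
            raise InvalidParameterError(f"unknown spectrum shape {self.shape!r}")
        if self.fwhm_bandwidth > 0.5 * self.center_wavelength:
            warnings.warn(
                "fwhm_bandwidth exceeds half the center wavelength; the "
                "quasi-monochromatic envelope model degrades",
                stacklevel=2,
            )

    @property
    def fwhm_wavenumber(self) -> float:
        """FWHM of the line shape in wavenumber units (1/nm)."""
        return self.fwhm_bandwidth / self.center_wavelength**2

    def sample(self, n: int = 201, span_fwhm: float = 3.0):
        """Discretize the spectrum: (wavelengths nm, normalized weights).

        Samples the wavenumber axis uniformly across ``span_fwhm`` FWHM on
        each side of the line center; used by the direct spectral
        superposition oracle of the envelope model.
        """
        nu0 = 1.0 / self.center_wavelength
        dnu = self.fwhm_wavenumber
        if dnu == 0:
            return np.array([self.center_wavelength]), np.array([1.0])
        if self.shape == "gaussian":
            half = span_fwhm * dnu
            nu = np.linspace(nu0 - half, nu0 + half, n)
            w = np.exp(-4.0 * _LN2 * ((nu - nu0) / dnu) ** 2)
        else:  # rect
            nu = np.linspace(nu0 - dnu / 2, nu0 + dnu / 2, n)
            w = np.ones(n)
        w = w / w.sum()
        return 1.0 / nu, w


@dataclass(frozen=True)
class CarrierModel:
    """Carrier-fringe geometry.

    ``tilt`` is the off-axis plane-wave carrier (straight equispaced
    fringes); ``curved`` adds a quadratic OPD term to the tilt (wavefront
    curvature mismatch between the interferometer arms); ``circular`` is the
    pure quadratic term (concentric ring fringes).  The carrier is
    parametrized by the observable fringe period in pixels rather than a
    beam angle.
    """

    kind: str = "tilt"
    fringe_period: float = 8.0
    curvature_coeff: float | None = None  # nm / px^2; derived if None
    center: tuple[float, float] | None = None  # (row, col); image center if None
    tilt_azimuth: float = 0.0  # rad, 0 = fringes normal along +x (columns)

    def __post_init__(self) -> None:
        if self.kind not in ("tilt", "curved", "circular"):
            raise InvalidParameterError(f"unknown carrier kind {self.kind!r}")
        if self.fringe_period < 2.0:
            raise InvalidParameterError(
                f"fringe_period {self.fringe_period} px violates the Nyquist "
                "limit of 2 px"
            )
        if self.kind == "tilt" and self.curvature_coeff not in (None, 0.0):
            raise InvalidParameterError("tilt carrier must have zero curvature")


@dataclass(frozen=True)
class TestObject:
    """Ground-truth specimen as a topographic height map (nm, reflection).

    ``mask`` marks foreground pixels (used for step objects and for
    height/phase statistics downstream); ``height_map`` carries the full
    per-pixel surface height.
    """

    kind: str
    height_map: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("step_text", "blobs", "flat"):
            raise InvalidParameterError(f"unknown object kind {self.kind!r}")
        if np.any(self.height_map < 0):
            raise InvalidParameterError("heights must be non-negative")
        if self.mask.shape != self.height_map.shape:
            raise InvalidParameterError("mask shape must equal height_map shape")


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera-side parameters of a synthetic acquisition."""

    image_shape: tuple[int, int] = (512, 512)
    background_level: float = 1.0  # a
    fringe_amplitude: float = 0.5  # b
    snr_db: float = np.inf
    amplitude_modulation: np.ndarray | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.background_level > self.fringe_amplitude >= 0:
            raise InvalidParameterError(
                "need background_level > fringe_amplitude >= 0 for "
                "non-negative intensities"
            )
        if self.amplitude_modulation is not None:
            m = self.amplitude_modulation
            if m.shape != tuple(self.image_shape):
                raise InvalidParameterError("amplitude_modulation shape mismatch")
            if np.any(m <= 0) or np.any(m > 1):
                raise InvalidParameterError("amplitude_modulation must be in (0, 1]")


@dataclass(frozen=True)
class Interferogram:
    """A recorded (or simulated) intensity frame plus its acquisition metadata."""

    intensity: np.ndarray
    spectrum: SpectrumModel | None = None
    carrier: CarrierModel | None = None
    acquisition: AcquisitionModel | None = None
    pixel_size_um: float = 1.0
    ground_truth_phase: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        inten = self.intensity
        if inten.ndim != 2:
            raise InvalidParameterError("intensity must be a 2D image")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise InvalidParameterError("intensities must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


# ---------------------------------------------------------------------------
# Test objects
# ---------------------------------------------------------------------------

# 5x7 bitmaps of the bundled glyphs (synthetic stand-in for a
# lithographically etched text target; the algorithms only see a binary mask).
_GLYPHS = {
    "L": ["10000", "10000", "10000", "10000", "10000", "10000", "11111"],
    "C": ["01111", "10000", "10000", "10000", "10000", "10000", "01111"],
    "Q": ["01110", "10001", "10001", "10001", "10101", "10010", "01101"],
}


def glyph_mask(shape: tuple[int, int], text: str = "LCQ",
               rel_height: float = 0.28) -> np.ndarray:
    """Render a blocky three-letter binary mask centered in ``shape``.

    ``rel_height`` sets the glyph height as a fraction of the image height.
    """
    rows, cols = shape
    bitmaps = []
    for ch in text:
        if ch not in _GLYPHS:
            raise InvalidParameterError(f"no glyph for character {ch!r}")
        bitmaps.append(np.array([[int(c) for c in r] for r in _GLYPHS[ch]], bool))
    gap = np.zeros((7, 1), bool)
    strip = bitmaps[0]
    for b in bitmaps[1:]:
        strip = np.hstack([strip, gap, b])
    scale = max(1, int(round(rel_height * rows / strip.shape[0])))
    big = np.kron(strip, np.ones((scale, scale), bool))
    mask = np.zeros(shape, bool)
    r0 = (rows - big.shape[0]) // 2
    c0 = (cols - big.shape[1]) // 2
    r1, c1 = max(r0, 0), max(c0, 0)
    sub = big[: rows - r1, : cols - c1]
    mask[r1 : r1 + sub.shape[0], c1 : c1 + sub.shape[1]] = sub
    return mask


def step_text_object(shape: tuple[int, int], height_nm: float = 110.0,
                     text: str = "LCQ") -> TestObject:
    """Binary step object: an etched glyph target of uniform height."""
    if height_nm < 0:
        raise InvalidParameterError("height must be non-negative")
    mask = glyph_mask(shape, text)
    return TestObject("step_text", height_nm * mask.astype(float), mask)


def blobs_object(shape: tuple[int, int], count: int = 6,
                 radius_range: tuple[float, float] = (12.0, 40.0),
                 peak_height_nm: float = 80.0, seed: int = 0) -> TestObject:
    """Smooth cell-like object: a sum of Gaussian height blobs.

    Blob centers are drawn uniformly inside the central 60% of the field so
    the specimen sits in the well-modulated region of a low-coherence FoV.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    h = np.zeros(shape, float)
    for _ in range(count):
        r = rng.uniform(*radius_range)
        cy = rng.uniform(0.2 * rows, 0.8 * rows)
        cx = rng.uniform(0.2 * cols, 0.8 * cols)
        h += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
    if h.max() > 0:
        h *= peak_height_nm / h.max()
    return TestObject("blobs", h, h > 0.1 * peak_height_nm)


def flat_object(shape: tuple[int, int]) -> TestObject:
    """Featureless reference surface (null scene)."""
    z = np.zeros(shape, float)
    return TestObject("flat", z, np.zeros(shape, bool))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def object_phase(obj: TestObject, spectrum: SpectrumModel) -> np.ndarray:
    """Ground-truth phase map (rad) of ``obj`` at the source peak wavelength.

    Reflection geometry: the beam traverses the height step twice, so
    ``phi = 4 pi h / lambda0``.
    """
    lam0 = spectrum.center_wavelength
    if lam0 <= 0:
        raise InvalidParameterError("center wavelength must be positive")
    return 4.0 * np.pi * obj.height_map / lam0


def visibility_envelope(spectrum: SpectrumModel, opd):
    """Fringe visibility V(OPD) in [0, 1] for the given source spectrum.

    Normalized magnitude of the Fourier transform of the spectral density:
    Gaussian line -> Gaussian envelope, rect line -> |sinc| envelope; a
    zero-bandwidth source has unit visibility at any path difference.
    """
    opd = np.asarray(opd, float)
    if not np.all(np.isfinite(opd)):
        raise InvalidParameterError("opd must be finite")
    dnu = spectrum.fwhm_wavenumber
    if dnu == 0:
        return np.ones_like(opd) if opd.ndim else 1.0
    if spectrum.shape == "gaussian":
        v = np.exp(-((np.pi * dnu * opd) ** 2) / (4.0 * _LN2))
    else:  # rect
        v = np.abs(np.sinc(dnu * opd))
    return v if opd.ndim else float(v)


def _carrier_center(carrier: CarrierModel, shape) -> tuple[float, float]:
    if carrier.center is not None:
        return carrier.center
    return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def carrier_opd_map(carrier: CarrierModel, shape: tuple[int, int],
                    lambda0: float) -> np.ndarray:
    """Carrier OPD (nm) over the field.

    Tilt gives a plane ramp of one wavelength per fringe period along the
    azimuth; curved adds (and circular is) a quadratic bowl about ``center``.
    The ramp is referenced to the image center, where the OPD is zero — the
    zero-path position an experimenter dials the reference stage to.
    """
    if carrier.fringe_period < 2.0:
        raise InvalidParameterError("fringe period below the 2 px Nyquist limit")
    cy, cx = _carrier_center(carrier, shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    u = xx - cx
    v = yy - cy
    p = carrier.fringe_period
    opd = np.zeros(shape, float)
    if carrier.kind in ("tilt", "curved"):
        opd += lambda0 * (u * np.cos(carrier.tilt_azimuth)
                          + v * np.sin(carrier.tilt_azimuth)) / p
    if carrier.kind in ("curved", "circular"):
        coeff = carrier.curvature_coeff
        if coeff is None:
            # choose the bowl so the local radial period at a quarter of the
            # field (circular) or the period perturbation at the field edge
            # (curved) is governed by fringe_period
            r_ref = min(shape) / 4.0
            coeff = lambda0 / (2.0 * p * r_ref)
        opd += coeff * (u**2 + v**2)
    return opd


def synthesize(phase: np.ndarray, carrier: CarrierModel,
               spectrum: SpectrumModel, acq: AcquisitionModel,
               phase_shift: float = 0.0, _noise_key: int = 0) -> Interferogram:
    """Render one interferogram frame from a ground-truth phase map.

    ``phase_shift`` (rad) offsets the carrier phase — the temporal
    phase-shifting degree of freedom.  Noise is additive Gaussian with
    standard deviation set by ``acq.snr_db`` relative to the fringe
    amplitude ``b``; intensities are clipped at zero.  Deterministic given
    ``acq.rng_seed`` (and the frame index for multi-frame series).
    """
    shape = tuple(acq.image_shape)
    if phase.shape != shape:
        raise InvalidParameterError(
            f"phase shape {phase.shape} does not match image_shape {shape}")
    lam0 = spectrum.center_wavelength
    opd = carrier_opd_map(carrier, shape, lam0) + lam0 * phase / (2.0 * np.pi)
    vis = visibility_envelope(spectrum, opd)
    m = acq.amplitude_modulation if acq.amplitude_modulation is not None else 1.0
    a, b = acq.background_level, acq.fringe_amplitude
    img = a * m + b * m * vis * np.cos(2.0 * np.pi * opd / lam0 + phase_shift)
    if np.isfinite(acq.snr_db):
        sigma = b * 10.0 ** (-acq.snr_db / 20.0)
        rng = np.random.default_rng([acq.rng_seed, _noise_key])
        img = img + rng.normal(0.0, sigma, shape)
    img = np.clip(img, 0.0, None)
    return Interferogram(img, spectrum, carrier, acq,
                         ground_truth_phase=phase.copy())


def phase_shifted_series(phase: np.ndarray, carrier: CarrierModel,
                         spectrum: SpectrumModel, acq: AcquisitionModel,
                         shifts) -> list[Interferogram]:
    """Temporal series of frames with carrier phase offsets ``shifts`` (rad).

    Frames share all parameters but draw independent noise realizations.
    """
    shifts = list(shifts)
    if not shifts:
        raise InvalidParameterError("need at least one phase shift")
    return [synthesize(phase, carrier, spectrum, acq,
                       phase_shift=s, _noise_key=k)
            for k, s in enumerate(shifts)]


# ---------------------------------------------------------------------------
# Fringe-contrast / field-of-view analysis
# ---------------------------------------------------------------------------

def _dominant_period(image: np.ndarray) -> float | None:
    """Global dominant fringe period (px) from the spectral peak, or None."""
    spec = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean())))
    rows, cols = image.shape
    cy, cx = rows // 2, cols // 2
    yy, xx = np.mgrid[0:rows, 0:cols]
    rr = np.hypot(yy - cy, xx - cx)
    guarded = spec.copy()
    guarded[rr < 3] = 0.0
    peak = np.unravel_index(np.argmax(guarded), spec.shape)
    if guarded[peak] <= 3.0 * np.median(spec) + 1e-12:
        return None
    fy = (peak[0] - cy) / rows
    fx = (peak[1] - cx) / cols
    f = np.hypot(fy, fx)
    if f == 0:
        return None
    return 1.0 / f


def usable_fov_fraction(ig: Interferogram, contrast_threshold: float = 0.5) -> float:
    """Fraction of the field with local fringe contrast above threshold.

    The local contrast (Imax - Imin)/(Imax + Imin) is measured with
    min/max order-statistic filters over one local fringe period, which
    tracks the temporal-coherence visibility envelope across the field.
    A fringe-free image yields 0 with a warning.
    """
    if not 0.0 < contrast_threshold < 1.0:
        raise InvalidParameterError("contrast_threshold must lie in (0, 1)")
    img = np.asarray(ig.intensity, float)
    period = _dominant_period(img)
    if period is None:
        warnings.warn("no fringe carrier detected; usable FoV is 0", stacklevel=2)
        return 0.0
    w = max(3, int(round(period)) | 1)
    # raw-order statistics: smoothing would attenuate high-density fringes;
    # denoise noisy inputs before calling this estimator
    mx = maximum_filter(img, size=w)
    mn = minimum_filter(img, size=w)
    contrast = (mx - mn) / np.maximum(mx + mn, 1e-12)
    m = w // 2  # the border ring sees a truncated window; score the interior
    interior = contrast[m : img.shape[0] - m, m : img.shape[1] - m]
    return float(np.mean(interior >= contrast_threshold))
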