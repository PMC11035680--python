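"""Phase demodulation: Hilbert spiral transform core plus two baselines.

Three demodulators recover the wrapped phase of a fringe pattern:

* Hilbert spiral transform (HST) — single shot.  The analytic signal
  ``s_A = s + i s_H`` is completed with the quadrature
  ``s_H = Re[-i exp(-i beta) F^-1{ P F[s] }]`` where
  ``P(z1, z2) = (z1 + i z2)/sqrt(z1^2 + z2^2)`` is the unit-magnitude
  spiral phase function (the isotropic 2D extension of the Hilbert
  transform's signum) and ``beta`` the local fringe direction.  The
  wrapped phase is ``atan2(s_H, s)``.
* Fourier-transform (FT) method — single shot.  The +1 carrier order is
  windowed in the spectrum, shifted to DC and inverse transformed; the
  window radius trades spectral-overlap artifacts against resolution.
* PCA temporal phase shifting (TPS) — multi frame.  After removing the
  per-pixel temporal mean, the two leading principal components of a
  phase-shifted frame stack are the cosine and sine maps of the fringe
  argument.

All three return the phase wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .orientation import DirectionMap
from .preprocess import FringeComponent

__all__ = [
    "SpiralFilter",
    "QuadraturePair",
    "WrappedPhaseMap",
    "SpectralWindow",
    "spiral_filter",
    "hst_quadrature",
    "hst_wrapped_phase",
    "hst_demodulate",
    "ft_method",
    "tps_pca",
    "wrap_phase",
]


def wrap_phase(phi):
    """Wrap to the principal interval (-pi, pi]."""
    w = (np.asarray(phi, float) + np.pi) % (2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpiralFilter:
    """Spiral phase function sampled on a centered frequency grid.

    Unit magnitude everywhere except the DC sample, which is zero by
    convention (removable singularity); conjugate-antisymmetric,
    ``P(-z) = -P(z)``.
    """

    values: np.ndarray

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class QuadraturePair:
    """Fringe signal ``s`` and its spiral-transform quadrature ``s_H``."""

    s: np.ndarray
    s_H: np.ndarray

    def __post_init__(self) -> None:
        if self.s.shape != self.s_H.shape:
            raise ValueError("s and s_H must share a shape")

    @property
    def amplitude(self) -> np.ndarray:
        """Local fringe modulation amplitude sqrt(s^2 + s_H^2)."""
        return np.hypot(self.s, self.s_H)


@dataclass(frozen=True)
class WrappedPhaseMap:
    """Phase wrapped to (-pi, pi] with a validity mask (False = degenerate pixel)."""

    phi: np.ndarray
    validity: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if np.any(self.phi <= -np.pi - 1e-12) or np.any(self.phi > np.pi + 1e-12):
            raise ValueError("wrapped phase must lie in (-pi, pi]")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("wrapped phase must be finite")


@dataclass(frozen=True)
class SpectralWindow:
    """Window around the +1 carrier order in the centered spectrum.

    ``center`` is the (row, col) pixel of the +1 peak; ``radius`` in
    frequency pixels; ``taper`` is 'hard' (ideal circular) or 'gaussian'
    (FWHM = radius).
    """

    center: tuple[int, int]
    radius: float
    taper: str = "hard"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("window radius must be >= 1 frequency pixel")
        if self.taper not in ("hard", "gaussian"):
            raise ValueError(f"unknown taper {self.taper!r}")


# ---------------------------------------------------------------------------
# Hilbert spiral transform
# ---------------------------------------------------------------------------

def spiral_filter(shape: tuple[int, int]) -> SpiralFilter:
    """Spiral phase function P(z1, z2) = (z1 + i z2)/|z| on a centered grid.

    z1 runs along columns (x frequency), z2 along rows (y frequency); the
    grid is the fftshifted FFT frequency lattice for ``shape``.
    """
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise ValueError("shape must be at least 2x2")
    z2 = np.fft.fftshift(np.fft.fftfreq(rows))[:, None]  # y frequency
    z1 = np.fft.fftshift(np.fft.fftfreq(cols))[None, :]  # x frequency
    rad = np.hypot(z1, z2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(rad > 0, (z1 + 1j * z2) / np.where(rad > 0, rad, 1.0), 0.0)
    return SpiralFilter(vals)


def _as_image(fringe) -> np.ndarray:
    if isinstance(fringe, FringeComponent):
        return fringe.image
    return np.asarray(fringe, float)


def _as_beta(beta, shape) -> np.ndarray:
    if isinstance(beta, DirectionMap):
        beta = beta.beta
    beta = np.asarray(beta, float)
    if beta.shape == ():
        beta = np.full(shape, float(beta))
    return beta


def hst_quadrature(fringe, beta, pad: int | None = None) -> QuadraturePair:
    """Spiral-transform quadrature of a zero-mean fringe image.

    ``s_H = Re[-i exp(-i beta) F^-1{ P F[s] }]``; the imaginary residue of
    the complex expression is the transform's known error term and is
    discarded.  The image is mirror-padded (default: 16 px, at least one
    fringe period is recommended) before the transforms to suppress
    wrap-around ringing, then cropped.
    """
    s = _as_image(fringe)
    rms = float(np.sqrt(np.mean(s**2)))
    if rms > 0 and abs(float(s.mean())) > 1e-2 * rms:
        raise ValueError(
            "fringe input is not zero-mean; run the pre-processing stage "
            "(background removal) before the quadrature transform")
    b = _as_beta(beta, s.shape)
    if b.shape != s.shape:
        raise ValueError("beta map shape must match the fringe image")
    if pad is None:
        pad = 16
    sp = np.pad(s, pad, mode="reflect")
    bp = np.pad(b, pad, mode="edge")
    filt = np.fft.ifftshift(spiral_filter(sp.shape).values)
    core = np.fft.ifft2(filt * np.fft.fft2(sp))
    s_h = np.real(-1j * np.exp(-1j * bp) * core)
    if pad:
        s_h = s_h[pad:-pad, pad:-pad]
    return QuadraturePair(s.copy(), s_h)


def hst_wrapped_phase(pair: QuadraturePair) -> WrappedPhaseMap:
    """Wrapped phase phi = atan2(s_H, s) in (-pi, pi].

    Pixels where both components vanish (no fringe modulation) are set to
    zero phase and flagged invalid.
    """
    amp = pair.amplitude
    eps = 1e-9 * max(float(amp.max()), 1e-300)
    degenerate = amp < eps
    phi = np.arctan2(pair.s_H, pair.s)
    phi = np.where(degenerate, 0.0, phi)
    phi = np.where(phi == -np.pi, np.pi, phi)
    return WrappedPhaseMap(phi, validity=~degenerate)


def hst_demodulate(fringe, beta, pad: int | None = None) -> WrappedPhaseMap:
    """Convenience: quadrature + arctangent in one call."""
    return hst_wrapped_phase(hst_quadrature(fringe, beta, pad=pad))


# ---------------------------------------------------------------------------
# Fourier-transform baseline
# ---------------------------------------------------------------------------

def _find_carrier_peak(spec_abs: np.ndarray, guard: float = 4.0):
    """Strongest off-DC spectral peak (centered coords), or raise."""
    rows, cols = spec_abs.shape
    cy, cx = rows // 2, cols // 2
    yy, xx = np.mgrid[0:rows, 0:cols]
    rr = np.hypot(yy - cy, xx - cx)
    masked = np.where(rr >= guard, spec_abs, 0.0)
    peak = np.unravel_index(np.argmax(masked), spec_abs.shape)
    if masked[peak] <= 3.0 * np.median(spec_abs) + 1e-12:
        raise ValueError("no carrier detected: no off-DC peak above 3x the "
                         "median spectral magnitude")
    # deterministic choice between the conjugate +1/-1 orders: positive x
    # frequency (or positive y on the fx = 0 line)
    if peak[1] < cx or (peak[1] == cx and peak[0] < cy):
        peak = (2 * cy - peak[0], 2 * cx - peak[1])
        peak = (peak[0] % rows, peak[1] % cols)
    return peak


def ft_method(ig, window="auto") -> WrappedPhaseMap:
    """Single-shot Fourier-transform demodulation of an off-axis fringe image.

    FFT -> select the +1 order (``window='auto'``: strongest off-DC peak,
    hard circular window of radius half the peak-to-DC distance, the
    conservative choice that avoids overlap with the zero order) -> shift
    the peak to DC -> inverse FFT -> phase of the analytic image.  The
    integer-bin carrier shift leaves a small residual tilt, removed by the
    aberration-correction stage downstream.
    """
    img = ig.intensity if hasattr(ig, "intensity") else np.asarray(ig, float)
    img = np.asarray(img, float)
    rows, cols = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    cy, cx = rows // 2, cols // 2
    if window == "auto" or window is None:
        peak = _find_carrier_peak(np.abs(spec))
        dist = float(np.hypot(peak[0] - cy, peak[1] - cx))
        window = SpectralWindow(peak, max(1.0, dist / 2.0), "hard")
    peak = window.center
    yy, xx = np.mgrid[0:rows, 0:cols]
    rr = np.hypot(yy - peak[0], xx - peak[1])
    if window.taper == "hard":
        w = (rr <= window.radius).astype(float)
    else:
        w = np.exp(-4.0 * np.log(2.0) * (rr / window.radius) ** 2)
        w[rr > 2.0 * window.radius] = 0.0
    w[cy, cx] = 0.0  # the window never includes the DC pixel
    filtered = spec * w
    filtered = np.roll(filtered, (cy - peak[0], cx - peak[1]), axis=(0, 1))
    analytic = np.fft.ifft2(np.fft.ifftshift(filtered))
    phi = np.angle(analytic)
    phi = np.where(phi == -np.pi, np.pi, phi)
    validity = np.abs(analytic) > 1e-9 * float(np.abs(analytic).max())
    return WrappedPhaseMap(phi, validity=validity)


# ---------------------------------------------------------------------------
# PCA temporal phase shifting baseline
# ---------------------------------------------------------------------------

def tps_pca(frames) -> WrappedPhaseMap:
    """Phase from >= 3 phase-shifted frames via principal component analysis.

    The per-pixel temporal mean (the incoherent background) is subtracted;
    the two leading principal components of the residual stack are the
    cosine and sine maps of the fringe argument, equalized in energy, and
    ``phi = atan2(PC2, PC1)``.  The global sign is fixed against the
    carrier tilt azimuth when frame metadata carries it; the piston is set
    so the circular mean phase is zero.
    """
    imgs = [f.intensity if hasattr(f, "intensity") else np.asarray(f, float)
            for f in frames]
    if len(imgs) < 3:
        raise ValueError("temporal phase shifting needs at least 3 frames")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all frames must share a shape")
    data = np.stack([im.ravel() for im in imgs], axis=1).astype(float)
    data -= data.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(data, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-300):
        raise ValueError("rank-deficient frame stack: the phase shifts are "
                         "degenerate (identical frames?)")
    pc1 = (u[:, 0] * s[0]).reshape(shape)
    pc2 = (u[:, 1] * s[1]).reshape(shape)
    # equalize component energy: ideal cos/sin maps have equal RMS
    pc1 /= np.sqrt(np.mean(pc1**2))
    pc2 /= np.sqrt(np.mean(pc2**2))
    phi = np.arctan2(pc2, pc1)

    carrier = getattr(frames[0], "carrier", None)
    if carrier is not None:
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        if carrier.kind == "circular":
            cy, cx = carrier.center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
            rr = np.maximum(np.hypot(xx - cx, yy - cy), 1e-9)
            ex, ey = (xx - cx) / rr, (yy - cy) / rr
        else:
            ex = np.full(shape, np.cos(carrier.tilt_azimuth))
            ey = np.full(shape, np.sin(carrier.tilt_azimuth))
        proj = float(np.sum(wrap_phase(np.diff(phi, axis=1)) * ex[:, 1:])
                     + np.sum(wrap_phase(np.diff(phi, axis=0)) * ey[1:, :]))
        if proj < 0.0:
            phi = -phi
    piston = float(np.angle(np.mean(np.exp(1j * phi))))
    phi = wrap_phase(phi - piston)
    return WrappedPhaseMap(phi, validity=np.ones(shape, bool))
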