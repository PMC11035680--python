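"""Interferogram pre-processing: denoising and fringe extraction by
adaptive bidimensional empirical mode decomposition (BEMD).

The single-shot quadrature transform downstream demands a fringe signal
that (1) oscillates around zero mean, (2) carries at most slowly varying
amplitude modulation and (3) is as noise-free as practical.  This module
delivers that: a pluggable denoiser, a per-pixel fringe-period estimate,
an order-statistics BEMD whose extrema windows are sized by the local
period (the period-guided variant, which keeps the whole fringe signal in
one mode and prevents mode mixing), and a selector that picks the
carrier-band intrinsic mode function (IMF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (
    gaussian_filter,
    maximum_filter,
    median_filter,
    minimum_filter,
    uniform_filter,
    zoom,
)

__all__ = [
    "IMFStack",
    "PeriodMap",
    "FringeComponent",
    "denoise",
    "local_period",
    "bemd",
    "select_fringe_imf",
    "extract_fringe_component",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IMFStack:
    """Ordered intrinsic mode functions, finest scale first, plus residual.

    By construction ``sum(imfs) + residual`` reproduces the decomposed
    image exactly (up to floating-point round-off).
    """

    imfs: list
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for m in self.imfs:
            out += m
        return out

    def __len__(self) -> int:
        return len(self.imfs)


@dataclass(frozen=True)
class PeriodMap:
    """Per-pixel dominant fringe period in pixels (>= 2)."""

    local_period: np.ndarray
    flagged: bool = False  # True when no oscillatory content was found

    def __post_init__(self) -> None:
        p = self.local_period
        if not np.all(np.isfinite(p)) or np.any(p < 2):
            raise ValueError("local periods must be finite and >= 2 px")


@dataclass(frozen=True)
class FringeComponent:
    """Zero-mean band-limited fringe image, ready for quadrature demodulation."""

    image: np.ndarray
    mean_abs: float
    in_band_fraction: float | None = None

    def __post_init__(self) -> None:
        rms = float(np.sqrt(np.mean(self.image**2)))
        if rms > 0 and self.mean_abs > 1e-3 * rms:
            raise ValueError("fringe component violates the zero-mean contract")


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

_DENOISERS = {}


def register_denoiser(name: str, fn) -> None:
    """Plug in an external denoiser ``fn(image, **params) -> image``.

    The contract: attenuate noise above the carrier band while changing the
    fringe-band amplitude by less than 5% on clean fringes.  A
    patch-collaborative filter (e.g. BM3D) slots in here when available.
    """
    _DENOISERS[name] = fn


def _wavelet_denoise(img, mode="soft"):
    from skimage.restoration import denoise_wavelet, estimate_sigma

    sigma = estimate_sigma(img)
    span = float(img.max() - img.min())
    if not np.isfinite(sigma) or sigma <= 1e-9 * max(span, 1e-300):
        return img.copy()  # noise-free input: nothing to remove
    return denoise_wavelet(img, sigma=sigma, method="BayesShrink", mode=mode,
                           rescale_sigma=True)


register_denoiser("none", lambda img: img.copy())
register_denoiser("wavelet", _wavelet_denoise)
register_denoiser("gaussian", lambda img, sigma=0.8: gaussian_filter(img, sigma))
register_denoiser("median", lambda img, size=3: median_filter(img, size=size,
                                                              mode="mirror"))


def denoise(image: np.ndarray, method: str = "wavelet", **params) -> np.ndarray:
    """Apply the named denoiser; ``method='none'`` is the identity."""
    image = np.asarray(image, float)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ValueError("expected a finite 2D image")
    try:
        fn = _DENOISERS[method]
    except KeyError:
        raise ValueError(
            f"unknown denoiser {method!r}; registered: {sorted(_DENOISERS)}"
        ) from None
    return fn(image, **params)


# ---------------------------------------------------------------------------
# Local fringe period
# ---------------------------------------------------------------------------

def local_period(image: np.ndarray, block: int = 64, stride: int | None = None,
                 default_period: float = 8.0) -> PeriodMap:
    """Per-pixel dominant fringe period from block-wise windowed spectra.

    Overlapping Hann-windowed blocks are Fourier transformed; the strongest
    off-DC radial frequency gives the block period, and the coarse grid is
    interpolated back to full resolution.  Values are clipped to
    ``[2, min(shape)/2]``.  A spectrally flat image is flagged and filled
    with ``default_period``.
    """
    img = np.asarray(image, float)
    rows, cols = img.shape
    block = min(block, rows, cols)
    stride = stride or block // 2
    win = np.hanning(block)[:, None] * np.hanning(block)[None, :]
    yy, xx = np.mgrid[0:block, 0:block]
    rr = np.hypot(yy - block // 2, xx - block // 2)
    guard = rr < 2.0

    r_starts = list(range(0, max(rows - block, 0) + 1, stride))
    c_starts = list(range(0, max(cols - block, 0) + 1, stride))
    grid = np.full((len(r_starts), len(c_starts)), np.nan)
    any_peak = False
    for i, r0 in enumerate(r_starts):
        for j, c0 in enumerate(c_starts):
            tile = img[r0 : r0 + block, c0 : c0 + block]
            tile = (tile - tile.mean()) * win
            spec = np.abs(np.fft.fftshift(np.fft.fft2(tile)))
            spec[guard] = 0.0
            peak = np.unravel_index(np.argmax(spec), spec.shape)
            if spec[peak] < 3.0 * np.median(spec) + 1e-12:
                continue
            f = rr[peak] / block
            if f > 0:
                grid[i, j] = 1.0 / f
                any_peak = True

    if not any_peak:
        warnings.warn("no oscillatory content detected; using default period",
                      stacklevel=2)
        return PeriodMap(np.full(img.shape, float(default_period)), flagged=True)

    # fill failed blocks with the median of the successful ones
    med = float(np.nanmedian(grid))
    grid = np.where(np.isnan(grid), med, grid)
    full = zoom(grid, (rows / grid.shape[0], cols / grid.shape[1]), order=1,
                mode="nearest", grid_mode=True)
    full = full[:rows, :cols]
    full = np.clip(full, 2.0, min(rows, cols) / 2.0)
    return PeriodMap(full)


# ---------------------------------------------------------------------------
# Order-statistics BEMD with period-guided windows
# ---------------------------------------------------------------------------

def _count_extrema(image: np.ndarray, w: int) -> int:
    mx = maximum_filter(image, size=w, mode="mirror")
    mn = minimum_filter(image, size=w, mode="mirror")
    varies = mx > mn  # a flat window holds no extremum
    return int(np.count_nonzero((image == mx) & varies)
               + np.count_nonzero((image == mn) & varies))


def _envelopes(image: np.ndarray, window: np.ndarray):
    """Upper/lower envelopes by max/min filtering + matched-scale smoothing.

    ``window`` is an integer odd-size map; sizes are binned so each distinct
    size costs one pass of the separable order-statistic filters.
    """
    sizes = np.unique(window)
    upper = np.empty_like(image)
    lower = np.empty_like(image)
    for w in sizes:
        sel = window == w
        w = int(w)
        up = uniform_filter(maximum_filter(image, size=w, mode="mirror"),
                            size=w, mode="mirror")
        lo = uniform_filter(minimum_filter(image, size=w, mode="mirror"),
                            size=w, mode="mirror")
        upper[sel] = up[sel]
        lower[sel] = lo[sel]
    return upper, lower


def _quantize_windows(period: np.ndarray, scale: float, nbins: int = 6) -> np.ndarray:
    """Round scaled periods to a small set of odd window sizes."""
    w = np.clip(np.round(period * scale), 3, None)
    w = (w // 2 * 2 + 1).astype(int)  # snap to odd
    sizes = np.unique(w)
    if len(sizes) > nbins:
        qs = np.quantile(w, np.linspace(0, 1, nbins))
        qs = np.unique((np.round(qs) // 2 * 2 + 1).astype(int))
        idx = np.abs(w[..., None] - qs[None, None, :]).argmin(axis=-1)
        w = qs[idx]
    return w


def bemd(image: np.ndarray, period_map: PeriodMap | None = None,
         max_imfs: int = 4, sift_iters: int = 2) -> IMFStack:
    """Bidimensional EMD by order-statistics (min/max envelope) sifting.

    Extrema are located in adaptive windows proportional to the local
    fringe period, envelopes are formed by max/min filtering followed by
    mean smoothing at the same scale, and each IMF is the input minus the
    mean envelope, sifted ``sift_iters`` times.  Successive modes double
    the window scale.  The decomposition is strictly additive: the sum of
    IMFs plus the residual reproduces the input.
    """
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")
    img = np.asarray(image, float)
    if period_map is None:
        period_map = local_period(img)
    period = period_map.local_period

    imfs: list[np.ndarray] = []
    residual = img.copy()
    scale = 1.0
    for _ in range(max_imfs):
        w_med = max(3, int(np.median(period) * scale) | 1)
        if _count_extrema(residual, w_med) < 4:
            break
        window = _quantize_windows(period, scale)
        mode = residual.copy()
        for _ in range(max(1, sift_iters)):
            upper, lower = _envelopes(mode, window)
            mode = mode - 0.5 * (upper + lower)
        imfs.append(mode)
        residual = residual - mode
        scale *= 2.0
        if 3 * w_med >= min(img.shape):
            break
    return IMFStack(imfs, residual)


# ---------------------------------------------------------------------------
# Fringe-mode selection
# ---------------------------------------------------------------------------

def _band_energy_fraction(image: np.ndarray, band: tuple[float, float]) -> float:
    """Fraction of (DC-free) spectral energy inside a radial frequency band."""
    spec = np.abs(np.fft.fftshift(np.fft.fft2(image - image.mean()))) ** 2
    rows, cols = image.shape
    fy = np.fft.fftshift(np.fft.fftfreq(rows))
    fx = np.fft.fftshift(np.fft.fftfreq(cols))
    rr = np.hypot(fy[:, None], fx[None, :])
    total = spec.sum()
    if total == 0:
        return 0.0
    lo, hi = band
    return float(spec[(rr >= lo) & (rr <= hi)].sum() / total)


def select_fringe_imf(stack: IMFStack, carrier_band: tuple[float, float] | None = None,
                      period_map: PeriodMap | None = None) -> FringeComponent:
    """Pick the mode (or contiguous run of modes) dominating the carrier band.

    ``carrier_band`` is a radial frequency interval in cycles/px; if omitted
    it is derived from the period map (median period +/- one octave).  The
    selected component has its spatial mean removed, enforcing the
    zero-mean contract of the quadrature transform.
    """
    if len(stack) == 0:
        raise ValueError("empty IMF stack: input had no oscillatory modes")
    if carrier_band is None:
        if period_map is None:
            raise ValueError("need carrier_band or period_map")
        p = float(np.median(period_map.local_period))
        carrier_band = (1.0 / (2.0 * p), min(0.5, 2.0 / p))

    fracs = [_band_energy_fraction(m, carrier_band) for m in stack.imfs]
    best = int(np.argmax(fracs))
    chosen = stack.imfs[best].copy()
    best_frac = fracs[best]
    # greedily merge spectrally adjacent modes while in-band purity improves
    for nxt in (best - 1, best + 1):
        if 0 <= nxt < len(stack):
            cand = chosen + stack.imfs[nxt]
            f = _band_energy_fraction(cand, carrier_band)
            if f > best_frac:
                chosen, best_frac = cand, f
    if best_frac < 0.5:
        warnings.warn(
            f"best IMF holds only {best_frac:.0%} of its energy in the carrier "
            "band; fringe separation may be poor", stacklevel=2)
    chosen = chosen - chosen.mean()
    return FringeComponent(chosen, float(abs(chosen.mean())), best_frac)


def extract_fringe_component(image: np.ndarray, denoiser: str = "wavelet",
                             max_imfs: int = 4, sift_iters: int = 2,
                             denoiser_params: dict | None = None):
    """Convenience front-end: denoise -> period map -> BEMD -> select.

    Returns ``(FringeComponent, PeriodMap)``.
    """
    clean = denoise(image, denoiser, **(denoiser_params or {}))
    pm = local_period(clean)
    stack = bemd(clean, pm, max_imfs=max_imfs, sift_iters=sift_iters)
    if len(stack) == 0:
        raise ValueError("decomposition produced no modes (input too smooth)")
    fc = select_fringe_imf(stack, period_map=pm)
    return fc, pm
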