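# Methods

## Forward model

A two-beam reflection interferogram is synthesized as

    I(x, y) = a·m + b·m·V(Δ)·cos(2πΔ/λ₀ + δ),

where the total optical path difference `Δ` is the carrier OPD plus the
object term `λ₀φ/(2π)`, `a` and `b` are background and fringe amplitude
(defaults 1.0 and 0.5 a.u., a typical visibility of 0.5), `m` an optional
slowly varying multiplicative field, and `δ` a temporal phase shift.
Additive Gaussian noise is parametrized by an SNR in dB relative to `b`;
intensities are clipped at zero. Photon (Poisson) noise is not modelled.

**Spectrum and coherence envelope.** The source line shape is defined in
the wavenumber domain (ν = 1/λ) — Gaussian or rectangular — with its FWHM
specified in wavelength units and converted by `Δν = Δλ/λ₀²`. The fringe
visibility envelope is then exactly the normalized Fourier transform of the
line: `V(Δ) = exp(−(πΔνΔ)²/(4 ln 2))` for the Gaussian, `|sinc(ΔνΔ)|` for
the rect. This quasi-monochromatic factorization (envelope × carrier
cosine) is the default forward model; a direct superposition over ≥201
discretized wavelengths is kept as an independent numerical oracle and
agrees to well below 1% RMS of `b` up to Δλ/λ₀ = 0.2.

**Carriers.** The carrier is parametrized by the observable fringe period
in pixels (not a beam angle). `tilt` is a plane OPD ramp of λ₀ per period
along a configurable azimuth; `curved` adds, and `circular` is, a quadratic
bowl `c·r²` modelling wavefront-curvature mismatch between the arms. The
ramp is referenced to the image center (zero OPD at the field center, where
an experimenter parks the reference stage), so the low-coherence envelope
is centred in the field; this differs from an absolute-coordinate ramp only
by a piston. If the quadratic coefficient is not given it is derived so the
local radial period a quarter-field from the center equals the configured
period.

**Test objects.** A binary glyph step target (three blocky letters rendered
from 5×7 bitmaps, scaled; a synthetic stand-in for an etched text target —
the algorithms only see a binary mask) with configurable height, default
110 nm; smooth "cell" phantoms as sums of Gaussian height blobs (default:
6 blobs, radii 12–40 px, 80 nm peak, placed in the central 60% of the
field where a low-coherence FoV is well modulated); and a flat null scene.
Reflection doubles the path: `φ = 4πh/λ₀`.

## Reconstruction chain

1. **Denoise.** Pluggable. Default: BayesShrink soft wavelet thresholding
   with the noise level estimated from the data, so a noise-free image
   passes through essentially unchanged (< 5% fringe-band change) while
   20 dB inputs gain ≈ 5 dB. A fixed Gaussian blur is also registered but
   attenuates period-8 fringes by ~18%, which violates the fringe-band
   preservation requirement — hence not the default. A patch-collaborative
   denoiser (e.g. BM3D) can be registered at run time through
   `preprocess.register_denoiser`.

2. **Fringe extraction (period-guided BEMD).** The local fringe period is
   estimated from overlapping 64-px Hann-windowed block spectra (strongest
   off-DC radial peak, bilinear upsampling, clipped to [2, N/2]).  Sifting
   uses order-statistics envelopes: max/min filters in windows proportional
   to the local period (quantized to ≤ 6 odd sizes for speed), smoothed by
   an averaging filter of the same size; an intrinsic mode function is the
   image minus the mean envelope after 2 sift iterations; successive modes
   double the window. Defaults `max_imfs = 4`, `sift_iters = 2`: the
   decomposition is used for component separation, not completeness. The
   additive-reconstruction invariant (Σ IMF + residual ≡ input) holds by
   construction. The fringe component is the IMF (greedily merged with a
   spectrally adjacent neighbour when that raises in-band purity) with the
   largest energy fraction inside the carrier band (median period ± one
   octave), mean-subtracted; a warning is raised below 50% purity.
   Borders use mirror padding throughout. Decomposition stops when a
   window holds fewer than four strict extrema (a constant image returns
   only a residual).

3. **Direction map.** Fringe-normal orientation from the gradient
   structure tensor (Gaussian derivatives at σ = 1 px, tensor averaging
   over the local fringe period), coherence = tensor anisotropy. The
   π-ambiguity is resolved by best-first region growing from the
   highest-coherence pixel: each pixel takes β ∈ {θ, θ+π} closest on the
   circle to the mean direction of its already-assigned neighbours. The
   one remaining global sign is fixed so that the recovered carrier phase
   increases along the configured tilt azimuth (or radially outward for
   circular carriers); flipping it only flips the sign of the recovered
   phase.

4. **Spiral-transform quadrature.** `s_H = Re[−i e^{−iβ} F⁻¹{P F[s]}]`
   with the unit-magnitude spiral filter `P = (ζ₁+iζ₂)/|ζ|`, `P(0,0) = 0`.
   The imaginary residue of the complex expression is the transform's known
   error term and is discarded. Images are mirror-padded by one median
   fringe period before the FFTs to suppress wrap-around ringing, and the
   input must be zero-mean (|mean| < 1% of RMS) — enforced with an error
   directing the user to the pre-processing stage. Wrapped phase is
   `atan2(s_H, s)` in (−π, π]; pixels with vanishing modulation are set to
   0 and flagged in a validity mask.

5. **Unwrapping.** Reliability-sorted noncontinuous-path unwrapping
   (second-difference reliabilities, edge sorting, group merging with 2π
   offsets) via `skimage.restoration.unwrap_phase`; masked inputs are
   supported, with disjoint regions carrying an undefined relative piston.
   Congruence `wrap(unwrap(w)) = w` is exact to float precision.

6. **Aberration removal.** Least-squares fit of {1, x, y, x², y², xy}
   (centered coordinates) on background pixels, subtracted everywhere;
   corrected background median set to zero. This explicit polynomial fit
   realizes "remove linear and spherical components" with a testable
   contract (exact on polynomial surfaces, idempotent). Without a
   user-supplied background mask it is derived in two passes: fit on all
   quality pixels, Otsu-threshold the absolute residual to detect the
   specimen, refit on the quiet background; fewer than 1% background
   pixels is an error. The pipeline's quality mask keeps only pixels whose
   quadrature modulation exceeds 15% of the bright-field level (95th
   percentile) — in a low-coherence scene the envelope extinguishes
   fringes at large OPD and phase there is noise that must not steer the
   fit.

## Baselines

**FT method.** FFT → strongest off-DC peak (4-px DC guard, at least 3× the
median spectral magnitude, else "no carrier detected"); of the two
conjugate orders the one with positive x-frequency is taken. The window is
a hard circle of radius half the peak-to-DC distance (the conservative
overlap-free choice; a Gaussian taper is available), the peak is rolled to
the integer DC bin, and the phase of the inverse transform is returned.
The residual sub-bin tilt is absorbed by the aberration fit.

**PCA-TPS.** Per-pixel temporal mean removed; SVD of the pixels × frames
matrix; the two leading score maps are equalized in RMS (removing the
ellipse distortion that unequal singular values would imprint) and
`φ = atan2(PC2, PC1)`. Degenerate stacks (< 3 frames, or rank < 2 from
identical shifts) raise errors. Sign is fixed against the carrier
metadata; piston so the circular-mean phase is zero. With four noise-free
kπ/2 frames this matches closed-form four-step demodulation to ~1e−5 rad.

## Comparison harness and metrics

`compare_methods` runs TPS, HST and FT on the same simulated scene (TPS
gets the phase-shifted series of that scene) and reports piston-removed
interior RMS against ground truth (16-px border excluded), recovered step
height from foreground/background medians, and the 10–90% edge width along
the central row. All methods are referenced to the fixture's known
specimen-free background for the aberration fit, so the scores isolate
demodulation quality; the blind two-pass background detection remains the
default in `run_pipeline`, and the headline step-height result uses that
blind path.

Problem sizes: the step-height study runs five seeds at 512×512; the
method-ranking and regime fixtures use 256×256 and the parameter grid
128×128 — sizes at which every reported effect is already stable.

## Known limitations

* Sharp phase discontinuities (the 2.19 rad glyph edge) distort the local
  fringe field; the quadrature transform leaves localized edge artifacts
  that can seed small 2π-offset patches in the unwrapped map (~1% of
  pixels on curved-carrier step fixtures). Median-based height estimates
  are unaffected, but full-frame RMS figures on step objects are dominated
  by these edges. Smooth specimens do not trigger this.
* The envelope forward model assumes quasi-monochromatic factorization;
  it is exact for a Gaussian-in-wavenumber line and validated to 1% up to
  Δλ/λ₀ = 0.2, beyond which a warning is raised.
* PCA-TPS assumes several fringes across the field (near-orthogonal
  cosine/sine maps); single-fringe fields would mix the components.
* The simulator does not model speckle (coherent sources), partial spatial
  coherence, polarization, or detector nonlinearity; passing tests on
  these phantoms demonstrates algorithmic correctness, not robustness to
  every instrumental artifact of a physical interferometer.
* Blind background detection biases the quadratic fit when a smooth
  specimen covers a large fraction of the field (tails are
  indistinguishable from defocus); supply an explicit background mask in
  that regime.
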