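# Methods

## Imaging model and scope

The optical model is two-dimensional, scalar and incoherent. The
detection pupil is a clear disk of radius NA/λ in spatial frequency; the
intensity PSF is the squared modulus of its transform and the OTF its
normalized autocorrelation, with cutoff k_c = 2·NA/λ. All lengths are
nanometres, all spatial frequencies cycles/nm (not angular). DFT arrays
use the standard corner-origin layout; centred views are a `fftshift`
away. Axial behaviour enters only through `xz_support_extents`, which
autocorrelates the x–z cross-section of the detection spherical cap
numerically and recovers the lateral and axial support extents
2n·sinα/λ and n(1−cosα)/λ. Vectorial high-NA effects, polarization,
aberrations, 3D OTFs and out-of-focus background are out of scope.

Convolutions in the forward model are circular. This matches the
periodic phantoms and keeps every reconstruction identity exact on the
torus; aperiodic samples must be padded by the caller.

## Sampling

Simulated grids require pixel_nm ≤ λ_em/(8·NA) — twice oversampled
relative to the Nyquist rate of a two-beam SIM reconstruction. The
real-space reconstruction needs headroom for frequencies up to
k_c + |p| without aliasing, and we chose oversampled raw data over a
Fourier upscaling step: the product D_m·M_m is then exactly
representable on the acquisition grid. `make_transfer_function` rejects
coarser grids with the required pixel size in the message.

Pattern frequency vectors are snapped to the nearest DFT grid frequency
by default, so fringes hold a whole number of periods across the
periodic grid, spectra are leakage-free, and the effective-OTF
construction (integer spectral rolls) is exact.

## TIRF decay length

The evanescent 1/e decay length is implemented as
l = λ₀ / (4π·√(n₁²sin²α − n₂²)), with a **minus** sign under the root.
The plus-sign variant sometimes seen in print yields a finite value
below the critical angle and no divergence at it — a non-decaying,
unphysical field. The minus form diverges at the critical angle and
reproduces the familiar ~100 nm scale for typical oil/water interfaces
(57.8 nm for n₁sinα = 1.49 against water at 488 nm).

## Local-oscillator reconstruction

The reconstruction is R = Σ_m D_m·M_m with a spectrally flat M_m:

- **Analytic oscillators** for 2/3-beam fringes: M_m = 1 + 2cos(u_m)
  (+ 2cos(2u_m) for three beams), all harmonic weights equal to 1. The
  DC term is retained, so reconstructions include the wide-field band
  exactly as the direct sum prescribes; no DC suppression or per-band
  apodization is applied in v1 — Wiener deconvolution on the effective
  OTF is the only shaping step offered.
- **Whitened oscillators** for lattices and bitmap projections:
  oscillator spectrum = Ĩ(k)/|Ĩ(k)| wherever |Ĩ| ≥ floor·max|Ĩ|, else 0.
  The default floor of 1e−3 cleanly separates true pattern peaks from
  numerical leakage on noiseless synthetic patterns; it is configurable
  and should be raised for noisy pattern estimates.

Phase sets must cancel Σ_m e^{iqφ_m} for q = 1..2(n_beams−1). For three
beams (five spectral components) this requires five phases with orders
1–4 cancelled; equal 2π/5 steps are the default. A two-phase set {0, π}
cancels order 1 but leaves order 2 at magnitude 2, leaving unmixed
S̃(k±2p)H̃(k±p) terms in the sum — the package quantifies this residual
(≈0.7% of spectral peak for the default phantom) rather than hiding it.

Multiple pattern orientations are reconstructed independently and summed
pixelwise — the minimal consistent extension of the single-orientation
derivation.

### Scale conventions

The classical component vector for two-beam data is taken as
(2·H̃S̃, H̃S̃(k±p)): the mixing matrix is pure phase factors and the
separated components carry a factor 2 relative to the complex-exponential
amplitudes (1, ½, ½) of the mean-1 pattern 1 + cos(u). `recombine`
multiplies the direct sum of shifted components by m (phases) over this
scale, which makes the Fourier pipeline *identical* to Σ_m D_m·M_m —
the central cross-validation, asserted at 1e−8 relative but holding at
machine precision. Correspondingly `effective_otf` returns
m·(H̃ + ½H̃(k±p)) for two beams and m·(3H̃ + 2H̃(k±p) + H̃(k±2p)) for
three — weights proportional to 2:1:1 and 3:2:2:1:1, with the absolute
scale set so it equals the FFT of a reconstructed unit point source.

The mixing-matrix separation is deliberately performed pixelwise in real
space (a per-pixel linear solve, no FFT), keeping the classical pipeline
maximally independent of the FFT-based forward model it cross-checks.

### ISM pixel reassignment

`ism_reassign` deposits each camera pixel at
scan + (β/2)·(pixel − scan), with β = λ_em/λ_ill, on a 2× upsampled
grid with bilinear weights; displacements use the minimal-image
convention on the periodic grid. The β/2 fraction is the geometric
midpoint rule; the Gaussian-PSF-optimal fraction 1/(1+β²) found
elsewhere in the ISM literature differs slightly for β ≠ 1 and is not
implemented.

## Nonlinear responses

Irradiance is dimensionless — multiples of the saturation irradiance
1/(στ) (photons per absorption cross-section per lifetime). Responses:
identity; integer power I^N; continuous-wave saturation I/(I + 1/τ);
pulsed saturation 1 − exp(−(Iσ + 1/τ)t_p) with the proportionality
constant fixed to 1. Polynomial harmonic strengths are computed exactly
with rational arithmetic, s_n = (N!)²/((N+n)!(N−n)!) (row 2N of
Pascal's triangle over its centre); the numerical analyzer reads them
off the DFT of the response applied to a unit-contrast sinusoid with a
whole number of periods, agreeing to 1e−10. The saturated-response
curves use CW saturation at mean irradiance 1 (one photon per
cross-section per lifetime) as the reference condition; harmonics then
decay geometrically beyond n = 1 and the first harmonic weakens
monotonically as irradiance rises. `extension_factor(n) = n + 1` is the
resolution multiple with n usable harmonics and a pattern at the
detection cutoff; a response with a finite harmonic count is always
band-limited, so only a non-polynomial response removes the limit.

## Synthetic data

The generator emulates the *structure* of standard simulation phantoms,
not any published pixel data:

- `periodic`: a broadband random field synthesized in the Fourier
  domain with a 1/(0.02+k) amplitude envelope and the DFT axes zeroed,
  so spectra show no axis-aligned "cross" and spectral-extension
  measurements are clean. Exactly periodic by construction.
- `beads`: Gaussian spots with an enforced minimum separation (torus
  metric, rejection sampling).
- `spokes`: a Siemens-star target whose local spatial frequency grows
  toward the centre.
- `bitmap_text`: rasterized text (Pillow's built-in font), also used as
  the arbitrary illumination pattern.

All phantoms are non-negative and bit-reproducible from a seed. Noise
(Poisson, optionally plus Gaussian read noise) is off by default so
every reconstruction identity is exact; with noise on, frames are
scaled to a mean total of 10⁶ photons before sampling from one seeded
RNG stream per stack. What passing tests show is therefore internal
consistency of the model and reconstruction algebra on ideal data —
they do not demonstrate robustness to pattern miscalibration, sample
motion, aberrations or realistic background, all of which real data
have.

## Default study conditions

Calculators use the published high-NA TIRF-SIM parameters (488/510 nm,
NA 1.58 illumination, effective NA 1.38 detection, 2.4 for the diamond
bound). Simulations default to a water-immersion-like configuration:
NA 1.2, n = 1.33, 488/510 nm, 20 nm pixels, 256² grids, fringe
frequency at 90% of the illumination cutoff, three phases (five for
three-beam), MSIM pitch 640 nm with a 4×4 raster. These sizes keep every
pipeline identity testable at machine precision while running in
seconds.

## Known limitations

- Pattern parameters are assumed known exactly (the simulator knows its
  own fringes); no pattern/phase estimation from data, no blind SIM.
- Circular convolution wraps bright structure across edges for
  non-periodic samples unless padded.
- The whitening floor is a hard threshold; on experimental data a
  noise-adaptive rule would be needed.
- Multifocal lattices are square; hexagonal lattices are not offered.
- TIRF patterns are in-plane irradiance only — the axial decay is a
  scalar prefactor, never a 3D field.
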