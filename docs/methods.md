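# Methods

## Forward model

A thin sample with complex transmission `o(r) = A(r) e^{i phi(r)}` is
illuminated by a quasi-plane wave from LED *m* with transverse wave vector
`U_m`. The microscope's objective passes the circular sub-aperture of the
object spectrum `O(u)` centred at `U_m` and weighted by the pupil function
`P(u)`, so the camera records

```
I_m(r) = | F^{-1}{ O(u - U_m) P(u) } |^2 .
```

All FFTs are *centred*: `fft2c = fftshift . fft2 . ifftshift` and its
inverse, so the DC bin sits at the array centre and sub-apertures are plain
array crops. The capture field carries the scale `(n_lr / n_hr)^2` so that
simulated intensities live on the object's own brightness scale (a uniform
object of amplitude `A` yields frames of intensity `A^2`).

### Geometry

The reference system (the defaults of `SystemGeometry`): 15×15 LEDs on a
4 mm pitch, 90.88 mm below the sample, wavelength 531 nm, a 4×/0.1 NA
objective, camera pixel 1.845 µm, a 512×512 high-resolution grid with
upsampling factor 4 (so captures are 128×128). Derived quantities:

* frequency step `du = 1 / (n_hr · hr_pixel)` ≈ 0.016938 µm⁻¹;
* pupil (NA cutoff) radius ≈ 11.12 frequency pixels;
* each LED ring shifts the sub-aperture by ≈ 4.9 pixels
  (`sin θ` per pitch step ≈ 0.04397);
* synthetic NA ≈ 0.4995, neighbouring sub-aperture overlap ≈ 72 %.

LED wave vectors use the exact radial construction
`sin θ = d / sqrt(d² + h²)` per axis, are rounded to the nearest frequency
pixel, and are processed centre-outward (by ring, then radius, then angle),
the standard FPM sweep that lets low frequencies stabilise first.
Geometries whose outermost sub-aperture falls off the grid are rejected.

### Aberrations and Zernike machinery

The pupil is `P(u) = exp(2 pi i W(u))` inside the NA disk and zero outside,
where `W` (in waves) is a sum of unnormalised Zernike polynomials in a
15-mode table ordering (piston, tilts, astigmatisms/defocus, comas/
trefoils, sphericals/tetrafoils), extended to 25 modes. Hybrid aberrations
draw every coefficient independently from `U(-bound, bound)` with
`bound = 0.2` waves by default. `zernike_decompose` performs ordinary
least squares on the support pixels (the modes are not orthogonal over the
discrete disk, so projection would be wrong) and refuses supports with
fewer than twice the number of modes.

### Synthetic scenes

Three procedural patterns (`blobs`, `speckle`, `strokes`) generate
amplitude in [0.1, 1] and phase in [0, 1] rad from independent
sub-streams of one seed. Their spatial scales are chosen so that
essentially all scene energy lies inside the synthetic-NA passband (the
information actually measured) while a substantial share lies beyond the
objective's own passband — otherwise reconstruction errors would be
dominated by an information-theoretic band-limit floor no algorithm can
beat. With the reference geometry the residual floors are ≈ 0.018–0.02
RMSE for `blobs`/`speckle`. Photographic test images (e.g. the classic
camera-operator amplitude / grass phase pair) have wide spectra and a
floor near 0.08; see Limitations.

## Reconstruction

All four algorithms share one engine. Per pass, frames are visited in
centre-outward order; for frame *m* the current sub-spectrum crop is
propagated to the camera, (optionally) denoised measurements replace the
field's amplitude, and the back-propagated difference
`Delta = Phi' - Phi` drives the update:

* **AP** — `O += conj(P) / max|P|² · Delta` with the pupil fixed at the
  ideal disk.
* **AA** — adaptive spectrum step
  `O += (alpha - w1) conj(P) / (|P|² + zeta1·max|P|²) · Delta` with
  `w1 = |P| / max|P|`, plus offset denoising. The adaptive factor is
  `alpha = max|P|² + (1 - tau)`, where `tau` is the mean of the per-frame
  denoise thresholds collected during the *previous* pass (0 on the first
  pass); with `tau = 0` and a unit pupil, `alpha = 2`.
* **EPRY** — AP-style object step plus a weighted regularised PIE pupil
  step on the *pre-update* sub-spectrum `S`:
  `P += (|S|/max|S|) · conj(S) / (|S|² + 1e-6·max|S|²) · Delta`.
  The weighting is essential: the plain quotient
  `conj(S)/max|S|² · Delta` has per-pixel gain `(|S|/max|S|)²`, and since
  natural-scene spectra are DC-dominated that gain is ~10⁻⁶ almost
  everywhere — the pupil never learns. The weighted form's gain is first
  order in `|S|/max|S|` and recovers the pupil reliably. The
  regularisation constant must stay small (10⁻⁶ of the peak power);
  10⁻⁴ already strangles the update.
* **AA-P** — the adaptive spectrum step, then an adaptive pupil step using
  the *freshly updated* sub-spectrum `S'` (a sequential Gauss–Seidel
  sweep): `P += (beta - w2) conj(S') / (|S'|² + zeta2·mean|S'|²) · Delta`
  with `w2 = |S'|/max|S'|`, followed by clamping the pupil modulus to
  ≤ 1 (a transmission) and zeroing outside the NA support. `zeta2`
  references the *mean* sub-spectrum power (the peak would reintroduce the
  DC-domination problem); its default 10 damps the step enough to stay
  stable across random hybrid aberrations.

Denoising subtracts per frame the offset
`thr = mean(I_measured) - mean(I_estimated)` and clips at zero; it is the
adaptive algorithms' native pre-step and is enabled for `aa`/`aap` by
default, disabled for `ap`/`epry` (overridable).

Convergence is tracked by the relative intensity-domain error
`sum_m mean (sqrt(I_m) - |psi_m|)² / sum_m mean I_m`, accumulated during
the pass; iteration stops at the cap (15 by default) or when the relative
change drops below 10⁻⁴. The study protocol throughout the tests and the
benchmark is exactly these defaults.

## Gauge freedoms and evaluation

Three transformations leave every measured intensity unchanged and are
removed before scoring:

1. **global phase** of the recovered field;
2. **tilt–shift**: a linear pupil phase is equivalent to a lateral object
   shift. Evaluation registers the recovered field to the reference by
   upsampled cross-correlation and moves the matching linear ramp back
   into the pupil before comparing pupil phases;
3. **scalar gauge**: a uniform complex factor can be traded between object
   and pupil transmission. Property tests compare fields and pupils modulo
   a least-squares complex scalar.

Amplitude RMSE min-max normalises both images; phase RMSE wraps the
pointwise difference, removes its mean and scales by the true phase range.
Pupil quality is the mean SSIM between the unwrapped, piston-free
recovered pupil phase and the true wavefront over the NA support.

## Observed behaviour and limitations

* **Ranking.** Under hybrid aberrations of 0.2 waves per mode the four
  algorithms order AP > AA > EPRY > AA-P in both amplitude and phase RMSE
  at the 15-iteration protocol, with AA-P reaching pupil SSIM ≈ 1.00 and
  Zernike recovery within a few thousandths of a wave. Given a much longer
  budget (≈30+ iterations) EPRY closes most of the gap to AA-P; the
  adaptive pupil step buys speed, not a different fixed point.
* **Limit cycle.** AA-P's error trace decreases strictly to a plateau
  around 10⁻³ and then jitters slightly (the near-`alpha = 2` steps
  overshoot); it never diverges. Tests encode this as: strict decrease
  until the trace minimum, bounded jitter afterwards.
* **Denoising under uncorrected aberration.** The offset-subtraction
  denoiser assumes the residual is a DC offset; with a strongly aberrated
  pupil that assumption misfires and degrades AA's phase estimate. It is
  harmless once the pupil is being corrected (AA-P).
* **Band-limit floor on photographic scenes.** Wide-spectrum photographic
  images carry substantial energy beyond the synthetic NA; no algorithm
  can reconstruct it, which floors the amplitude RMSE near 0.08 for the
  camera-operator image regardless of pupil quality. Relative
  improvements between two floor-limited algorithms are therefore small
  even when one recovers the pupil perfectly and the other does not.
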