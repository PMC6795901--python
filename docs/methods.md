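# Methods

## Forward model

A specimen is a non-negative emitter density S(x, y, α) on a regular spatial
grid (default 20 nm) and a periodic angular grid over [0°, 180°). The default
angular grid is **15 bins of 12°**: a 12.5° step does not tile the half-turn
evenly, and an uneven wrap would alias the first angular harmonic that the
whole method rests on. Angular integrals use the midpoint rule; because the
illumination and detection factors contain only angular frequencies 0 and
±1/π per radian, the midpoint rule is *exact* for any n_α ≥ 3 (trigonometric
degree), so the coarse angular grid costs no accuracy.

One frame is D = [Σ_α S · I · F Δα] ⊗ PSF, evaluated on the fine scene grid,
blurred through the optical transfer function, box-binned to the camera grid
(default 80 nm), then degraded by Poisson shot noise (`photon_scale` photons
per unit signal; scenes are normalized so the brightest pixel has unit total
density, making the photon budget well defined) plus Gaussian read noise.
Fine-grid blocks are centered on the camera samples, so binning is
phase-neutral and the protocol phases remain exact on the camera grid.

The detection model is the paraxial incoherent OTF of an unaberrated circular
pupil (the pupil-autocorrelation "chinese hat"), cutoff k_c = 2·NA/λ with the
*emission* wavelength (default 610 nm, NA 1.4 → k_c ≈ 4.59 µm⁻¹, Abbe limit
≈ 218 nm). No vectorial high-NA effects, no axial dimension, no
photobleaching — the simulator emulates a well-corrected 2-D acquisition, so
passing tests demonstrate algorithmic correctness, not robustness to
aberrations, drift between frames, or out-of-focus background.

Default protocol: polarizations θ = 0°, 60°, 120°; phases 0, 2π/3, 4π/3;
stripes parallel to the polarization (s-polarized interference), so the
stripe normal is θ + 90° (a flag flips this for unusual systems); stripe
frequency 0.9·k_c, typical of commercial 2-D SIM; modulation m = 1.

## Reconstruction

**SIM step.** Per direction the three frames are solved per spatial frequency
with the phase matrix rows [1, (m/2)e^{iφ_j}, (m/2)e^{−iφ_j}] — an exact 3×3
inverse, no regularization. The matrix omits constant prefactors so that the
back-transformed zeroth component equals the plain three-phase average, which
is also how the widefield image is defined. Repeated phases (mod 2π) raise a
conditioning error naming the pair. m is clamped to [0.05, 1] to bound the
amplification of a mis-estimated modulation.

**Pattern estimation.** The stripe vector is found by *phase correlation*
between the whitened zeroth and +1 components: whitening (dividing each
spectral bin by its magnitude) removes the scene's spectral coloring, which
otherwise buries the stripe peak under the scene autocorrelation. The coarse
peak (searched in an annulus, default 0.1–0.48 cycles/px) is refined to
sub-pixel precision by a simplex search, then polished on the un-whitened
overlap correlation. The starting phase is the complex argument at the
optimum, **referenced to the field-center pixel**: the origin-referenced
phase is ill-conditioned because it trades off against the residual k-error
times the scene centroid. (k, φ) and (−k, −φ) describe the same pattern; a
canonical half-plane (k_x > 0, with a 10⁻³ cycles/px axis tolerance) is
reported. Typical accuracy on the synthetic scenes: |Δk| < 10⁻³ cycles/px,
|Δφ| < 5 mrad noise-free; modulation is the cross/auto correlation magnitude
ratio at the optimum. A stack with no detectable stripes (modulation below
0.05 or correlation peak below 4× the annulus median) raises
"no stripes detected".

**PM step.** The three zeroth components mix the angular harmonics through
rows (η/2)·[1, ½e^{−2iθ_i}, ½e^{2iθ_i}]; exact inversion yields the angular
DC s₀ and the first harmonic h = Σ_α S e^{2iα} Δα. Package convention:
**arg h = +2α** (h is the coefficient paired with e^{−2iθ}); a unit test pins
this sign against the absorption law. Degenerate polarization sets raise an
error naming the angles.

**Assembly.** Components are registered by sub-pixel Fourier shift on a 2×
zero-padded grid and combined by a generalized Wiener filter: numerator
Σ conj(OTF_c)·H_c, denominator Σ OTF_c² + w (default w = 0.05 on the
normalized OTF², a config key), apodized by a cone to the doubled cutoff
k_c + |k_pattern|. Two modes produce the maps:

- `"hyperspace"` (default): the literal nine-component reciprocal-space
  assembly — the angular-DC plane holds the zeroth plus six shifted spatial
  components (super-resolved B), the ±1 angular planes hold the PM-solved
  harmonics (diffraction-limited A and α); the unsolvable cross harmonics
  are zero. This is the method's native information structure.
- `"perdir"`: each direction's own three components are assembled into a
  super-resolved image under that polarization and the three images are fit
  per pixel. The naive version of this biases orientation by 3–4° on
  structures not aligned with a polarization axis, because each direction's
  effective transfer is anisotropic along its own stripe axis and the
  three-point cosine fit ratios unequally-filtered images. The implementation
  therefore equalizes the three spectra to their pointwise minimum transfer
  before the fit, which removes the bias (< 2° circular RMS on the star) at
  the cost of restricting the orientation information to the common support —
  the same trade the hyperspace mode makes openly.

Both modes agree on orientation within 2° circular RMS on noise-free scenes.
The per-pixel cosine fit is closed-form: solve (B, A cos 2α, A sin 2α)
linearly, A = hypot ≥ 0, α = ½·atan2 reduced to [0°, 180°). Pixels with
A + B below `mask_frac` (default 5%) of the 99.9ᵗʰ-percentile intensity are
masked — orientation is meaningless at background level. p = 2A/(A+B) is
*not* clamped above 1; noise can push it over, and `DipoleFit.p_overrange`
flags such pixels instead of silently truncating.

## Calibration

Sparse isotropic beads report the per-direction excitation gain. Beads are
localized by local maxima plus a background-subtracted 7×7 intensity-weighted
centroid (≈ 0.05 px accuracy on synthetic spots); beads matched across all
three directions within 1 px contribute their intensity divided by the
cross-direction mean; a degree-5 ("quintic" — the sensible reading of the
protocol's nonstandard term) 2-D polynomial is fit per direction on
[-1, 1]-normalized coordinates and normalized to unit mean. Note the fitted
field is the *cross-direction relative* gain gᵢ/mean_i gᵢ — exactly what the
PM step needs, since any common spatial envelope cancels in the per-pixel
fit. Compensation defaults to the separated zeroth components (before the PM
step); a frames-stage option and an optional Wiener-regularized OTF division
(ε = 10⁻³; the bare inverse filter is unstable at the cutoff) exist behind
config keys. An imposed 0.7→1.3 gradient (≈ 50% swing, the realistic
outer-FOV magnitude) biases orientation by ~4° and calibration brings the
residual under 0.3°.

## Cross-harmonic ablation

`ablate_cross_harmonics` Fourier-transforms the ground-truth scene over
(x, y, α), keeps either the nine pSIM-observable pedals or all 21 of the
doubled region, inverse-transforms and extracts (intensity, α, p). Both
regions share the angular-DC plane, so the intensity null result is exact;
orientation is *exactly* preserved for an isolated structure (band-limiting a
constant-phase complex field cannot rotate its argument) and degrades only
through crosstalk between structures closer than the diffraction limit in
the angular planes. The shipped verification scenes (4-line radial star,
concentric circles) keep line separations above the widefield limit
everywhere, isolating the cross-harmonic question from crowding; the default
8-line Siemens star is kept for resolution tests, where crowding is the
point. The polarization factor, by contrast, picks up high-frequency
deviations of 0.05–0.4 — the one quantity the missing cross harmonics
genuinely affect.

## Analysis utilities

Harmonic census: for leakage-free analytic patterns every spectral bin above
threshold (default 10⁻³ of the maximum; counts are stable over 10⁻⁶–10⁻²) is
one harmonic, classified dc/spatial/angular/cross by its index signature —
the angular harmonics always sit in the bins adjacent to DC, which is why a
local-maximum census would miss them. Orientation statistics use the
doubled-angle circular mean and the wrapped standard deviation about it
(differences wrapped to (−90°, 90°]; a uniform axial distribution gives
180/√12 ≈ 51.96°). Histogram bins are 5°. The structure-tensor reference
direction uses σ = 2 px Gaussian gradients. Line-profile periodicity:
linear interpolation along the polyline, mean subtraction, Hann window,
rFFT, parabolic peak refinement; a peak below 4× the median spectrum is
"no significant period". Pseudocolor: hue = 2α, saturation = min(p, 1),
value = normalized intensity; masked pixels are desaturated to gray; the
color wheel is emitted alongside every rendering.

## Problem sizes

The shipped tests and examples use 256²–512² scene grids (5–20 µm fields at
20–40 nm sampling), 64²–256² camera frames, 250-bead calibration fields, and
20-seed noise ensembles at photon budgets of 500–1000 photons per brightest
pixel — sizes at which every pipeline stage is exercised at realistic SNR
while a full suite run stays in the minutes range on a laptop core.

## Known limitations

2-D in-plane orientation only (s-polarized excitation carries no axial
information); no 3-D SIM assembly; no blind/iterative reconstruction; the
gain calibration models smooth nonuniformity only (no fixed-pattern noise);
pattern estimation assumes the nominal phase *steps* are correct and
estimates only the global offset per direction; p is quantitatively reliable
only up to the cross-harmonic limitation inherent to the method.
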