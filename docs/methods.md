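# Methods

This note records the physical model behind `aosim`, the parameters that
matter, the numerical conventions, and the design choices made where the
design was genuinely open. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Optical model

The package uses scalar Fourier optics. The objective pupil is a uniform
circular aperture on normalized coordinates (ρ ≤ 1); aberrations enter as a
pupil phase `Σ_j a_j Z_j(ρ, θ)` over RMS-normalized (Noll) Zernike modes, so
coefficients add in quadrature to the wavefront RMS and one coefficient unit
is one radian of RMS phase. Piston is excluded. Amplitudes are radians *at a
declared reference wavelength* (default 525 nm, the green emission band);
`ZernikeVector.to_nm/from_nm` convert to wavefront nanometres, and vectors
with different reference wavelengths refuse to combine rather than silently
mixing units.

The intensity PSF is `|FT(P · e^{iφ_z})|²` per axial plane, with the exact
high-NA defocus phase `φ_z = k n z √(1 − (NA ρ / n)²)` (a paraxial
quadratic is available behind the `paraxial` flag). The pupil is sampled
directly on the image frequency grid `fftfreq(N, voxel_xy)`, so PSFs land on
the declared voxel grid with no resampling; with Nyquist-sampled voxels
(`voxel_xy ≤ λ_em/4NA`) this leaves ≥ 2× padding around the aperture.
Rendering refuses configurations whose pupil support exceeds the grid
Nyquist frequency.

Conventions, fixed in `aosim.optics` and used everywhere: arrays are
(z, y, x); PSF peak and OTF DC sit at the central index `N//2`; frequency
axes are reported in µm⁻¹ (1 nm⁻¹ = 1000 µm⁻¹); the OTF is the 3D DFT of
the intensity PSF.

**Accuracy caveat.** At NA 1.1 a vectorial PSF model would differ in detail
(polarization mixing, apodization); the scalar model conserves energy,
reproduces the correct cutoffs and defocus behaviour, and is sufficient for
exercising correction logic and resolution bookkeeping, which is this
package's purpose. Absolute PSF widths are therefore *better* than a real
instrument's (e.g. the simulated widefield lateral FWHM of ~245 nm at
NA 1.1/525 nm against ~333 nm measured on hardware of the same aperture);
comparisons inside the simulator are meaningful, absolute values are ideal
diffraction-limited ones.

## Virtual microscope

`VirtualScope` is the hardware stand-in: a phantom, a ground-truth
aberration (fixed vector, system-intrinsic term, and/or a depth model), a
DM model, a noise model, and a render counter (so tests can assert image
budgets exactly).

*Phantoms.* Bead fields (default 100 nm diameter, rendered as anti-aliased
spheres, or projected disks for single-plane scenes), curvilinear filaments
(Gaussian cross-section of declared FWHM; heading-angle diffusion sets the
curvature), and epithelial mosaics (boundaries of a nearest-seed tiling).
All are bit-identical under a fixed seed.

*Depth aberrations.* Affine per-mode growth `a_j(depth) = s_j·depth + c_j`,
reflecting that dominant depth aberrations (spherical foremost) scale with
focusing depth; an optional seeded per-mode random slope emulates specimen
inhomogeneity. When a plane is reached by remote focusing rather than stage
motion, the model is evaluated at the *imaged* depth, which is what the
light actually traverses.

*Deformable mirror.* Achieved = fidelity × clip(requested), restricted to
the correctable mode set (default Noll 2–22); out-of-set requests are
reported as uncorrectable residual, never silently dropped. An optional
single-exponential creep term (fractional amplitude, time constant) models
slow drift after a shape is set; it is off by default.

*Structured illumination.* Three-beam (0, ±1 order) interference. The
lateral pattern frequency is expressed as a fraction of the excitation
coherent cutoff `NA/λ_ex` — the highest frequency the ±1 orders can carry —
with default 0.8, a conservative line-width choice; a requested fraction
above 1 is physically impossible and raises. The first lateral harmonic is
modulated axially at the 0/±1 beat frequency (the 3D-SIM axial component);
the ±1/∓1 second harmonic is axially constant. Beam amplitudes are derived
from the declared focal-plane modulation depth m (default 0.9, a stated
stand-in: the measured depth of a real system depends on polarization and
scattering). Two-beam (2D-SIM) patterns are available via `axial=False`.
The five phase offsets are exact 2π/5 steps, so the phase sum is uniform to
machine precision — the identity behind pseudo-widefield.

*Image formation.* Locally shift-invariant: each focal plane is the sum over
object planes of 2D convolutions with the corresponding slice of the 3D PSF
for the aberration at that depth. Photon conversion is calibrated so a
unit-amplitude in-focus emitter in an unaberrated system yields the noise
model's `photon_budget` expected peak photons (default 500, with 2 e⁻ read
noise and 5 background photons — enough to make metric tests realistically
noisy); aberration then dims the image by the Strehl factor, as on hardware.
Shot noise is Poisson, read noise Gaussian, everything seeded.

## Sensorless correction

The metric is the Hann-windowed 2D power spectrum integrated over an
annulus [0.1, 0.9] × `2NA/λ_em`, minus the annulus-area-scaled mean power of
the band beyond the cutoff (default [1.02, 1.35] ×, clipped to Nyquist),
floored at zero; optional DC normalization makes it exposure-invariant. The
exact constants are exposed in `MetricConfig`. A constant frame scores zero
with a warning rather than raising, so a failed acquisition cannot crash a
correction loop.

The per-mode optimum is the mean of a Gaussian-plus-offset fitted to the
five (bias, metric) points. If the fit fails, its R² falls below 0.5, or the
mean lands outside 1.5× the scanned range, the routine falls back to the
max-metric bias and flags the scan; a correction in which *every* mode fell
back raises "correction unreliable". Modes are scanned in ascending Noll
order, each optimum accumulated before the next scan; one pass by default.

**Mode coupling and scan-range endpoints.** The scalar metric couples modes
of equal azimuthal symmetry — the pairs (7, 9), (8, 10) and (11, 22) — by
about 0.1 rad when the foreign aberration reaches 0.6–1 rad: a single pass
recovers the scanned-and-corrected aberration to ≲ 0.03 rad but can leave
~0.1 rad of spurious correction on a partner mode scanned before its
counterpart was corrected. Separately, when the true optimum sits at the
edge of the bias range (a 1 rad aberration scanned with ±1 rad biases), the
Gaussian is fitted from one-sided samples and its mean is biased. Both
effects are properties of sequential modal sensorless AO, not of this
implementation, and both vanish when the routine is re-run on top of its
own correction: a second pass (`passes=2`) nulls every mode to ≤ 0.01 rad
in the cases above, and the suite asserts that repeated passes never
increase the residual. The default remains a single pass — the 40-image,
seconds-long routine an operator runs before acquisition — with iteration
available when aberrations approach the scan-range edge.

The system flat is measured by running the same loop on a sparse bead scene
carrying only instrument-intrinsic aberration; the returned vector is passed
as `initial` to subsequent sample corrections, and results keep the two
contributions separate (`combined = system_flat + sample_correction` is the
DM-ready sum). Stored corrections are the amplitudes *applied to the DM*
(already negated), so they can be sent to the mirror as-is.

## MPAC and remote focusing

`mpac_fit` fits an independent least-squares line per mode over the union of
anchor modes (a mode missing at an anchor counts as zero there); two anchors
are interpolated exactly, and prediction is affine, so the method is exact
on the affine model class it assumes. Extrapolation beyond the anchor span
warns rather than raising — two-anchor usage at volume top and bottom is the
expected practice.

`refocus_phase` projects the high-NA defocus phase onto the rotationally
symmetric modes (4, 11, 22) by midpoint quadrature in ρ² (4096 nodes); the
sign convention is chosen so a positive shift images the plane at +z under
the renderer's axial-phase convention. The decomposition residual RMS
(piston removed) is returned, never dropped; it stays below 0.05 rad out to
±10 µm at NA 1.1/n 1.33. Requests beyond the declared DM range (±10 µm
default) raise.

Calibration sweeps commanded shifts (default ±5 µm, 11 steps), renders a
single-bead volume per command with the mechanical focus fixed, and
localizes the axial peak by centre-of-mass within ±3 planes of the maximum
followed by parabolic refinement (ties break toward smaller z). Step 1
(precision) is the linear regression of achieved on commanded shift; R²
below 0.99 over the requested range is a calibration failure that reports
the usable sub-range. Step 2 (accuracy) inverts a monotone cubic (PCHIP)
through the raw pairs, so systematic DM imperfections (e.g. 90% stroke
fidelity) are corrected when targeting a plane. Calibration belongs on a
dedicated single-bead scene: with several beads at different depths the
peak localization locks onto whichever bead is nearest the commanded plane
and the mapping inherits that bead's offset.

`remote_z_stack` images each target plane with mechanical focus untouched:
command = calibrated inverse of the target + MPAC prediction for that
depth, output layout identical to a mechanical stack. Targets outside the
validated range raise, listing the offending planes.

## Resolution metrics

Bead FWHM: 1D Gaussian-plus-offset fits along x, y and z through each
detected bead; the lateral value is the x/y mean (isotropy assumption).
Rejection rules (declared, since any choice here is policy): fit R² < 0.95,
FWHM above 3× a supplied diffraction estimate, or a neighbour within 10×
the FWHM. The estimator is unbiased to < 0.5% on noiseless Gaussians for
σ between 100 and 400 nm.

Spectral (OTF-support) resolution: the volume mean is subtracted (a DC
offset carries no resolution information), a Hann window applied
(switchable), and the 3D power spectrum formed. The lateral profile is the
radial average of the central kxy plane; the axial profile folds the two
0 → ±kz directions of the central kxz plane and averages along kx. Log
power is normalised to [0, 1] between its noise floor and maximum, where
the floor is the mean over the highest-frequency 5% of bins but never more
than 8 decades below the maximum — noiseless synthetic data would otherwise
push the floor to numerical leakage tens of decades down, far below
anything a camera records. Values below the floor are clipped to it (the
pre-display noise threshold). The resolution is the reciprocal of the first
interpolated crossing below 0.01; a profile that never crosses reports the
grid-limited value with a flag. The axial estimate is reported but is
window-leakage-limited on short z-stacks; the lateral estimate matches
`2NA/λ_em` to within one frequency bin on the unaberrated PSF.

Modulation contrast: per pixel, the five-phase sequence is Fourier-analysed;
the contrast is `2|X₁|/X₀`, aggregated as a ratio of pixel means per
(angle, z, channel). On a pure sinusoid of depth m this returns exactly m
(the 5-point DFT separates the first and second pattern harmonics exactly).

## Acquisition bookkeeping

SIM volumes always carry the full 5-phase × 3-angle complement:
`frames = 5 · 3 · n_channels · n_z` (so 210 for 2 channels × 7 sections,
1200 for 80 sections in one channel), a z-stack spans `(n − 1) · step`
(16.0 µm for 129 sections at 125 nm), and a volume takes `frames/fps`
seconds (10.5 s at 20 fps for the 210-frame volume). Frame ordering is
phase-fastest by default (phase stepping is the cheapest state change);
any permutation can be declared, and stacks written under one permutation
read back into canonical order. Trigger tables reference a deduplicated
per-z set of precomputed DM patterns, mirroring a TTL-driven acquisition in
which all mirror shapes are uploaded beforehand.

## What the simulator does and does not show

Passing tests demonstrate that the correction loop, calibrations and
analyses are mutually consistent and match independent oracles (direct
Debye-integral quadrature for the PSF, the extended Maréchal relation
exp(−σ²) for Strehl, closed forms for pattern arithmetic). They do not
demonstrate performance on real tissue: the simulator has no scattering, no
field-dependent aberrations, no polarization effects, no reconstruction
step, and its phantoms are far sparser than real specimens. Problem sizes
in the suite (128² correction frames, 32–64-voxel calibration volumes,
≤ 33-plane stacks) were chosen as the smallest grids on which the measured
quantities are grid-converged to well inside the asserted tolerances.

## Known limitations

- Scalar diffraction; no vectorial high-NA effects.
- Per-plane shift-invariant blur; no spatially varying PSF within a plane.
- The Fourier metric's exact constants are this package's declared choice;
  other sensorless implementations weight the passband differently.
- The axial OTF-support estimate is leakage-limited on short stacks.
- SIM reconstruction itself (Wiener filtering) is out of scope; the raw
  stacks are the product.
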