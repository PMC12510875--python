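# Methods and numerical choices

This document records the physical model behind `tcbfstem`, the conventions
used throughout the code, and the numerical decisions that are not obvious
from the API alone.

## Physical model

### Tilt-corrected bright-field STEM

A defocused STEM probe illuminates the specimen over a grid of scan
positions; a pixelated detector records the bright-field (BF) disk at each
position. Each detector pixel at angle Θ from the optic axis forms a
"shadow image" of the specimen that is laterally displaced by the parallax
shift

    W(Θ) = Δf · Θ          (pure defocus)

and more generally by W = −(1/k₀) ∇χ(Θ), where χ is the probe aberration
phase and k₀ = 2π/λ. Measuring W(Θ) by cross-correlation, undoing it, and
summing the single-pixel images yields the tilt-corrected bright-field
(tcBF) image: incoherent-bright-field dose efficiency with phase-contrast
transfer. Because different detector pixels place their samples at
different sub-scan-pixel positions, the shift-corrected sum on a finer grid
recovers information beyond the scan Nyquist frequency.

### Contrast transfer

For a round aperture of semi-angle α and pure defocus, the tcBF transfer
function has the closed form

    CTF_tcBF(ω) = −L(ω/α) · sin(½ k₀ Δf ω²)

where L(u) = (2/π)[cos⁻¹(u/2) − (u/2)√(1 − u²/4)] is the two-disk overlap
envelope, supported on ω ≤ 2α. The axial BF pixel alone transfers
sin χ(ω), the same oscillation without the envelope. `optics.ctf_tcbf`
implements the closed form; `optics.ctf_tcbf_numeric` integrates the tilted
weak-phase transfer function over the aperture and converges to it, which
is used as an internal oracle. The first-moment (center-of-mass) DPC
transfer equals ω/α·L(ω/α)/2 inside the aperture, so the integrated-DPC
curve normalized at the origin equals L(ω/α) exactly
(`optics.pctf_idpc`). Detective-quantum-efficiency curves for tcBF, DPC
and iDPC are the squared transfer per unit dose (`optics.dqe_curves`).

### Mean free paths and dose efficiency

Thickness t attenuates the energy-filtered (zero-loss) TEM signal as
exp(−t/λ_in′), with λ_in′ = λ_in·a/(a+1) the high-angle-corrected
inelastic mean free path (a is the measured ratio of the high-angle to the
inelastic path; a = 46 gives the factor 0.979 and 303 nm for vitreous ice
with λ_in = 310 nm). tcBF collects everything except high-angle elastic
scattering, decaying as exp(−t/λ_el) with λ_el ≈ 830 nm. The retained-dose
ratio between the two grows as exp(t/λ_eff) with
1/λ_eff = 1/λ_in′ − 1/λ_el (≈ 500 nm for ice). `scattering.fit_elastic_mfp`
recovers λ_el from (thickness, fraction) series by a through-origin
least-squares fit of ln(fraction) against thickness.

## Conventions and units

- Lengths in ångström (thickness helpers in the `scattering` module use
  nanometres, as stated in their docstrings); angles in radians; voltage
  in kV; spatial frequency in 1/Å.
- Scan arrays are row-major with the row as the slow axis, 0-based.
- Detector angles are measured from the fitted disk center:
  Θ = (index − center)·Δα.
- Shift sign: W(Θ) is the translation mapping the reference image onto the
  pixel image; reconstruction applies −W. Pure positive defocus gives an
  outward-pointing shift field W = Δf·Θ.
- χ(Θ) = −½ k₀ Δf |Θ|² + astigmatic and spherical terms; the axial BF
  transfer is +sin χ.

## Numerical choices

### Aperture quadrature by signed distance

Transfer-function integrals over the aperture (and over shifted-aperture
overlaps) use a uniform Cartesian grid with fractional cell coverage
computed from the signed distance to the nearest disk edge,
`clip(d/h + 0.5, 0, 1)`. The minimum of the signed distances to all
bounding disks tracks the true region boundary even where two edges nearly
coincide, giving smooth convergence of edge-dominated integrals without
adaptive meshing.

### Registration and iterative reference

Per-pixel images are registered by phase cross-correlation with
transform-upsampled local peak refinement and no spectral normalization
(plain cross-correlation is more robust for smooth, low-contrast BF
images). Iteration 0 registers against the axial-pixel image; subsequent
iterations register against the running shift-corrected weighted mean,
with the axial pixel re-zeroed each pass. Convergence is declared when the
maximum shift update falls below 0.05 scan pixels (default 3 iterations).

### Global offset as a nuisance parameter

Re-zeroing on a single axial pixel leaves a small global offset in the
measured shift field (the axial pixel's own registration noise). The
aberration-surface fit therefore includes a constant 2-vector intercept as
a nuisance parameter; a global image translation is unobservable and does
not bias the recovered defocus or astigmatism.

### Acquisition design rule for parameter-recovery simulations

The parallax spread across the BF disk is α·Δf. Recovery simulations keep
α·Δf ≈ 5 scan pixels (40 Å at an 8 Å step): enough sub-pixel leverage for
the fit, while staying well clear of the periodic field of view. This rule
is set by geometry, not tuned per dataset.

### Reconstruction by kernel-density splatting

Each masked pixel's virtual image is accumulated onto the upsampled grid
at its shift-corrected positions with bilinear (triangle-kernel) weights,
and the sum is divided by the accumulated coverage. Splatting the original
samples — rather than interpolating each image first — is what folds the
aliased super-Nyquist content back to its true frequencies and enables
super-resolution. A band-limited alternative (Fourier-upsample each image,
then roll) would suppress the aliases instead and cannot resolve beyond
the scan Nyquist.

The triangle kernel multiplies the spectrum by sinc² per axis of the fine
grid, reaching (2/π)² per axis at that grid's Nyquist frequency. This
attenuation is deterministic and known, so it can be removed exactly by
dividing the spectrum by the kernel transform
(`parallax.correct_kernel_rolloff`), the standard roll-off correction of
gridding reconstructions. Apply it before comparing power spectra of
reconstructions made at different upsampling factors; otherwise the
coarser grid's band edge appears attenuated by up to (π/2)⁴ in power
relative to the same frequencies on a finer grid.

When comparing an upsampled and a non-upsampled reconstruction inside the
scan Nyquist band, also restrict both spectra to the same discrete
frequencies by band-limiting the upsampled image to the scan grid
(`parallax.fourier_downsample`); radial bins otherwise average different
frequency sets and differ for purely geometric reasons. A small residual
difference remains in the outermost bins because the non-upsampled image
retains aliases of just-above-Nyquist content that the upsampled image
relocates to its true frequencies — that relocation is the point of
upsampling.

## Simulator realism and limits

`phantom_sim` implements a single-slice weak-phase/amplitude object with a
Fourier-propagated defocused probe, optional inelastic blur, exponential
thickness attenuation, and Poisson counting noise (seeded per scan
position from one root seed). It reproduces: parallax shifts W = Δf·Θ,
the BF-disk geometry, defocus contrast oscillations, dose statistics and
the aliasing behavior needed for super-resolution tests. It does not
model: dynamical (multislice) scattering, energy-dependent inelastic
angular distributions, detector MTF, source size, scan distortion, or
beam-induced motion. Quantities that depend on those effects — recorded
experimental micrographs, single-particle reconstructions from many
particles, and multislice predictions of the elastic mean free path — are
out of scope for this package and are not validated by its test suite;
the analytic and simulation-backed properties above are.

## Scope and exclusions

In scope: transfer-function theory for tcBF/DPC/iDPC, mean-free-path and
thickness arithmetic, the forward simulator, parallax measurement and
reconstruction, acquisition-design arithmetic, and file/CLI plumbing
(HDF5 datacubes, MRC/TIFF images, CSV/JSON reports, TOML run configs).

Out of scope: processing of experimental micrographs beyond the provided
containers, GPU execution, movie-mode/beam-induced-motion correction,
scan-distortion correction, ptychographic refinement, single-particle
workflows, and multislice simulation.
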