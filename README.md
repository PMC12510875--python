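# tcbfstem

Tilt-corrected bright-field STEM (tcBF-STEM) simulation, reconstruction and
design toolkit.

In a defocused STEM acquisition with a pixelated detector, every detector
pixel inside the bright-field disk records a shadow image of the specimen
displaced by the parallax shift `W(Θ) = Δf·Θ`. Measuring those shifts by
cross-correlation, undoing them, and summing the per-pixel images yields a
phase-contrast image with near-incoherent dose efficiency; because the
corrected samples land at sub-scan-pixel positions, accumulation on a finer
grid recovers information beyond the scan Nyquist frequency. This package
implements that pipeline end to end, together with the supporting
transfer-function theory, mean-free-path/thickness arithmetic for thick
cryo specimens, a seeded 4D-STEM forward simulator for validation, and
acquisition-design helpers.

## Modules

| Module        | Contents |
|---------------|----------|
| `optics`      | wavelength/aberrations, tilted weak-phase CTF, closed-form tcBF CTF with overlap envelope, DPC/iDPC curves, DQE comparison |
| `scattering`  | inelastic/elastic mean free paths, high-angle correction, thickness maps, through-origin MFP fitting |
| `phantom_sim` | phantoms (gold-on-carbon, membranes, point grid), defocused-probe 4D-STEM simulator with Poisson noise, attenuation and inelastic blur |
| `parallax`    | BF-disk detection, per-pixel virtual images, iterative sub-pixel shift measurement, aberration-surface fitting/regularization, upsampled splatting reconstruction, radial power spectra, DPC images |
| `design`      | acquisition-design report (blur, step bounds, depth of field, information limits, speed-up) |
| `io` / `cli`  | HDF5 datacube container, MRC/TIFF images, CSV/JSON reports, TOML run configs, `tcbfstem` command-line interface |

## Worked example

Simulate a gold-on-carbon phantom at 300 kV, 8 mrad, 500 nm defocus
(32×32 scan at 8 Å, 48×48 detector pixels), then reconstruct:

```sh
$ tcbfstem --seed 1 simulate --defocus-nm 500 --out datacube.h5
wrote datacube.h5
$ tcbfstem reconstruct --in datacube.h5 --upsample 8 \
      --out-image tcbf.mrc --out-shifts shifts.csv
wrote tcbf.mrc
fitted defocus 5049.2 A (R^2 = 0.9963)
```

The reconstruction report (`reconstruct_report.json`) shows the measured
shift field recovering the simulated 5000 Å defocus within 1%:

```json
{
  "fitted_defocus_A": 5049.2,
  "residual_rms_A": 1.15,
  "r_squared": 0.9963,
  "n_bf_pixels": 1187,
  "bf_radius_mrad": 7.97,
  "upsample": 8,
  "pixel_size_A": 1.0
}
```

Acquisition-design numbers for the same conditions:

```sh
$ tcbfstem design --alpha-mrad 8 --defocus-nm 500 --scan-step-angstrom 8
probe_blur_diameter     80.0      # 2*alpha*defocus, A
max_step_gap_free       56.6      # sqrt(2)*alpha*defocus, A
recommended_step        40.0      # alpha*defocus, A
max_upsampling          32.0      # alpha/delta_alpha
depth_of_field          615.2     # 2*lambda/alpha^2, A
scan_nyquist_period     16.0      # 2*step, A
```

Mean-free-path arithmetic from a thickness series (collected fractions of
the incident dose on three lamellae, energy-filtered TEM vs tcBF-STEM):

```python
>>> import numpy as np
>>> from tcbfstem.scattering import fit_elastic_mfp, lambda_in_prime
>>> lambda_in_prime(310.0, 46.0)        # high-angle-corrected inelastic MFP, nm
303.40425531914894
>>> t = -310.0 * np.log(np.array([0.171, 0.114, 0.143]))   # thicknesses, nm
>>> fit_elastic_mfp(t, np.array([0.533, 0.403, 0.522]))    # elastic MFP, nm
(828.0603810218522, 58.57828923167983)
```

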