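"""Synthetic 4D-STEM generator for defocused-probe phase-contrast imaging.

Single-slice forward model: a weak-phase specimen multiplies the defocused
probe, the far-field intensity gives the convergent-beam (CBED) pattern, and
Poisson noise is drawn at the configured dose.  Thick-specimen behavior is
emulated with exponential attenuation of the coherent signal (elastic mean
free path) plus an inelastically scattered fraction that is angularly
blurred in the detector plane — inelastic scattering in ice mostly preserves
the elastic contrast and blurs the angular distribution by well under a
milliradian, so the blur width is a small fraction of the aperture angle.

All test inputs for the reconstruction pipeline come from here; the
generator is deterministic under its seed, with one counter-based stream per
scan position so patterns do not depend on iteration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import AberrationSurface, OpticalConfig, chi
from .scattering import MFPModel
from .parallax import DataCube4D

__all__ = [
    "WeakPhaseObject",
    "SimConfig",
    "make_phantom",
    "build_probe",
    "simulate_datacube",
    "attenuation_pair",
]


@dataclass
class WeakPhaseObject:
    """Projected specimen: phase map (rad), amplitude map and pixel size (A).

    ``thickness`` (nm) is optional and drives attenuation and inelastic
    blur during simulation.
    """

    phase: np.ndarray
    pixel_size: float
    amplitude: np.ndarray | None = None
    thickness: float | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.amplitude is None:
            self.amplitude = np.ones_like(self.phase)
        else:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if np.any(self.amplitude < 0) or np.any(self.amplitude > 1):
                raise ValueError("amplitude must lie in [0, 1]")

    @property
    def transmission(self) -> np.ndarray:
        """Complex transmission function a(r) * exp(i*phi(r))."""
        return self.amplitude * np.exp(1j * self.phase)


def make_phantom(kind: str, size: int, pixel_size: float,
                 params: dict | None = None, seed: int = 0) -> WeakPhaseObject:
    """Generate a weak-phase test specimen.

    Kinds
    -----
    ``gold_on_carbon``
        Strong-phase disks carrying a sinusoidal lattice (default spacing
        4.6x the pixel size, the 2.3-A lattice analogue at half-angstrom
        sampling) over a low-amplitude smooth background.
    ``membranes``
        Paired parallel ridges (bilayer analogue) at configurable
        separation.
    ``point_grid``
        Sparse Gaussian bumps; a single centered bump by default.
    """
    if size < 64:
        raise ValueError("phantom size must be at least 64 pixels per side")
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size] * pixel_size
    phase = np.zeros((size, size))

    if kind == "gold_on_carbon":
        spacing = p.get("lattice_spacing", 4.6 * pixel_size)
        if spacing < 2.0 * pixel_size:
            raise ValueError(
                f"lattice spacing {spacing} A is below twice the pixel size "
                f"({pixel_size} A): the lattice would alias")
        # smooth carbon-like background
        bg = ndimage.gaussian_filter(rng.normal(size=(size, size)), 6.0)
        phase += p.get("background_amp", 0.05) * bg / max(bg.std(), 1e-12)
        n_disks = p.get("n_disks", 12)
        r_lo, r_hi = p.get("disk_radius", (0.04 * size, 0.10 * size))
        disk_phase = p.get("disk_phase", 1.0)
        lattice_amp = p.get("lattice_amp", 0.25)
        lattice = np.zeros_like(phase)
        for ang in p.get("lattice_angles", (0.3, 1.5, 2.6)):
            kvec = 2 * np.pi / spacing * np.array([np.sin(ang), np.cos(ang)])
            lattice += np.cos(kvec[0] * yy + kvec[1] * xx + rng.uniform(0, 2 * np.pi))
        for _ in range(n_disks):
            cy, cx = rng.uniform(0.1 * size, 0.9 * size, 2) * pixel_size
            rad = rng.uniform(r_lo, r_hi) * pixel_size
            d = np.hypot(yy - cy, xx - cx)
            disk = 0.5 * (1.0 - np.tanh((d - rad) / (1.5 * pixel_size)))
            phase += disk * (disk_phase + lattice_amp * lattice)
    elif kind == "membranes":
        sep = p.get("separation", 40.0)
        width = p.get("ridge_width", 8.0)
        amp = p.get("ridge_phase", 0.3)
        for _ in range(p.get("n_pairs", 3)):
            ang = rng.uniform(0, np.pi)
            n = np.array([np.sin(ang), np.cos(ang)])
            offset = rng.uniform(0.25, 0.75) * size * pixel_size
            d = yy * n[0] + xx * n[1] - offset
            for side in (-0.5, 0.5):
                phase += amp * np.exp(-0.5 * ((d - side * sep) / width) ** 2)
    elif kind == "point_grid":
        sigma = p.get("sigma", 2.0 * pixel_size)
        amp = p.get("bump_phase", 0.5)
        centers = p.get("centers")
        if centers is None:
            spacing = p.get("spacing")
            if spacing is None:
                centers = [(size // 2 * pixel_size, size // 2 * pixel_size)]
            else:
                ax = np.arange(spacing / 2, size * pixel_size, spacing)
                centers = [(cy, cx) for cy in ax for cx in ax]
        for cy, cx in centers:
            phase += amp * np.exp(-0.5 * ((yy - cy) ** 2 + (xx - cx) ** 2) / sigma**2)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    return WeakPhaseObject(phase=phase, pixel_size=pixel_size)


def build_probe(cfg: OpticalConfig, ab: AberrationSurface, field_size: int,
                pixel_size: float, center: tuple[float, float] | None = None
                ) -> np.ndarray:
    """Defocused probe wavefunction on a ``field_size`` grid (unit intensity).

    Inverse transform of ``A(theta) * exp(-i*chi(theta))``.  Raises if the
    geometric blur disk ``2*alpha*|defocus|`` does not fit in the field.
    """
    extent = field_size * pixel_size
    blur = 2.0 * cfg.alpha * abs(ab.defocus)
    if blur > 0.8 * extent:
        raise ValueError(
            f"geometric blur disk {blur:.0f} A exceeds 80% of the field "
            f"{extent:.0f} A; enlarge the field or reduce defocus")
    kx = np.fft.fftfreq(field_size, d=pixel_size)
    fy, fx = np.meshgrid(kx, kx, indexing="ij")
    ty, tx = fy * cfg.wavelength, fx * cfg.wavelength
    ap = (np.hypot(ty, tx) <= cfg.alpha).astype(float)
    psi_k = ap * np.exp(-1j * chi(ab, cfg, tx, ty))
    if center is not None:
        psi_k = psi_k * np.exp(-2j * np.pi * (fy * center[0] + fx * center[1]))
    psi = np.fft.ifft2(psi_k)
    return psi / np.sqrt(np.sum(np.abs(psi) ** 2))


@dataclass
class SimConfig:
    """Acquisition parameters for :func:`simulate_datacube`.

    ``dose`` is in incident electrons per square angstrom (``None`` disables
    Poisson noise and returns expected intensities).  ``detector_shape``
    pixels are box-binned from the object's reciprocal grid;
    ``inelastic_blur_sigma`` (rad) is the angular width of the inelastic
    redistribution kernel and ``inelastic_contrast`` the fraction of elastic
    contrast preserved in the inelastic channel.
    """

    optics: OpticalConfig
    aberrations: AberrationSurface = field(default_factory=AberrationSurface)
    scan_shape: tuple[int, int] = (16, 16)
    scan_step: float = 8.0
    detector_shape: tuple[int, int] = (48, 48)
    detector_bin: int | None = None
    dose: float | None = None
    inelastic_blur_sigma: float = 0.0
    inelastic_contrast: float = 1.0
    attenuation: MFPModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose is not None and self.dose < 0:
            raise ValueError("dose must be non-negative")


def _bin2d(arr: np.ndarray, b: int) -> np.ndarray:
    ny, nx = arr.shape
    return arr.reshape(ny // b, b, nx // b, b).sum(axis=(1, 3))


def simulate_datacube(obj: WeakPhaseObject, sim: SimConfig) -> DataCube4D:
    """Simulate a 4D-STEM datacube from a projected specimen.

    For each scan position the probe is shifted (Fourier phase ramp, exact
    sub-pixel positioning), multiplied by the specimen transmission, and the
    far-field intensity is binned onto the detector grid.  If an attenuation
    model and specimen thickness are set, the pattern is scaled by
    ``exp(-t/lambda_el)`` and a fraction ``1 - exp(-t/lambda_in)`` is
    redistributed through the inelastic blur kernel.  Expected counts per
    pattern are ``dose * scan_step**2`` times the transmitted fraction.
    """
    n = obj.phase.shape[0]
    if obj.phase.shape[0] != obj.phase.shape[1]:
        raise ValueError("phantom must be square")
    cfg, ab = sim.optics, sim.aberrations
    px = obj.pixel_size
    extent = n * px

    dy, dx = sim.detector_shape
    b = sim.detector_bin or max(min(n // dy, n // dx), 1)
    if dy * b > n or dx * b > n:
        raise ValueError("detector_shape x bin exceeds the reciprocal grid")
    dtheta = cfg.wavelength / extent          # reciprocal pixel, rad
    det_pixel = b * dtheta
    if min(dy, dx) / 2 * det_pixel < cfg.alpha:
        warnings.warn("detector angular range is smaller than the aperture "
                      "semi-angle: the BF disk will be clipped", stacklevel=2)

    # scan grid centred on the field
    sy, sx = sim.scan_shape
    ry = (np.arange(sy) - (sy - 1) / 2.0) * sim.scan_step
    rx = (np.arange(sx) - (sx - 1) / 2.0) * sim.scan_step
    blur_radius = cfg.alpha * abs(ab.defocus)
    max_r = max(abs(ry[0]), abs(ry[-1]), abs(rx[0]), abs(rx[-1]))
    if max_r + blur_radius > 0.5 * extent:
        raise ValueError("scan area plus probe blur disk exceeds the phantom "
                         "field; enlarge the phantom or shrink the scan")

    freq = np.fft.fftfreq(n, d=px)
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    ty, tx = fy * cfg.wavelength, fx * cfg.wavelength
    ap = (np.hypot(ty, tx) <= cfg.alpha).astype(float)
    probe_k0 = ap * np.exp(-1j * chi(ab, cfg, tx, ty))
    # normalize so the real-space probe carries unit intensity
    # (sum |ifft2(probe_k0)|^2 = sum |probe_k0|^2 / n^2 = 1)
    probe_k0 = probe_k0 * (n / np.sqrt(np.sum(np.abs(probe_k0) ** 2)))
    trans = obj.transmission

    # attenuation bookkeeping (scalar thickness)
    el_frac, inel_frac = 1.0, 0.0
    sigma_px = 0.0
    if sim.attenuation is not None and obj.thickness is not None:
        model = sim.attenuation
        if model.lambda_el is None:
            raise ValueError("attenuation model needs lambda_el")
        el_frac = float(np.exp(-obj.thickness / model.lambda_el))
        inel_frac = float(1.0 - np.exp(-obj.thickness / model.lambda_in))
        sigma_px = sim.inelastic_blur_sigma / dtheta
    flat_cbed = np.fft.fftshift(np.abs(probe_k0) ** 2) / n**2  # object-free

    counts = np.empty((sy, sx, dy, dx), dtype=np.float64)
    c0 = n // 2
    y0, x0 = c0 - (dy * b) // 2, c0 - (dx * b) // 2
    root = np.random.SeedSequence(sim.seed)
    for iy in range(sy):
        for ix in range(sx):
            ramp = np.exp(-2j * np.pi * (fy * ry[iy] + fx * rx[ix]))
            psi = np.fft.ifft2(probe_k0 * ramp) * trans
            cbed = np.fft.fftshift(np.abs(np.fft.fft2(psi)) ** 2) / n**2
            if inel_frac > 0.0 and sigma_px > 0.0:
                src = (sim.inelastic_contrast * cbed
                       + (1.0 - sim.inelastic_contrast) * flat_cbed * cbed.sum())
                inel = ndimage.gaussian_filter(src, sigma_px, mode="constant")
                cbed = (1.0 - inel_frac) * cbed + inel_frac * inel
            cbed = el_frac * cbed
            pat = _bin2d(cbed[y0:y0 + dy * b, x0:x0 + dx * b], b)
            if sim.dose is not None:
                lam = sim.dose * sim.scan_step**2 * pat
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(iy * sx + ix,)))
                pat = rng.poisson(lam).astype(np.float64)
            counts[iy, ix] = pat

    # centre of the binned crop in detector pixel coordinates
    det_center = ((c0 - y0 + 0.5) / b - 0.5, (c0 - x0 + 0.5) / b - 0.5)
    return DataCube4D(
        counts=counts,
        scan_step=sim.scan_step,
        det_pixel=det_pixel,
        det_center=det_center,
        optics=cfg,
        metadata={
            "dose": sim.dose,
            "seed": sim.seed,
            "defocus_A": ab.defocus,
            "transmitted_fraction": el_frac,
            "pixel_size_A": px,
        },
    )


def attenuation_pair(thickness_grid, model: MFPModel) -> dict[str, np.ndarray]:
    """EFTEM and tcBF retained fractions versus thickness (nm).

    EFTEM decays with the corrected inelastic MFP, unfiltered tcBF with the
    elastic MFP; their ratio is the dose advantage ``exp(t/lambda_eff)``.
    """
    if model.lambda_el is None:
        raise ValueError("model needs lambda_el for the tcBF curve")
    t = np.asarray(thickness_grid, dtype=float)
    return {
        "eftem_fraction": np.exp(-t / model.lambda_in_prime),
        "tcbf_fraction": np.exp(-t / model.lambda_el),
    }
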