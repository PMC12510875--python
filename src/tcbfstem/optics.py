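"""Electron-optical constants, the aberration surface and analytic transfer curves.

This module collects the linear imaging theory for phase contrast in the
bright-field (BF) disk of a pixelated STEM detector:

* each detector pixel at angle ``theta`` inside the probe-forming aperture of
  semi-angle ``alpha`` acts, by reciprocity, as a tilted-illumination BF
  detector with a phase-contrast transfer function (PCTF) built from the
  aperture indicator ``A`` and the lens aberration function ``chi``;
* summing the tilt-corrected per-pixel PCTFs over the disk gives the
  tilt-corrected BF (tcBF) CTF, whose closed form is the product of the
  classic two-disk overlap envelope ``L(omega/alpha)`` and the defocus
  oscillation ``sin(k0*defocus*omega**2/2)``;
* the in-focus differential phase contrast (DPC) signal and its integrated
  counterpart (iDPC) give the competing BF-disk phase-contrast modes, and the
  detective quantum efficiency (DQE) curves compare their dose efficiency
  under flat (Poisson) noise.

Scattering angles ``omega`` and detector angles ``theta`` are in radians;
lengths (wavelength, defocus) are in angstroms.  Spatial frequency is
``q = omega / wavelength`` and is only formed at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "OpticalConfig",
    "AberrationSurface",
    "TransferCurve",
    "electron_wavelength",
    "chi",
    "aperture",
    "pctf_tilted",
    "overlap_envelope",
    "ctf_axial_bf",
    "ctf_tcbf",
    "ctf_tcbf_numeric",
    "ctf_dpc",
    "pctf_idpc",
    "overlap_region",
    "dqe_curves",
    "ctf_thickness_averaged",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in angstroms for a voltage in kV.

    ``lambda = h c / sqrt(E^2 + 2 E m_e c^2)`` with ``E = e V``.
    """
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    energy_ev = voltage_kv * 1e3
    mec2_ev = _const.electron_mass * _const.c**2 / _const.elementary_charge
    hc_ev_angstrom = _const.h * _const.c / _const.elementary_charge * 1e10
    return hc_ev_angstrom / np.sqrt(energy_ev**2 + 2.0 * energy_ev * mec2_ev)


@dataclass(frozen=True)
class OpticalConfig:
    """Probe-forming optics: voltage, aperture and detector angular sampling.

    Parameters
    ----------
    voltage_kv : accelerating voltage in kV.
    alpha : probe-forming aperture semi-angle in rad.
    delta_alpha : detector angular pixel size in rad (must be < alpha).
    """

    voltage_kv: float
    alpha: float
    delta_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise ValueError("voltage_kv must be positive")
        if self.alpha <= 0 or self.delta_alpha <= 0:
            raise ValueError("alpha and delta_alpha must be positive")
        if self.delta_alpha >= self.alpha:
            raise ValueError("delta_alpha must be smaller than alpha")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in angstroms."""
        return electron_wavelength(self.voltage_kv)

    @property
    def k0(self) -> float:
        """Angular wavenumber 2*pi/lambda in rad/angstrom."""
        return 2.0 * np.pi / self.wavelength

    @property
    def omega0(self) -> float:
        """Solid angle pi*alpha**2 subtended by the aperture (sr)."""
        return np.pi * self.alpha**2


@dataclass(frozen=True)
class AberrationSurface:
    """Low-order aberration function chi(theta) of the probe-forming lens.

    With all optional terms zero,
    ``chi(theta) = -0.5 * k0 * defocus * |theta|**2``; astigmatism adds
    ``-0.5 * k0 * astig * |theta|**2 * cos(2*(phi - astig_angle))`` and
    third-order spherical aberration adds ``-0.25 * k0 * c3 * |theta|**4``.
    Positive defocus produces outward parallax shifts ``W = defocus * theta``.

    Lengths in angstroms, angles in radians.
    """

    defocus: float = 0.0
    astig: float = 0.0
    astig_angle: float = 0.0
    c3: float = 0.0


def chi(ab: AberrationSurface, cfg: OpticalConfig, theta_x, theta_y):
    """Aberration phase (rad) at detector angle(s) ``(theta_x, theta_y)``."""
    tx = np.asarray(theta_x, dtype=float)
    ty = np.asarray(theta_y, dtype=float)
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ValueError("theta must be finite")
    t2 = tx**2 + ty**2
    k0 = cfg.k0
    out = -0.5 * k0 * ab.defocus * t2
    if ab.astig != 0.0:
        phi = np.arctan2(ty, tx)
        out = out - 0.5 * k0 * ab.astig * t2 * np.cos(2.0 * (phi - ab.astig_angle))
    if ab.c3 != 0.0:
        out = out - 0.25 * k0 * ab.c3 * t2**2
    return out


def shift_field_model(ab: AberrationSurface, theta_x, theta_y):
    """Parallax image shift W(theta) = -(1/k0) grad chi, in angstroms.

    For pure defocus this is ``W = defocus * theta`` (outward for positive
    defocus); astigmatism adds the usual saddle term.
    """
    tx = np.asarray(theta_x, dtype=float)
    ty = np.asarray(theta_y, dtype=float)
    a = ab.astig * np.cos(2.0 * ab.astig_angle)
    b = ab.astig * np.sin(2.0 * ab.astig_angle)
    t2 = tx**2 + ty**2
    wx = ab.defocus * tx + a * tx + b * ty + ab.c3 * t2 * tx
    wy = ab.defocus * ty - a * ty + b * tx + ab.c3 * t2 * ty
    return wx, wy


def aperture(cfg: OpticalConfig, theta_x, theta_y, soft_edge: float = 0.0):
    """Top-hat aperture indicator A(theta): 1 inside |theta| <= alpha.

    ``soft_edge > 0`` replaces the hard edge with a linear ramp of that
    angular width (fractional-coverage antialiasing for quadrature use).
    """
    t = np.hypot(np.asarray(theta_x, dtype=float), np.asarray(theta_y, dtype=float))
    if soft_edge > 0.0:
        return np.clip((cfg.alpha - t) / soft_edge + 0.5, 0.0, 1.0)
    return (t <= cfg.alpha).astype(float)


@dataclass
class TransferCurve:
    """A radial transfer curve: angles ``omega`` (rad) and transfer values.

    ``label`` tags the mode (axial_bf | tilted | tcbf | dpc | idpc | dqe_*).
    ``q`` converts the angle axis to spatial frequency in 1/angstrom.
    """

    omega: np.ndarray
    values: np.ndarray
    label: str
    wavelength: float = field(default=np.nan)

    @property
    def q(self) -> np.ndarray:
        return self.omega / self.wavelength


def pctf_tilted(cfg: OpticalConfig, ab: AberrationSurface, omega_x, omega_y,
                theta: tuple[float, float], tilt_corrected: bool = False,
                soft_edge: float = 0.0):
    """Complex PCTF of the image formed at detector pixel ``theta``.

    ``(i/2) * A(theta) * {A(w-t) exp(-i[chi(w-t)-chi(t)])
                          - A(w+t) exp(+i[chi(w+t)-chi(t)])}``
    with the 1/2 normalization capping |PCTF| at 1.  With
    ``tilt_corrected=True`` the linear phase ramp from the parallax shift
    ``W(theta)`` is removed (the shift-theorem term), leaving the transfer of
    the shift-corrected image.
    """
    tx, ty = float(theta[0]), float(theta[1])
    if np.hypot(tx, ty) > cfg.alpha * (1 + 1e-12):
        raise ValueError(
            f"detector angle |theta|={np.hypot(tx, ty):.4g} rad exceeds alpha={cfg.alpha:.4g}"
        )
    wx = np.asarray(omega_x, dtype=float)
    wy = np.asarray(omega_y, dtype=float)
    chi_t = chi(ab, cfg, tx, ty)
    minus = aperture(cfg, wx - tx, wy - ty, soft_edge) * np.exp(
        -1j * (chi(ab, cfg, wx - tx, wy - ty) - chi_t))
    plus = aperture(cfg, wx + tx, wy + ty, soft_edge) * np.exp(
        +1j * (chi(ab, cfg, wx + tx, wy + ty) - chi_t))
    out = 0.5j * (minus - plus)
    if tilt_corrected:
        sx, sy = shift_field_model(ab, tx, ty)
        out = out * np.exp(1j * cfg.k0 * (sx * wx + sy * wy))
    return out


def overlap_envelope(u):
    """Normalized overlap area L(u) of two unit-diameter disks a distance u apart.

    ``L(u) = (2/pi) * [arccos(u/2) - (u/2) sqrt(1 - u^2/4)]`` on [0, 2], zero
    beyond; the classic self-luminous (ADF) envelope and the damping envelope
    of the tcBF CTF, with u = omega/alpha.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("overlap_envelope argument must be non-negative")
    uc = np.clip(u, 0.0, 2.0)
    out = (2.0 / np.pi) * (np.arccos(uc / 2.0) - (uc / 2.0) * np.sqrt(1.0 - uc**2 / 4.0))
    return np.where(u <= 2.0, out, 0.0)


def ctf_axial_bf(cfg: OpticalConfig, ab: AberrationSurface, omega) -> TransferCurve:
    """Axial bright-field CTF ``sin(chi(omega))``, cut off at omega = alpha.

    The axial limit of the tilted PCTF: for pure defocus this equals
    ``-sin(k0*defocus*omega^2/2)``, matching the tcBF closed form without
    its overlap envelope.
    """
    w = np.asarray(omega, dtype=float)
    vals = np.sin(chi(ab, cfg, w, 0.0)) * (w <= cfg.alpha)
    return TransferCurve(w, vals, "axial_bf", cfg.wavelength)


def ctf_tcbf(cfg: OpticalConfig, defocus: float, omega) -> TransferCurve:
    """Closed-form tcBF CTF ``-L(omega/alpha) * sin(k0*defocus*omega^2/2)``."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be non-negative")
    vals = -overlap_envelope(w / cfg.alpha) * np.sin(0.5 * cfg.k0 * defocus * w**2)
    return TransferCurve(w, vals, "tcbf", cfg.wavelength)


def _quad_grid(cfg: OpticalConfig, n_samples: int):
    """Quadrature samples covering the aperture disk plus one edge cell.

    Returns sample coordinates, the signed distance into the aperture and
    the cell size.  Fractional cell coverage of a region bounded by one or
    more disk edges is obtained from the minimum signed distance, which
    tracks the true region boundary even where two edges nearly coincide.
    """
    h = 2.0 * cfg.alpha / n_samples
    ax = (np.arange(n_samples + 2) - (n_samples + 1) / 2.0) * h
    tx, ty = np.meshgrid(ax, ax, indexing="ij")
    d0 = cfg.alpha - np.hypot(tx, ty)
    keep = d0 > -h
    return tx[keep], ty[keep], d0[keep], h


def _coverage(dist, h):
    """Fractional cell coverage from a signed boundary distance."""
    return np.clip(dist / h + 0.5, 0.0, 1.0)


def ctf_tcbf_numeric(cfg: OpticalConfig, ab: AberrationSurface, omega,
                     n_samples: int = 256) -> TransferCurve:
    """tcBF CTF by direct quadrature of the tilt-corrected PCTF over the disk.

    Pairs of detector angles ``(theta, -theta)`` are summed symmetrically
    (the half-disk sum), then the half-disk quadrature is completed; for
    defocus-only aberrations the real part converges to :func:`ctf_tcbf`.
    """
    if n_samples < 64:
        raise ValueError("need at least 64 quadrature samples across the disk")
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    tx, ty, d0, h = _quad_grid(cfg, n_samples)
    norm = _coverage(d0, h).sum()
    chi_t = chi(ab, cfg, tx, ty)
    sx, sy = shift_field_model(ab, tx, ty)
    vals = np.empty_like(w)
    # pairing (theta, -theta) is implicit: the grid is symmetric under
    # theta -> -theta and both members are summed with equal weight
    for i, om in enumerate(w):
        d_m = cfg.alpha - np.hypot(om - tx, ty)
        d_p = cfg.alpha - np.hypot(om + tx, ty)
        cov_m = _coverage(np.minimum(d0, d_m), h)
        cov_p = _coverage(np.minimum(d0, d_p), h)
        minus = cov_m * np.exp(-1j * (chi(ab, cfg, om - tx, -ty) - chi_t))
        plus = cov_p * np.exp(+1j * (chi(ab, cfg, om + tx, ty) - chi_t))
        ramp = np.exp(1j * cfg.k0 * sx * om)  # undo the parallax shift
        vals[i] = np.real(np.sum(0.5j * (minus - plus) * ramp)) / norm
    vals = vals.reshape(np.shape(omega))
    return TransferCurve(w, vals, "tcbf", cfg.wavelength)


def ctf_dpc(cfg: OpticalConfig, omega, n_samples: int = 512,
            weighting: str = "halfplane") -> TransferCurve:
    """In-focus DPC CTF along the x direction.

    The DPC_x signal subtracts left-tilted (theta_x < 0) from right-tilted
    (theta_x > 0) detector signals; with ``weighting='com'`` pixels are
    weighted by theta_x/alpha (detector first moment) instead of its sign.
    The in-focus per-pixel PCTF is purely antisymmetric (imaginary); the
    returned curve is its imaginary part averaged over the disk.
    """
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    tx, ty, d0, h = _quad_grid(cfg, n_samples)
    if weighting == "halfplane":
        gain = np.sign(tx)
    elif weighting == "com":
        gain = tx / cfg.alpha
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    norm = _coverage(d0, h).sum()
    vals = np.empty_like(w)
    for i, om in enumerate(w):
        # in focus the per-pixel PCTF is (i/2)[A(w-t) - A(w+t)]; inside the
        # aperture this reduces to the overlap-region indicators
        d_m = cfg.alpha - np.hypot(om - tx, ty)
        d_p = cfg.alpha - np.hypot(om + tx, ty)
        diff = (_coverage(np.minimum(d0, d_m), h)
                - _coverage(np.minimum(d0, d_p), h))
        vals[i] = 0.5 * np.sum(gain * diff) / norm
    vals = vals.reshape(np.shape(omega))
    return TransferCurve(w, vals, "dpc", cfg.wavelength)


def pctf_idpc(cfg: OpticalConfig, omega, n_samples: int = 512) -> TransferCurve:
    """Integrated-DPC CTF: first-moment DPC components divided by frequency.

    ``PCTF_iDPC = (DPC_x + i DPC_y) / (i (k_x + i k_y))``.  With the detector
    first moment as the DPC weighting this radial curve equals the two-disk
    overlap envelope L(omega/alpha); the division is regularized by taking
    the omega -> 0 limit at the DC sample.
    """
    w = np.asarray(omega, dtype=float)
    dpc = ctf_dpc(cfg, w, n_samples=n_samples, weighting="com")
    vals = np.empty_like(w)
    nz = w > 0
    # for omega along x the y component vanishes; division by i*kx maps the
    # antisymmetric (imaginary) DPC curve to a real, symmetric one
    vals[nz] = dpc.values[nz] / (w[nz] / cfg.alpha)
    # omega -> 0 limit of the divided first-moment curve: the disk-averaged
    # DPC_com tends to (omega/alpha) * L(0)/2, so the limit is 1/2
    vals[~nz] = 0.5
    # normalize the ideal-pixel curve to 1 at omega -> 0 so that it can be
    # compared directly with the overlap envelope
    vals = vals / 0.5
    return TransferCurve(w, vals, "idpc", cfg.wavelength)


def overlap_region(cfg: OpticalConfig, omega: tuple[float, float],
                   theta: tuple[float, float]) -> str:
    """Classify (omega, theta) into 'none', 'double' or 'triple' overlap.

    Triple overlap (both diffracted beams inside the aperture) carries the
    defocus-activated tcBF phase contrast at double the amplitude of the
    double-overlap region used by DPC/SSB.
    """
    wx, wy = float(omega[0]), float(omega[1])
    tx, ty = float(theta[0]), float(theta[1])
    if np.hypot(tx, ty) > cfg.alpha * (1 + 1e-12):
        raise ValueError("detector angle outside the aperture")
    a = cfg.alpha
    in_minus = np.hypot(wx - tx, wy - ty) < a
    in_plus = np.hypot(wx + tx, wy + ty) < a
    if np.hypot(wx, wy) < a and in_minus and in_plus:
        return "triple"
    if np.hypot(wx, wy) < a and (in_minus != in_plus):
        return "double"
    return "none"


def dqe_curves(cfg: OpticalConfig, defocus: float, omega,
               n_samples: int = 512) -> dict[str, TransferCurve]:
    """DQE curves for tcBF, DPC and iDPC under flat unit Poisson noise.

    With the noise power spectrum normalized to 1 and DQE(0)=1 for an ideal
    pixel, each DQE is the squared magnitude of the corresponding
    disk-averaged CTF; the iDPC DQE averages the two DPC components (for the
    azimuthally symmetric curve the two are equal, so it matches the DPC
    DQE -- the frequency division amplifies noise and signal alike).
    """
    w = np.asarray(omega, dtype=float)
    lam = cfg.wavelength
    tc = ctf_tcbf(cfg, defocus, w).values
    dp = ctf_dpc(cfg, w, n_samples=n_samples).values
    return {
        "dqe_tcbf": TransferCurve(w, np.abs(tc) ** 2, "dqe_tcbf", lam),
        "dqe_dpc": TransferCurve(w, np.abs(dp) ** 2, "dqe_dpc", lam),
        "dqe_idpc": TransferCurve(w, (np.abs(dp) ** 2 + np.abs(dp) ** 2) / 2.0,
                                  "dqe_idpc", lam),
    }


def ctf_thickness_averaged(cfg: OpticalConfig, defocus_center: float,
                           thickness: float, omega,
                           n_points: int = 65) -> TransferCurve:
    """tcBF CTF averaged over a uniform defocus ramp spanning the thickness.

    Models a specimen uniform through thickness ``t`` (angstroms): the CTF is
    the mean of :func:`ctf_tcbf` for defocus in
    ``[defocus_center - t/2, defocus_center + t/2]``, which damps high
    frequencies on the scale of the per-frequency depth of field
    ``lambda/omega**2`` (the depth-of-field relation evaluated at the spatial
    frequency of interest).
    """
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    w = np.asarray(omega, dtype=float)
    if thickness == 0:
        tc = ctf_tcbf(cfg, defocus_center, w)
        return TransferCurve(w, tc.values, "tcbf_thickness_avg", cfg.wavelength)
    dfs = defocus_center + np.linspace(-0.5, 0.5, n_points) * thickness
    vals = np.mean([ctf_tcbf(cfg, df, w).values for df in dfs], axis=0)
    return TransferCurve(w, vals, "tcbf_thickness_avg", cfg.wavelength)
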