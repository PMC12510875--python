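"""Acquisition-design calculator: sampling rules and derived optical lengths.

For a probe-forming semi-angle ``alpha``, defocus ``defocus`` and detector
angular pixel ``delta_alpha``, the defocused probe paints a shadow disk of
diameter ``2*alpha*defocus`` on the specimen, each detector pixel blurs over
``delta_alpha*defocus``, and the scan step must stay below
``sqrt(2)*alpha*defocus`` to leave no sampling gaps (below ``alpha*defocus``
for uniform dose).  The largest useful upsampling ratio is the ratio of the
two blurs, ``alpha/delta_alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .optics import electron_wavelength

__all__ = ["DesignReport", "design_report", "speedup_factor"]


@dataclass(frozen=True)
class DesignReport:
    """Derived acquisition quantities; lengths in angstroms, ratios unitless."""

    probe_blur_diameter: float      # geometric shadow disk 2*alpha*defocus
    single_pixel_blur: float        # delta_alpha * defocus
    max_step_gap_free: float        # sqrt(2) * alpha * defocus
    recommended_step: float         # alpha * defocus (uniform dose bound)
    max_upsampling: float           # alpha / delta_alpha
    depth_of_field: float           # 2 * lambda / alpha**2
    probe_size_diffraction: float   # 0.61 * lambda / alpha
    info_limit_1a: float            # lambda / alpha  (period at 1-alpha cutoff)
    info_limit_2a: float            # lambda / (2 alpha)
    scan_nyquist_period: float      # 2 * scan_step
    scan_step: float
    gap_risk: bool                  # scan_step > sqrt(2) alpha defocus
    nonuniform_dose: bool           # scan_step > alpha defocus

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def design_report(voltage_kv: float, alpha: float, delta_alpha: float,
                  defocus: float, scan_step: float) -> DesignReport:
    """Fill a :class:`DesignReport` from the acquisition parameters.

    ``alpha`` and ``delta_alpha`` in rad, ``defocus`` and ``scan_step`` in
    angstroms, voltage in kV.
    """
    if min(voltage_kv, alpha, delta_alpha, defocus, scan_step) <= 0:
        raise ValueError("all design inputs must be positive")
    lam = electron_wavelength(voltage_kv)
    max_gap_free = 2.0**0.5 * alpha * defocus
    recommended = alpha * defocus
    return DesignReport(
        probe_blur_diameter=2.0 * alpha * defocus,
        single_pixel_blur=delta_alpha * defocus,
        max_step_gap_free=max_gap_free,
        recommended_step=recommended,
        max_upsampling=alpha / delta_alpha,
        depth_of_field=2.0 * lam / alpha**2,
        probe_size_diffraction=0.61 * lam / alpha,
        info_limit_1a=lam / alpha,
        info_limit_2a=lam / (2.0 * alpha),
        scan_nyquist_period=2.0 * scan_step,
        scan_step=scan_step,
        gap_risk=scan_step > max_gap_free,
        nonuniform_dose=scan_step > recommended,
    )


def speedup_factor(scan_step: float, achieved_resolution: float) -> tuple[int, int]:
    """Acquisition speed-up from imaging beyond the scan Nyquist period.

    The linear gain is the scan Nyquist period ``2*scan_step`` over the
    achieved resolution, rounded to the nearest integer; the areal
    acquisition speed-up is its square.  Returns ``(linear, areal)``.
    """
    if scan_step <= 0 or achieved_resolution <= 0:
        raise ValueError("inputs must be positive")
    linear = round(2.0 * scan_step / achieved_resolution)
    return linear, linear**2
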