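"""Free-field acoustics of a tubular rewarming transducer.

A cylindrical (tube) transducer driven in a resonant mode radiates inward
and produces, in the long-tube approximation, a radial pressure profile

    p(r) = p0 / J0(k a) * J0(k r)

where ``J0`` is the zero-order Bessel function of the first kind, ``k`` the
wavenumber in the coupling water, ``a`` the tube radius and ``p0`` the
pressure at the tube wall.  This module evaluates that profile, summarises
measured axial (vertical) hydrophone scans, relates drive voltage to mean
and peak axial pressure with a through-origin linear fit, and converts
pressure amplitudes to plane-wave acoustic intensity.

Pressure values are signed (the Bessel profile has phase-reversed lobes);
all scan statistics operate on amplitude magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import j0

__all__ = [
    "TubeFieldModel",
    "AxialScan",
    "AxialStats",
    "DriveResponse",
    "IntensityResult",
    "tube_pressure_profile",
    "axial_stats",
    "fit_drive_response",
    "plane_wave_intensity",
]

#: |J0(k a)| below this is treated as a singular model configuration.
J0_SINGULAR_TOL = 1e-6


@dataclass(frozen=True)
class TubeFieldModel:
    """Parameters of the cylindrical free-field pressure model.

    Parameters
    ----------
    frequency : float
        Drive frequency in Hz (the device resonance, e.g. ``474e3``).
    tube_radius : float
        Inner radius ``a`` of the tube in metres.
    wall_pressure : float
        Pressure amplitude ``p0`` at the tube wall in Pa.
    sound_speed : float, optional
        Sound speed of the coupling water in m/s.  Default 1520.1 m/s,
        pure water at the 33 °C bath temperature (standard sound-speed
        correlation).
    """

    frequency: float
    tube_radius: float
    wall_pressure: float
    sound_speed: float = 1520.1

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if not self.sound_speed > 0:
            raise ValueError("sound_speed must be positive")
        if not self.tube_radius > 0:
            raise ValueError("tube_radius must be positive")
        if abs(j0(self.wavenumber * self.tube_radius)) < J0_SINGULAR_TOL:
            raise ValueError(
                "singular model: k*a lies at a zero of J0; the wall "
                "pressure does not determine the interior field"
            )

    @property
    def wavenumber(self) -> float:
        """Wavenumber ``k = 2 pi f / c`` in rad/m."""
        return 2.0 * math.pi * self.frequency / self.sound_speed


def tube_pressure_profile(
    model: TubeFieldModel, radii: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Evaluate the signed Bessel pressure profile at radial positions.

    Parameters
    ----------
    model : TubeFieldModel
    radii : array-like of float
        Radial positions in metres; each must satisfy ``|r| <= tube_radius``.

    Returns
    -------
    numpy.ndarray
        Signed pressure ``p0 / J0(k a) * J0(k r)`` in Pa.  Take ``abs`` for
        amplitude magnitudes.
    """
    r = np.asarray(radii, dtype=float)
    if np.any(np.abs(r) > model.tube_radius):
        raise ValueError("radial position outside the tube (|r| > a)")
    k = model.wavenumber
    return model.wall_pressure / j0(k * model.tube_radius) * j0(k * r)


@dataclass(frozen=True)
class AxialScan:
    """A hydrophone line scan along the vertical (cryovial) axis.

    ``positions_mm`` must be strictly monotone and amplitudes non-negative.
    """

    positions_mm: np.ndarray
    amplitudes_pa: np.ndarray
    drive_voltage: float
    electrical_power: float | None = None
    pulse_descriptor: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.positions_mm, dtype=float)
        p = np.asarray(self.amplitudes_pa, dtype=float)
        object.__setattr__(self, "positions_mm", z)
        object.__setattr__(self, "amplitudes_pa", p)
        if z.size < 2:
            raise ValueError("a scan needs at least 2 points")
        if z.shape != p.shape:
            raise ValueError("positions and amplitudes must have equal length")
        dz = np.diff(z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("scan positions must be strictly monotone")
        if np.any(p < 0):
            raise ValueError("amplitudes must be non-negative")

    def windowed(self, z_min: float | None = None, z_max: float | None = None) -> "AxialScan":
        """Restrict the scan to a z window (used to exclude aberrated regions)."""
        z = self.positions_mm
        mask = np.ones_like(z, dtype=bool)
        if z_min is not None:
            mask &= z >= z_min
        if z_max is not None:
            mask &= z <= z_max
        if mask.sum() < 2:
            raise ValueError("z window leaves fewer than 2 scan points")
        return AxialScan(
            z[mask], self.amplitudes_pa[mask], self.drive_voltage,
            self.electrical_power, self.pulse_descriptor, dict(self.meta),
        )


@dataclass(frozen=True)
class AxialStats:
    mean_pa: float
    peak_pa: float
    sd_percent: float


def axial_stats(scan: AxialScan) -> AxialStats:
    """Mean, peak and relative spread of axial pressure amplitudes.

    Returns the arithmetic mean, the maximum sample (no interpolation) and
    the population standard deviation as a percentage of the mean over the
    scanned z-range.
    """
    amp = scan.amplitudes_pa
    mean = float(np.mean(amp))
    peak = float(np.max(amp))
    if mean == 0.0:
        sd_pct = 0.0 if np.all(amp == 0) else float("inf")
    else:
        sd_pct = float(np.std(amp) / mean * 100.0)
    return AxialStats(mean_pa=mean, peak_pa=peak, sd_percent=sd_pct)


@dataclass(frozen=True)
class DriveResponse:
    """Through-origin linear relation between drive voltage and mean axial pressure."""

    voltages: np.ndarray
    mean_pressures_pa: np.ndarray
    peak_pressures_pa: np.ndarray
    slope_pa_per_v: float
    residuals_percent: np.ndarray
    flagged: np.ndarray  # points deviating more than the flag threshold
    flag_threshold_percent: float


def fit_drive_response(
    scans: Sequence[AxialScan], flag_threshold_percent: float = 3.0
) -> DriveResponse:
    """Fit mean axial pressure vs drive voltage with a line through the origin.

    Zero drive produces zero pressure physically, so the fit has no
    intercept: ``slope = sum(V p) / sum(V^2)``.  Per-point residuals are
    reported as a percentage of the fitted value.  Flagging of deviating
    points (compression at high drive, say) uses leave-one-out residuals —
    each point judged against the trend fitted to the others — because a
    deviating high-voltage point carries enough leverage to pull the full
    fit toward itself and mask its own residual.
    """
    if len(scans) < 3:
        raise ValueError("need scans at at least 3 distinct voltages")
    volts = np.array([s.drive_voltage for s in scans], dtype=float)
    if np.any(volts <= 0):
        raise ValueError("drive voltages must be positive")
    if np.unique(volts).size < 3:
        raise ValueError("need at least 3 distinct voltages")
    stats = [axial_stats(s) for s in scans]
    means = np.array([s.mean_pa for s in stats])
    peaks = np.array([s.peak_pa for s in stats])
    slope = float(np.sum(volts * means) / np.sum(volts**2))
    fitted = slope * volts
    resid_pct = (means - fitted) / fitted * 100.0
    sum_vp, sum_v2 = np.sum(volts * means), np.sum(volts**2)
    loo_slopes = (sum_vp - volts * means) / (sum_v2 - volts**2)
    loo_resid_pct = (means - loo_slopes * volts) / (loo_slopes * volts) * 100.0
    flagged = np.abs(loo_resid_pct) > flag_threshold_percent
    return DriveResponse(
        voltages=volts,
        mean_pressures_pa=means,
        peak_pressures_pa=peaks,
        slope_pa_per_v=slope,
        residuals_percent=resid_pct,
        flagged=flagged,
        flag_threshold_percent=flag_threshold_percent,
    )


def plane_wave_intensity(
    pressure_pa: float, impedance_rayl: float = 1.5e6, duty_cycle: float = 1.0
) -> float:
    """Plane-wave acoustic intensity in W/cm² for a pressure amplitude.

    ``I = duty_cycle * p^2 / (2 Z)`` in W/m², divided by 1e4 for W/cm².
    The default impedance is 1.5 MRayl (water / soft tissue).
    """
    if pressure_pa < 0:
        raise ValueError("pressure amplitude must be non-negative")
    if impedance_rayl <= 0:
        raise ValueError("impedance must be positive")
    if not 0 < duty_cycle <= 1:
        raise ValueError("duty cycle must be in (0, 1]")
    return duty_cycle * pressure_pa**2 / (2.0 * impedance_rayl) / 1e4


@dataclass(frozen=True)
class IntensityResult:
    pressure_amplitude_pa: float
    impedance_rayl: float
    duty_cycle: float
    intensity_w_cm2: float

    @classmethod
    def compute(
        cls,
        pressure_pa: float,
        impedance_rayl: float = 1.5e6,
        duty_cycle: float = 1.0,
    ) -> "IntensityResult":
        return cls(
            pressure_amplitude_pa=pressure_pa,
            impedance_rayl=impedance_rayl,
            duty_cycle=duty_cycle,
            intensity_w_cm2=plane_wave_intensity(pressure_pa, impedance_rayl, duty_cycle),
        )
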