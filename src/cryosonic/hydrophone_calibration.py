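"""Hydrophone amplitude extraction, sensitivity transfer and uncertainty.

A fibre-optic hydrophone (FOH) is calibrated by cross-comparison against a
reference capsule hydrophone in a shared tone-burst field: both record the
same pressure, the reference sensitivity converts its voltage amplitude to
pressure, and the FOH sensitivity follows as voltage over pressure.  The
reference sensitivity is first corrected from its calibration temperature
to the working temperature with a linear coefficient (0.64 %/°C by
default).  Amplitudes are extracted from the steady-state portion of the
burst by single-frequency discrete Fourier projection over an exact
integer number of cycles, which rejects DC and all harmonics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ToneBurstRecord",
    "SensitivityRecord",
    "UncertaintyBudget",
    "extract_steady_state_amplitude",
    "correct_sensitivity",
    "cross_calibrate",
    "combine_uncertainty",
]


@dataclass(frozen=True)
class ToneBurstRecord:
    """A sampled tone-burst voltage waveform.

    ``samples`` are in volts; time zero is the first sample.  For records
    digitised with a delay between trigger and burst arrival, pass the
    arrival time as ``delay_s`` to the extraction routine.
    """

    samples: np.ndarray
    sample_rate: float
    drive_frequency: float
    n_cycles: int | None = None
    averaging_count: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if self.sample_rate <= 2.0 * self.drive_frequency:
            raise ValueError("sample rate must exceed twice the drive frequency")
        if x.ndim != 1 or x.size < 2:
            raise ValueError("samples must be a 1-D array with at least 2 points")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def extract_steady_state_amplitude(
    record: ToneBurstRecord,
    window: tuple[int, int] = (90, 100),
    delay_s: float = 0.0,
) -> tuple[float, float]:
    """Amplitude and phase of the drive-frequency component over a cycle window.

    Parameters
    ----------
    record : ToneBurstRecord
    window : (int, int)
        Start and end cycle indices of the analysis window, counted from
        ``delay_s``.  The span must be a whole number of cycles — the
        projection is only orthogonal to DC and harmonics on integer-cycle
        spans — so non-integer windows are rejected rather than truncated.
    delay_s : float
        Time of burst arrival relative to the first sample (0 if the record
        starts with the burst).

    Returns
    -------
    (amplitude, phase)
        Amplitude in the units of ``samples`` and phase in radians
        referenced to a cosine at the window start.
    """
    start_c, end_c = window
    for c in (start_c, end_c):
        if abs(c - round(c)) > 1e-9:
            raise ValueError("window bounds must be integer cycle counts")
    start_c, end_c = int(round(start_c)), int(round(end_c))
    if end_c <= start_c:
        raise ValueError("window must span at least one cycle")
    f0 = record.drive_frequency
    t0 = delay_s + start_c / f0
    t1 = delay_s + end_c / f0
    if t0 < 0 or t1 > record.duration + 0.5 / record.sample_rate:
        raise ValueError("analysis window lies outside the record")
    n = record.samples.size
    t = np.arange(n) / record.sample_rate
    mask = (t >= t0) & (t < t1)
    if mask.sum() < 4:
        raise ValueError("analysis window contains too few samples")
    x = record.samples[mask]
    # single-bin projection; reference phase to the window start
    phase_ref = np.exp(-2j * math.pi * f0 * (t[mask] - t0))
    c = 2.0 * np.sum(x * phase_ref) / x.size
    return float(np.abs(c)), float(np.angle(c))


@dataclass(frozen=True)
class SensitivityRecord:
    """Hydrophone sensitivity with its calibration temperature.

    ``temperature_coefficient`` is the fractional sensitivity change per
    °C (default 0.0064, i.e. 0.64 %/°C).  Its sign is configurable: a
    negative coefficient models sensitivity decreasing with temperature.
    """

    sensitivity_v_per_pa: float
    calibration_temperature_c: float
    temperature_coefficient: float = 0.0064

    def __post_init__(self) -> None:
        if not self.sensitivity_v_per_pa > 0:
            raise ValueError("sensitivity must be positive")
        if not (
            math.isfinite(self.temperature_coefficient)
            and math.isfinite(self.calibration_temperature_c)
        ):
            raise ValueError("coefficient and temperature must be finite")


def correct_sensitivity(ref: SensitivityRecord, target_temperature_c: float) -> float:
    """Linearly correct a sensitivity to a target temperature.

    ``s' = s * (1 + coeff * (T_target - T_cal))``.
    """
    if not math.isfinite(target_temperature_c):
        raise ValueError("target temperature must be finite")
    dt = target_temperature_c - ref.calibration_temperature_c
    return ref.sensitivity_v_per_pa * (1.0 + ref.temperature_coefficient * dt)


def cross_calibrate(
    foh_amplitude_v: float, ref_amplitude_v: float, ref_sensitivity_v_per_pa: float
) -> float:
    """Transfer sensitivity from a reference hydrophone to the FOH.

    The reference amplitude and sensitivity give the common field pressure;
    the FOH sensitivity is its own amplitude divided by that pressure.
    """
    for name, v in (
        ("foh_amplitude_v", foh_amplitude_v),
        ("ref_amplitude_v", ref_amplitude_v),
        ("ref_sensitivity_v_per_pa", ref_sensitivity_v_per_pa),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    pressure = ref_amplitude_v / ref_sensitivity_v_per_pa
    return foh_amplitude_v / pressure


def combine_uncertainty(components_percent: Sequence[float]) -> float:
    """Combine independent relative uncertainty components in quadrature."""
    comps = np.asarray(list(components_percent), dtype=float)
    if comps.size == 0:
        raise ValueError("need at least one component")
    if np.any(comps < 0):
        raise ValueError("uncertainty components must be non-negative")
    return float(np.sqrt(np.sum(comps**2)))


@dataclass(frozen=True)
class UncertaintyBudget:
    """Labelled uncertainty components combined in quadrature."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if any(pct < 0 for _, pct in self.components):
            raise ValueError("uncertainty components must be non-negative")

    @property
    def combined_percent(self) -> float:
        return combine_uncertainty([pct for _, pct in self.components])
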