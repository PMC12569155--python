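"""Synthetic raw-data generators with known ground truth.

Every raw input the analysis chain consumes can be generated here with
seeded randomness and the generating parameters attached as ground truth:

* ``simulate_rewarming`` — cryovial thermocouple traces from a lumped
  (zero-dimensional) phase-change model,
* ``generate_burst`` — ring-up tone-burst hydrophone waveforms,
* ``generate_axial_scan`` — axial pressure scans with the empirical
  vertical amplitude modulation of the tube field,
* ``generate_bead_images`` — paired FDA/PI bead images with a known dead
  fraction,
* ``generate_viability_timecourse`` — recovery time-courses with known
  condition offsets, for statistical power and calibration checks.

The rewarming model integrates

    dT/dt = [k_c (T_bath - T) + eta(T) P + q_art(T, P)] / C_app(T)

with an apparent heat capacity ``C_app`` equal to the frozen capacity
below the melt window, the thawed capacity above it, and the mean capacity
plus ``latent_heat / (T_liquidus - T_solidus)`` inside it.  The coupling
``eta`` (absorbed electrical power converted to heat in the vial) is
piecewise constant — the frozen value below the solidus, the thawed value
at and above it — and ``q_art`` is an additive thermocouple
viscous-heating term, active only above the solidus and only under
drive, emulating the artifact that inflates apparent rates once the
medium is fluid enough for the probe to oscillate.

The default constants are effective lumped values calibrated once
(closed-form piecewise-exponential solution) to the study conditions: a
33 °C bath warming a ~1.8 ml vial at ≈100 °C/min below the transition and
traversing −65 → 5 °C in ≈189 s at 0 W and ≈33 s at 100 W, with the
phase-transition rate dip ≈1/20 of the low-temperature rate at 0 W and
≈1/3 at 100 W.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from skimage.draw import disk

from .acoustic_field import AxialScan, TubeFieldModel, tube_pressure_profile
from .hydrophone_calibration import ToneBurstRecord
from .rewarming_kinetics import TemperatureTrace
from .viability_analysis import FluorescencePair, TimecourseDataset

__all__ = [
    "RewarmSimConfig",
    "BurstConfig",
    "ScanConfig",
    "BeadImageConfig",
    "simulate_rewarming",
    "simulate_rewarming_ensemble",
    "generate_burst",
    "generate_axial_scan",
    "generate_bead_images",
    "generate_viability_timecourse",
]


@dataclass(frozen=True)
class RewarmSimConfig:
    """Lumped phase-change rewarming model parameters.

    Units: temperatures °C, power W, conduction W/°C, capacities J/°C,
    latent heat J, sample rate Hz.  ``eta_frozen``/``eta_thawed`` are the
    dimensionless fractions of electrical drive power deposited as heat in
    the vial below/above the solidus; ``artifact_gain`` is the additional
    apparent (thermocouple viscous-heating) power fraction above the
    solidus when driven.
    """

    power_w: float = 0.0
    bath_temperature_c: float = 33.0
    initial_temperature_c: float = -65.0
    conduction_w_per_c: float = 0.1
    frozen_heat_capacity_j_per_c: float = 4.98
    thawed_heat_capacity_j_per_c: float = 9.96
    latent_heat_j: float = 436.8
    melt_window_c: tuple[float, float] = (-15.0, 0.0)
    eta_frozen: float = 0.075
    eta_thawed: float = 0.05
    artifact_gain: float = 0.29
    noise_sd_c: float = 0.2
    sample_rate_hz: float = 2.0
    stop_temperature_c: float = 8.0
    max_duration_s: float = 900.0
    seed: int | None = None

    def __post_init__(self) -> None:
        t_s, t_l = self.melt_window_c
        if not t_s < t_l < self.bath_temperature_c:
            raise ValueError("need solidus < liquidus < bath temperature")
        if self.frozen_heat_capacity_j_per_c <= 0 or self.thawed_heat_capacity_j_per_c <= 0:
            raise ValueError("heat capacities must be positive")
        if self.latent_heat_j < 0:
            raise ValueError("latent heat must be non-negative")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def apparent_heat_capacity(self, temperature_c: float) -> float:
        t_s, t_l = self.melt_window_c
        if temperature_c < t_s:
            return self.frozen_heat_capacity_j_per_c
        if temperature_c > t_l:
            return self.thawed_heat_capacity_j_per_c
        mid = 0.5 * (
            self.frozen_heat_capacity_j_per_c + self.thawed_heat_capacity_j_per_c
        )
        return mid + self.latent_heat_j / (t_l - t_s)

    def heat_input_w(self, temperature_c: float) -> float:
        t_s, _ = self.melt_window_c
        q = self.conduction_w_per_c * (self.bath_temperature_c - temperature_c)
        eta = self.eta_frozen if temperature_c < t_s else self.eta_thawed
        q += eta * self.power_w
        if self.power_w > 0 and temperature_c >= t_s:
            q += self.artifact_gain * self.power_w
        return q


def simulate_rewarming(config: RewarmSimConfig) -> TemperatureTrace:
    """Integrate the lumped model and sample it like a thermocouple logger.

    Explicit adaptive integration (RK45, relative tolerance 1e-8, step
    capped at half the sample interval so regime boundaries are resolved)
    on a fixed output grid at ``sample_rate_hz``; Gaussian measurement
    noise of ``noise_sd_c`` is added per sample.  Integration stops once
    the temperature exceeds ``stop_temperature_c`` (comfortably above the
    5 °C analysis endpoint).  Deterministic per seed.
    """

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        T = float(y[0])
        return [config.heat_input_w(T) / config.apparent_heat_capacity(T)]

    def reached_stop(_t: float, y: np.ndarray) -> float:
        return float(y[0]) - config.stop_temperature_c

    reached_stop.terminal = True
    reached_stop.direction = 1.0

    dt = 1.0 / config.sample_rate_hz
    t_eval = np.arange(0.0, config.max_duration_s + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs,
        (0.0, config.max_duration_s),
        [config.initial_temperature_c],
        t_eval=t_eval,
        events=reached_stop,
        method="RK45",
        rtol=1e-8,
        atol=1e-8,
        max_step=0.5 * dt,
    )
    times = sol.t
    temps = sol.y[0]
    if sol.t_events[0].size == 0 and temps.max() < config.stop_temperature_c:
        warnings.warn(
            "trace did not reach stop_temperature_c within max_duration_s"
        )
    if config.noise_sd_c > 0:
        rng = np.random.default_rng(config.seed)
        temps = temps + rng.normal(0.0, config.noise_sd_c, size=temps.size)
    return TemperatureTrace(
        times_s=times,
        temperatures_c=temps,
        power_w=config.power_w,
        labels={"source": "simulate_rewarming", "seed": config.seed},
    )


def simulate_rewarming_ensemble(
    config: RewarmSimConfig, n_traces: int = 3, seed: int | None = None
) -> list[TemperatureTrace]:
    """Replicate traces of one condition with independent noise streams."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_traces)
    return [
        simulate_rewarming(
            replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
        )
        for child in children
    ]


@dataclass(frozen=True)
class BurstConfig:
    """Tone-burst waveform parameters.

    ``ring_up_cycles`` is the exponential ring-up time constant in cycles
    (0 for an instant-on burst), emulating the resonant cavity's approach
    to steady state.  Default sampling is 100 samples per cycle, so the
    sample rate is commensurate with the drive frequency and integer-cycle
    analysis windows align exactly with sample boundaries.
    """

    frequency_hz: float = 474e3
    n_cycles: int = 100
    plateau_amplitude: float = 1.0
    ring_up_cycles: float = 20.0
    samples_per_cycle: int = 100
    noise_sd: float = 0.0
    phase_rad: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.samples_per_cycle <= 2:
            raise ValueError("undersampled: need > 2 samples per cycle")
        if self.ring_up_cycles < 0 or self.noise_sd < 0:
            raise ValueError("ring_up_cycles and noise_sd must be non-negative")

    @property
    def sample_rate_hz(self) -> float:
        return self.samples_per_cycle * self.frequency_hz


def generate_burst(config: BurstConfig) -> ToneBurstRecord:
    """Sinusoid with exponential ring-up to a plateau, plus optional noise.

    The ground-truth plateau amplitude and ring-up constant are stored in
    the record's ``meta``.
    """
    fs = config.sample_rate_hz
    n = config.n_cycles * config.samples_per_cycle
    t = np.arange(n) / fs
    cycles = t * config.frequency_hz
    if config.ring_up_cycles > 0:
        envelope = 1.0 - np.exp(-cycles / config.ring_up_cycles)
    else:
        envelope = np.ones_like(t)
    x = (
        config.plateau_amplitude
        * envelope
        * np.cos(2.0 * math.pi * config.frequency_hz * t + config.phase_rad)
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        x = x + rng.normal(0.0, config.noise_sd, size=n)
    return ToneBurstRecord(
        samples=x,
        sample_rate=fs,
        drive_frequency=config.frequency_hz,
        n_cycles=config.n_cycles,
        meta={
            "plateau_amplitude": config.plateau_amplitude,
            "ring_up_cycles": config.ring_up_cycles,
            "phase_rad": config.phase_rad,
            "seed": config.seed,
        },
    )


@dataclass(frozen=True)
class ScanConfig:
    """Axial-scan generator parameters.

    The vertical standing-wave structure of the real cavity is emulated
    empirically as a sinusoidal amplitude modulation whose depth is set by
    the target relative spread: for a sinusoid the population SD is
    depth/sqrt(2), so ``depth = sqrt(2) * target_sd_percent / 100``.  The
    measured device shows an 11–12 % spread at all drive voltages.
    """

    drive_voltage_v: float = 61.0
    pressure_per_volt_pa: float = 38400.0
    electrical_power_w: float | None = None
    z_start_mm: float = 10.0
    z_stop_mm: float = 35.0
    dz_mm: float = 0.5
    target_sd_percent: float = 11.5
    modulation_wavelength_mm: float = 6.3
    modulation_phase_rad: float = 0.0
    noise_sd_pa: float = 0.0
    field_model: TubeFieldModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target_sd_percent < 0 or self.noise_sd_pa < 0:
            raise ValueError("modulation depth and noise must be non-negative")
        if self.dz_mm <= 0 or self.z_stop_mm <= self.z_start_mm:
            raise ValueError("invalid z range")


def generate_axial_scan(config: ScanConfig) -> AxialScan:
    """Axial amplitudes: base pressure x (1 + vertical modulation) + noise.

    The base on-axis pressure is linear in drive voltage (or, when a
    ``field_model`` is given, its on-axis value scaled to the drive).
    Ground truth (base pressure, modulation depth) is stored in ``meta``.
    """
    n = int(round((config.z_stop_mm - config.z_start_mm) / config.dz_mm)) + 1
    z = config.z_start_mm + config.dz_mm * np.arange(n)
    if config.field_model is not None:
        # the model's wall pressure encodes the drive level
        base = float(abs(tube_pressure_profile(config.field_model, [0.0])[0]))
    else:
        base = config.drive_voltage_v * config.pressure_per_volt_pa
    depth = math.sqrt(2.0) * config.target_sd_percent / 100.0
    modulation = depth * np.sin(
        2.0 * math.pi * z / config.modulation_wavelength_mm
        + config.modulation_phase_rad
    )
    amp = base * (1.0 + modulation)
    if config.noise_sd_pa > 0:
        rng = np.random.default_rng(config.seed)
        amp = amp + rng.normal(0.0, config.noise_sd_pa, size=n)
    amp = np.clip(amp, 0.0, None)
    return AxialScan(
        positions_mm=z,
        amplitudes_pa=amp,
        drive_voltage=config.drive_voltage_v,
        electrical_power=config.electrical_power_w,
        pulse_descriptor={"cycles": 100, "repetition_rate_hz": 1000.0},
        meta={
            "base_pressure_pa": base,
            "modulation_depth": depth,
            "target_sd_percent": config.target_sd_percent,
            "seed": config.seed,
        },
    )


@dataclass(frozen=True)
class BeadImageConfig:
    """Live/dead bead image generator parameters.

    Beads are rendered as uniform disks; live beads emit in the FDA
    channel, dead beads in the PI channel.  Intensities are in 16-bit
    camera counts.  ``dead_fraction`` is realised exactly as
    ``round(dead_fraction * n_beads)`` dead beads.
    """

    shape: tuple[int, int] = (256, 256)
    n_beads: int = 16
    bead_radius_px: float = 12.0
    bead_radius_sd_px: float = 0.5
    dead_fraction: float = 0.1
    live_intensity: float = 3000.0
    live_intensity_sd: float = 200.0
    dead_intensity: float = 3000.0
    dead_intensity_sd: float = 200.0
    background_level: float = 100.0
    noise_sd: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.live_intensity < 0 or self.dead_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.n_beads < 1:
            raise ValueError("need at least one bead")


def generate_bead_images(config: BeadImageConfig) -> FluorescencePair:
    """Render paired FDA/PI bead images with known ground truth.

    The pair's ``meta`` stores the realised dead fraction and the
    integrated (noise-free, background-free) signal in each channel.
    Beads whose disks extend past the image bounds are clipped with a
    warning.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    n_dead = int(round(config.dead_fraction * config.n_beads))
    fda = np.zeros(config.shape, dtype=float)
    pi = np.zeros(config.shape, dtype=float)
    clipped = 0
    for i in range(config.n_beads):
        r = max(1.0, rng.normal(config.bead_radius_px, config.bead_radius_sd_px))
        cy = rng.uniform(r, h - r) if h > 2 * r else h / 2
        cx = rng.uniform(r, w - r) if w > 2 * r else w / 2
        rr, cc = disk((cy, cx), r, shape=config.shape)
        full_area = math.pi * r * r
        if rr.size < 0.95 * full_area:
            clipped += 1
        is_dead = i < n_dead
        if is_dead:
            level = max(0.0, rng.normal(config.dead_intensity, config.dead_intensity_sd))
            pi[rr, cc] += level
        else:
            level = max(0.0, rng.normal(config.live_intensity, config.live_intensity_sd))
            fda[rr, cc] += level
    if clipped:
        warnings.warn(f"{clipped} bead(s) clipped at the image boundary")
    fda_signal = float(fda.sum())
    pi_signal = float(pi.sum())
    fda_img = fda + config.background_level
    pi_img = pi + config.background_level
    if config.noise_sd > 0:
        fda_img = fda_img + rng.normal(0.0, config.noise_sd, size=config.shape)
        pi_img = pi_img + rng.normal(0.0, config.noise_sd, size=config.shape)
    fda_u16 = np.clip(np.rint(fda_img), 0, 65535).astype(np.uint16)
    pi_u16 = np.clip(np.rint(pi_img), 0, 65535).astype(np.uint16)
    return FluorescencePair(
        fda_image=fda_u16,
        pi_image=pi_u16,
        meta={
            "dead_fraction": n_dead / config.n_beads,
            "n_dead": n_dead,
            "n_beads": config.n_beads,
            "fda_signal": fda_signal,
            "pi_signal": pi_signal,
            "background_level": config.background_level,
            "seed": config.seed,
        },
    )


#: Recovery trajectory emulating the study design: high viability on
#: rewarming, a dip at 24 h, then near-linear recovery (percent).
DEFAULT_BASELINE_PCT: Mapping[float, float] = {
    0.0: 88.0,
    2.0: 87.0,
    24.0: 80.0,
    48.0: 83.0,
    72.0: 86.0,
    96.0: 89.0,
}


def generate_viability_timecourse(
    condition_offsets_pct: Mapping[str, float] | None = None,
    baseline_pct: Mapping[float, float] | None = None,
    n_replicates: int = 5,
    noise_sd_pct: float = 1.2,
    seed: int | None = None,
) -> TimecourseDataset:
    """Generate a conditions x timepoints x replicates viability dataset.

    Values are viability percentages: the shared baseline trajectory plus
    a constant per-condition offset plus Gaussian replicate noise.  The
    defaults mirror the study layout — three rewarming conditions, six
    timepoints {0, 2, 24, 48, 72, 96} h, five replicate vials — with
    offsets of +1.6 (low-power ultrasound) and −2.0 (high-power
    ultrasound) percentage points relative to the water bath and a
    between-replicate spread of 1.2 points.
    """
    if condition_offsets_pct is None:
        condition_offsets_pct = {
            "water_bath": 0.0,
            "us_20w": 1.6,
            "us_100w": -2.0,
        }
    if baseline_pct is None:
        baseline_pct = DEFAULT_BASELINE_PCT
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, offset in condition_offsets_pct.items():
        for tp, base in baseline_pct.items():
            for rep in range(n_replicates):
                rows.append(
                    {
                        "condition": cond,
                        "timepoint_h": float(tp),
                        "replicate": rep,
                        "value": base + offset + rng.normal(0.0, noise_sd_pct),
                    }
                )
    return TimecourseDataset(pd.DataFrame(rows))
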