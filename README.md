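# cryosonic

Analysis toolkit for **ultrasonic rewarming of cryopreserved samples** in
2 ml cryovials: the acoustic characterisation of a tubular rewarming
transducer, hydrophone cross-calibration, thermocouple rewarming-kinetics
extraction with feedback-free exposure planning, and FDA/PI fluorescence
viability statistics — together with seeded synthetic-data generators that
emulate every raw measurement the chain consumes.

It is written for cryobiology / biomedical-ultrasound labs that rewarm
slowly-frozen cell preparations (e.g. alginate-encapsulated liver
spheroids) with a resonant tube transducer and need reproducible,
scriptable versions of the standard analysis steps.

## What it computes

**Acoustic field.** The free field inside a tubular radiator of radius
*a* follows the zero-order Bessel profile

```
p(r) = p0 / J0(k a) · J0(k r)
```

with wavenumber *k = 2πf/c*. The package evaluates this profile, reduces
axial hydrophone scans to mean/peak pressure and relative spread, fits the
through-origin drive-voltage → pressure line (flagging compression at high
drive via leave-one-out residuals), and converts amplitudes to plane-wave
intensity `I = D·p²/(2Z)` (duty cycle *D*, impedance *Z* = 1.5 MRayl by
default).

**Hydrophone calibration.** Steady-state tone-burst amplitudes by
single-bin Fourier projection over an exact integer number of cycles
(default cycles 90–100 of a 100-cycle burst), linear temperature
correction of a reference sensitivity (0.64 %/°C default), sensitivity
transfer to a fibre-optic hydrophone, and quadrature uncertainty budgets.

**Rewarming kinetics.** First-crossing times, windowed rates over
[−60, −40] °C (frozen regime) and [−20, 5] °C (phase transition), total
−65 → 5 °C rewarming times, time-at-temperature ensemble curves,
normalised curves and instantaneous rate–temperature profiles, and
feedback-free exposure plans (ceil of the mean time to target). Group
comparisons: one-way ANOVA with Tukey HSD, two-tailed t-tests.

**Viability.** `viability = ΣFDA / (ΣFDA + ΣPI)` from paired 16-bit
fluorescence images, recovery trajectories over the
{0, 2, 24, 48, 72, 96} h timepoints, and two-way ANOVA
(condition × timepoint) with Shapiro–Wilk residual checks and Tukey
pairwise condition comparisons.

**Synthetic data.** A lumped apparent-heat-capacity phase-change model for
thermocouple traces (latent-heat plateau, power-dependent acceleration,
thermocouple viscous-heating artifact, measurement noise), ring-up tone
bursts, modulated axial scans, live/dead bead image pairs, and viability
time-courses — all seeded, all with ground truth attached.

## Worked example

Plan a feedback-free 20 W exposure from three simulated replicate vials:

```python
import cryosonic as cs

traces = cs.simulate_rewarming_ensemble(
    cs.RewarmSimConfig(power_w=20.0), n_traces=3, seed=0
)
summary = cs.summarise_kinetics(traces)
plan = cs.plan_exposure(cs.ensemble_mean_curve(traces))
print(f"low-T rate (-60..-40 °C): {summary.mean_low_t_rate:.0f} ± {summary.sd_low_t_rate:.0f} °C/min")
print(f"total time -65 -> 5 °C: {summary.mean_total_time_s:.1f} ± {summary.sd_total_time_s:.1f} s")
print(f"planned exposure: {plan.duration_s} s at {plan.power_w:.0f} W")
print(f"plane-wave intensity at 2.8 MPa: {cs.plane_wave_intensity(2.8e6):.0f} W/cm2")
```

prints

```
low-T rate (-60..-40 °C): 119 ± 1 °C/min
total time -65 -> 5 °C: 84.8 ± 0.1 s
planned exposure: 85 s at 20 W
plane-wave intensity at 2.8 MPa: 261 W/cm2
```

The 20 W vials cross the frozen regime at ~119 °C/min, take ~85 s to reach
the 5 °C endpoint (chosen to stay below cryoprotectant-toxicity
temperatures), and the planner rounds the mean time up to a whole second
for the exposure timer. At the 100 W condition's 2.8 MPa mean axial
pressure the plane-wave intensity is 261 W/cm².

A CLI mirrors the library: `cryosonic field|calibrate|kinetics|plan|viability|simulate …`
(each subcommand reads the CSV/TIFF/YAML conventions described in
`cryosonic.io` and emits JSON).

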