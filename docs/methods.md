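# Methods

This note documents the models and numerical choices behind `cryosonic`,
what the synthetic-data generators do and do not emulate, and the
package's known limitations.

## Acoustic field model

The tube transducer is approximated as an infinite cylinder radiating
inward, giving the radial pressure profile `p(r) = p0/J0(ka)·J0(kr)`.
The model is singular when `k·a` sits at a zero of `J0`; construction
rejects configurations with `|J0(ka)| < 1e-6`. Pressures are signed
(phase-reversed lobes); scan statistics use magnitudes.

Parameters and defaults:

| parameter | default | rationale |
|---|---|---|
| frequency | user-set (474 kHz typical) | device resonance |
| sound speed | 1520.1 m/s | pure water at the 33 °C bath temperature (standard correlation); required because the bath is held warm |
| impedance | 1.5 MRayl | water/soft tissue, plane-wave intensity convention |
| scan spread | population SD as % of mean | matches the hand-checkable worked values; for the ~50-point scans involved the sample/population distinction is below measurement uncertainty |

The drive-voltage → mean-pressure relation is fitted through the origin
(zero drive is zero pressure). Deviating points are flagged with
**leave-one-out** residuals at a 3 % default threshold: a sagging
high-voltage point has enough leverage in a through-origin fit to pull
the slope toward itself and hide in its own full-fit residual, so each
point is judged against the trend of the others. "Peak" axial pressure is
the maximum scanned sample, with no interpolation — it is a discrete
hydrophone scan. The mean-axial-pressure z-window is a parameter
(`AxialScan.windowed`) because holder-aberrated regions may need
excluding; no window is applied by default. Intensity is returned at full
precision; only the CLI summary rounds to 2 significant figures.

## Hydrophone calibration

Steady-state amplitude and phase come from a single-bin discrete Fourier
projection over an exact integer number of cycles (no window function):
on integer-cycle spans the projection is orthogonal to DC and to all
harmonics below Nyquist, which is what makes the 90–100-cycle window of a
100-cycle resonant burst a clean amplitude estimate. Non-integer cycle
windows are rejected, never silently truncated. With sampling
incommensurate with the drive frequency a small leakage error remains
(order 1/n_samples per cycle); the generators default to 100
samples/cycle so windows align exactly.

The reference sensitivity temperature correction is linear and
multiplicative, `s' = s(1 + α ΔT)` with α = 0.0064/°C. The *sign* of the
coefficient is configurable because the direction of the drift is
instrument-specific; the default raises sensitivity with temperature.
Uncertainty components combine in quadrature only — the module reports
`sqrt(9² + 4²) ≈ 9.85 %` for the canonical 9 % + 4 % budget and applies no
conservative inflation; users wanting a rounded-up headline figure apply
it downstream.

## Rewarming kinetics

Crossing times interpolate linearly between samples and take the FIRST
upward crossing; warming traces are near-monotone and the first crossing
is conservative under noise. Ensemble averaging is over
**time-at-temperature** (mean/SD of crossing times at each grid
temperature), not temperature-at-time, which keeps latent-heat plateaus
aligned across replicates; the default grid is 0.5 °C from −65 to 5 °C.
Rates are reported in °C/min, times in seconds. The start temperature
default is −65 °C (vial temperature at insertion; storage itself is
colder), exposed as a parameter.

The ensemble "overall rate" is reported under both conventions — mean of
per-trace rates, and span divided by mean total time — because they
differ slightly for heterogeneous replicates; both appear in
`KineticsSummary`.

Instantaneous rates are central differences of the mean
time-at-temperature curve (`numpy.gradient`), with an optional
odd-width moving average (width 5 suggested) that is **off** by default:
differentiation amplifies noise on measured traces, but smoothing would
bias the noiseless calibration checks.

Exposure plans take the ceiling of the mean time to target — the timer
has 1 s resolution and undershoot (residual ice) is the failure mode to
avoid — so the plan is monotone: a slower ensemble never yields a shorter
duration.

Group comparisons use one-way ANOVA with Tukey-HSD follow-up (the
concrete realisation chosen for an otherwise unspecified
multiple-comparison-of-means step) and equal-variance two-tailed t-tests,
via scipy. Degenerate inputs (all values identical; zero-variance shifted
groups) are flagged explicitly rather than returning NaN.

## Viability analysis

The viability ratio uses raw channel sums by default: the ratio
definition is stated on sums, and the channels' different exposure times
(100 ms FDA, 800 ms PI) are part of the assay's calibration, so no
cross-channel normalisation is applied; a constant-offset background
subtraction (clipped at zero) and a correction factor are available as
options. The two-way ANOVA includes the condition × timepoint interaction
by default and is fitted with statsmodels OLS; residual normality is
reported with Shapiro–Wilk; pairwise condition comparisons pool across
timepoints with Tukey HSD. Unbalanced layouts are rejected unless
explicitly permitted (type-II sums of squares are then used as fitted).

## Synthetic-data generators

### Rewarming simulator

A lumped (zero-dimensional) model: the analysis consumes single-point
centre-of-vial thermocouple traces, and no spatial coefficients are
available, so a radial PDE would add parameters without adding testable
structure. The ODE is

```
dT/dt = [k_c (T_bath − T) + η(T)·P + q_art(T, P)] / C_app(T)
```

with apparent heat capacity `C_app` equal to the frozen capacity below
the solidus (−15 °C), the thawed capacity above the liquidus (0 °C), and
the mean capacity plus `L/(T_l − T_s)` inside the melt window. The
coupling η is piecewise constant (frozen/thawed values switching at the
solidus); its true temperature dependence in cryopreserved media is
unknown, and this stand-in makes no claim about it. The thermocouple
viscous-heating artifact is an additive heat term `g·P`, active only
above the solidus and only under drive — emulating the spurious apparent
rates a thermocouple reports once the medium is fluid enough for the
probe to oscillate. Integration is adaptive RK45 (rtol 1e-8, step capped
at half the 2 Hz sample interval so the regime discontinuities are
resolved), sampled on the fixed logger grid with Gaussian noise
(0.2 °C default) per sample; deterministic per seed.

Default constants (effective lumped values for a ~1.8 ml vial plus
holder):

| constant | value | anchored to |
|---|---|---|
| bath temperature | 33 °C | device water temperature |
| conduction k_c | 0.1 W/°C | sets the absolute time scale |
| C_frozen / C_thawed | 4.98 / 9.96 J/°C | ice ≈ half the specific heat of water; frozen-regime conduction rate ≈ 100 °C/min |
| latent heat L | 436.8 J | 0 W total −65→5 °C time of 189 s |
| η_frozen | 0.075 | 100 W total time ≈ 33 s with a frozen-regime rate ≈ 190 °C/min |
| η_thawed + artifact gain | 0.05 + 0.29 | transition-rate dip ≈ 1/3 of the low-T rate at 100 W (vs ≈ 1/18 at 0 W) |

These were calibrated once against the study-condition anchors using the
closed-form piecewise-exponential solution of the noiseless model, then
frozen. With them the model traverses −65 → 5 °C in 189.0 s at 0 W,
32.8 s at 100 W and 84.8 s at 20 W, with rate dips of ≈ 0.056 (0 W) and
≈ 0.32 (100 W) of the respective low-temperature rates.

What the simulator does **not** emulate: freezing (supercooling and
nucleation), spatial temperature heterogeneity within the vial,
replicate-to-replicate coupling variation (only additive measurement
noise is modelled, so ensemble SDs are smaller than those of real
replicate vials), cavitation, and any real temperature dependence of
ultrasonic absorption. Passing tests therefore demonstrate that the
*extraction chain* is correct and self-consistent — not that the model
predicts real vials beyond the anchored traversal times.

### Other generators

*Tone bursts*: cosine with exponential ring-up (time constant in cycles,
default 20) to a plateau, 100 samples/cycle, optional Gaussian noise.
*Axial scans*: base pressure linear in drive voltage (38.4 kPa/V default)
times a sinusoidal vertical modulation whose depth is `√2·sd%/100`
(population SD of a sinusoid is depth/√2), defaulting to an 11.5 %
target spread with a 6.3 mm modulation wavelength over z = 10–35 mm; the
standing-wave physics behind the modulation is deliberately not
modelled. *Bead images*: uniform disks (live → FDA channel, dead → PI
channel), 16 beads of 12 ± 0.5 px radius on 256² frames, per-bead
brightness 3000 ± 200 counts, background 100 counts, noise SD 5,
quantised to uint16. The radius spread is tight (Jetcutter beads are
near-monodisperse) so that the realised intensity dead-fraction of a
single frame tracks the configured count fraction within ±0.03.
*Viability time-courses*: a shared baseline trajectory (high at 0 h, dip
at 24 h, near-linear recovery) plus constant condition offsets (defaults
+1.6 / −2.0 percentage points for low/high-power ultrasound vs bath) and
1.2-point replicate noise across 3 conditions × 6 timepoints × 5
replicates.

## Problem sizes and tolerances

The test suite and acceptance script run the chain at the study's own
scales: 2 Hz traces of 60–400 s, 100-cycle bursts at 100 samples/cycle,
51-point scans, 256² images, 3–5 replicates. Permutation oracles use
1e5 resamples; the parametric vs permutation p-value agreement is
asserted at 0.01 absolute, the small-sample discreteness of n = 12
fixtures dominating the Monte-Carlo error. The type-I-rate check runs
200 seeded null datasets and asserts a rejection fraction in
[0.02, 0.09].

## Known limitations

* The tube-field model is strictly radial; vertical structure enters only
  through the empirical scan modulation.
* No frequency-response deconvolution or directivity correction in the
  calibration chain; sensitivity transfer assumes both hydrophones sample
  the same field.
* Measured-trace artifacts (viscous heating) are *modelled* in the
  generator but not *corrected* in the analysis — extracted
  phase-transition rates from driven thermocouple traces remain
  artifact-inflated, as they are in practice.
* The viability statistics assume the image pairs are comparable across
  conditions (same staining, exposure and field-of-view conventions);
  no spatial/per-bead analysis is performed.
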