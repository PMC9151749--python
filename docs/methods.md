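# Methods

This note documents the models behind `nirsox`, the parameter choices that
matter, and what the synthetic tests do and do not demonstrate.

## Spatially resolved StO₂ inversion

The inversion assumes a homogeneous semi-infinite diffusive medium in which
the absorbance gradient is ∂A/∂ρ = (μ_eff + 2/ρ)/ln10 with
μ_eff = √(3 μ_a μ_s′). Two conventions are open in a two-point realization
and were fixed as follows:

- **Effective ρ in the 2/ρ term**: the logarithmic mean
  ρ_lm = (ρ₂−ρ₁)/ln(ρ₂/ρ₁) ≈ 5.36 mm for the 4/7 mm pair. With this
  choice, the finite-difference gradient of the intensity law
  I ∝ exp(−μ_eff ρ)/ρ² returns exactly μ_eff: the geometric term cancels
  identically and the generator→inverter round trip is exact to machine
  precision in the noise-free limit. The arithmetic midpoint (5.5 mm) is
  available by configuration; it breaks the exact cancellation at the
  few-percent level.
- **Smoothing domain**: the 5-s moving average is applied to the
  gradient-of-optical-density (an OD-domain quantity) after Butterworth DC
  extraction and before the inversion, i.e. smoothing acts on the linear
  stage of the chain, not on the squared/solved outputs.

The channel calibration divides raw detector readings by the
transimpedance-gain ratio (4.3:1 for far:near). Scaling both gains by a
common factor provably leaves StO₂ unchanged; an error in the *ratio*
biases StO₂ — this calibration sensitivity is exercised by a test.

Negative solved concentrations (possible under noise) are clipped to zero
before the saturation ratio and the sample is flagged; samples with
non-positive total hemoglobin are flagged invalid (NaN), never raised, so
streaming runs survive isolated bad frames. Invalid raw samples are
hold-last-value repaired before the IIR filter (and flagged), because a NaN
would otherwise poison the filter state permanently.

### Accuracy floor of the two-point method

The diffusion gradient law is asymptotic. An independent dipole-diffusion
evaluation (semi-infinite Green's function with extrapolated boundary, no
Monte Carlo involved) shows that inverting two-point intensities at
4/7 mm under-reads StO₂ increasingly as absorption grows: with total
hemoglobin 0.90 mmol/L the bias is ≈ −0.01 at StO₂ 0.9, −0.04 at 0.7,
−0.08 at 0.5 and −0.15 at 0.3 (the 660 nm channel then has
μ_a/μ_s′ ≈ 0.17, outside the diffusion regime). Monte Carlo–in-the-loop
recovery reproduces this floor; it is a property of the method at this
geometry and tissue, not of the implementation. Users comparing against
reference oximetry at low saturations should expect this systematic.

## Single-detector modified Beer–Lambert comparator

`mbll_sto2` converts absorbance changes at one detector into concentration
changes through the extinction matrix and an externally supplied
differential pathlength, then applies the baseline-calibrated saturation
formula. The pathlength may be a scalar or a per-wavelength pair — the
differential pathlength factors at 660 and 850 nm differ by ~7 % in muscle,
and the pair form is what makes model-consistent cross-checks against the
spatially resolved route agree within 0.03.

## Photon Monte Carlo

Standard weighted-packet transport: step length −ln U/μ_t, per-interaction
deposition W μ_a/μ_t, Henyey–Greenstein deflection, Russian roulette below
weight 10⁻⁴ with survival factor 10 (conventional values). μ_s is recovered
from the printed μ_s′ and g by the similarity relation μ_s = μ_s′/(1−g).
Fluence is deposited energy / (μ_a × voxel volume), normalized so the total
launched weight carries the **time-averaged** source power
irradiance × emitting area × duty (duty 0.10): the probe operates pulsed at
50 Hz / 10 % duty, and the reported penetration figures describe that
operating point. Sources launch uniformly over the 0.25 × 0.25 mm emitter
with directions uniform over the ±60° solid-angle cone (the stated angular
support; the profile within it is not specified).

**Boundary condition.** The default is unpolarized Fresnel reflection with
total internal reflection at the top surface using n = 1.37 — the
physically appropriate model for an implanted probe interface, and the
configuration under which the red-source penetration depth and illuminated
volume land on the reference figures. A matched-index escaping boundary
("escape") is retained — it is the configuration mirrored by the
closed-form diffusion oracle — as is an infinite-medium mode ("none") used
to validate the kernel against the point-source Green's function
P exp(−μ_eff r)/(4πDr), D = 1/(3μ_s′) (agreement within 5 % for
r = 2–5 mm; ~1 transport mean free path from the source the diffusion
formula itself is off by ~15 %, so the near-field tolerance is wider).

**Grids and statistics.** The full-fidelity grid (1000³ voxels of
5×10⁻⁹ cm³) is supported but desk runs default to 0.2 mm voxels over
16 × 16 × 12 mm. This is a deliberate statistical choice, not only a memory
one: at the 10⁻³ mW/mm² contour a 0.2 mm voxel collects ~10 deposits per
10⁶ packets, enough for stable threshold counting, whereas 17 µm voxels
would be hit-or-miss there and threshold-based volumes would measure shot
noise. The axial profile used for penetration depth averages voxels within
0.3 mm of the source axis and applies a 3-layer geometric-mean smoothing
before log-linear interpolation of the crossing.

**Known discrepancy (NIR source).** Under every convention examined
(similarity vs. direct μ_s interpretation, per-pulse vs. duty-averaged
power, matched vs. Fresnel boundary, axial vs. lateral readout) the NIR
(850 nm) penetration depth and illuminated volume cannot be brought
simultaneously to the reference pair (6.17 mm, 179.8 mm³): matching the
volume requires ~1.1× the computed on-axis fluence while matching the depth
requires ~2.2×, and μ_s′ exp(−√(3μ_a μ_s′) z) is maximized near the quoted
μ_s′ itself, so no scattering value closes the gap at fixed source power.
The red source reproduces both its reference figures through the identical
code path. The package reports the computed NIR values (~4.7 mm,
~155 mm³ at the default operating point) without adjustment.

## Pennes bioheat model

ρC_p ∂T/∂t = ∇·(k∇T) + Q_the + φμ_a with muscle constants k = 0.49 W/m·K,
ρ = 1090 kg/m³, C_p = 3421 J/kg·K (standard skeletal-muscle values; the
tissue constants are configurable). Perfusion and metabolism are neglected
(constant-background assumption), so the solved field is the temperature
*rise*. The explicit FTCS scheme (numba-compiled) enforces
dt ≤ dx²ρC_p/(6k) and refuses unstable steps with a suggested dt; far
boundaries are held at zero rise. Validation: equilibrium, the diffusion
maximum principle, stored-energy balance (2 %), the continuous point-source
transient Q/(4πkr)·erfc(r/2√(αt)) (5 %), and grid-refinement convergence
(<10 % on halving dx).

The two LED dies (340 × 340 × 270 µm footprints, modeled 0.8 mm apart
center-to-center — the probe-tip layout is not dimensioned, and the
near-field bounds are insensitive to this at the 10 % level) dissipate
their duty-averaged electrical-minus-optical power uniformly over their
footprints: 0.28 mW (red: 2.1 V × 1.7 mA − 0.77 mW) and 0.41 mW (NIR:
1.55 V × 3.0 mA − 0.58 mW) at 10 % duty. The absorbed-light term φμ_a is
resampled from the Monte Carlo fluence grids (already duty-averaged through
the source normalization). Probe substrate and encapsulation conduction are
neglected — the safety claims are upper bounds, tolerant to this
simplification. The desk-scale study (0.1 mm grid, 2 cm domain, 300 s)
gives ~0.14 °C at 0.5 mm above the dies, under the 0.25 °C near-field bound,
and ~0.06 °C beyond 1.5 mm, under the 0.1 °C far-field bound.

The NTC thermistor companion uses R = R₀ exp B(1/T − 1/T₀) with
R₀ = 10 kΩ, B = 3380 K and the datasheet reference T₀ = 298.15 K (25 °C,
not stated with the device constants).

## Synthetic-signal generator

The generator emulates the porcine occlusion protocol: two cycles of
baseline / arterial occlusion (ischemia) / recovery / venous occlusion
(congestion) / recovery, 15 min per phase at full scale, with exponential
transitions between segment targets. Defaults:

- **Episode StO₂ levels** 0.70 / 0.40 / 0.45 (baseline / ischemia /
  congestion): plausible placeholders for levels only shown graphically in
  vivo; they are configuration, not measured truth.
- **Total hemoglobin 0.90 mmol/L**, which places the baseline absorption
  coefficients at the muscle values used in the optical simulations
  (0.53/0.49 cm⁻¹ at StO₂ 0.76).
- **Pulsation** as an added arterial-blood volume oscillation (saturation
  0.97) at the cardiac (120 beats/min, inside the observed 1.7–2.5 Hz
  band) and respiratory (18 breaths/min ≈ 0.3 Hz) frequencies, 2 % and
  0.8 % of total hemoglobin respectively — a typical perfusion index. The
  arterial weighting makes ratio-of-ratios SpO₂ meaningful. Pulsation is
  switched off (through the same exponential envelope) in occlusion
  segments, emulating pulsatility loss.
- **Noise**: multiplicative white noise (default SD 1 % of the sample),
  slow per-wavelength source drift (1 %, 60 s period — common to both
  detectors, so it cancels in the gradient), optional ambient offset
  removable via a dark slot. All randomness flows from one seed.
- **Transition time constant** 10 s at full scale, shrunk proportionally
  (clamped to ≥0.5 s) for scaled-down protocols so plateaus remain
  distinguishable.

The generator shares the diffusion intensity law, extinction spectra and
single-k scattering model with the inversion. Round-trip tests therefore
demonstrate *internal consistency and pipeline correctness* — recovery of
commanded StO₂ to ≤0.02 noise-free and ≤0.05 at 1 % noise — not absolute
in vivo accuracy, which is bounded separately by the Monte Carlo-in-the-loop
study. Features of real data the generator does not emulate: motion
artifacts, heterogeneous/layered tissue, probe-tissue coupling drift,
hemodynamic transients beyond first-order exponentials.

## Signal conditioning and vitals

DC extraction uses a causal single-pass second-order Butterworth low-pass
at 0.2 Hz (streaming semantics; zero-phase offered for offline use),
initialized at the first sample so constants pass unchanged. The moving
average is a trailing 5-s window with expanding warm-up. The heart-rate
search band is 0.8–5 Hz — wider than the observed porcine 1.7–2.5 Hz,
which is species context rather than a filter specification; respiration
uses 0.1–0.7 Hz. Rate estimates take the dominant Welch-spectrum peak in
band; confidence is the peak-to-median in-band power ratio (floor 10).
Pulse presence additionally requires a perfusion index (relative AC
amplitude) above 0.2 % — spectral confidence alone is scale-invariant and
would report a "pulse" in numerically tiny residue; the combination makes
the no-pulse flag during occlusions robust both in noise-free and noisy
streams. SpO₂ uses the conventional empirical line
SpO₂ = 1.10 − 0.25 R clamped to [0, 1]; these coefficients are a stated
convention, not a device calibration against co-oximetry, and absolute
SpO₂ from this package should be treated accordingly. Bland–Altman returns
the mean ± sample SD (n−1) of paired differences; the zero-lag normalized
cross-correlation is the Pearson inner product of mean-removed series.

## Acquisition model

The LED frame runs at 50 Hz; each ADC samples at 100 Sa/s per detector,
giving two slots per frame (red-lit, NIR-lit) in the default layout. A
"dark" slot for ambient subtraction is supported by raising the ADC rate
(e.g. 150 Sa/s with a red/nir/dark slot order); without one, ambient is
assumed removed by the per-channel dark offsets. Slot assignment is derived
from the time base, so a dropped sample resynchronizes automatically and
the affected frame is flagged rather than shifting all later slots.

## Numerical and degenerate-input choices

- Penetration-depth interpolation is linear in log-fluence between layer
  centers; a profile already below threshold at the surface returns 0;
  a profile never crossing raises (grid too small) rather than
  extrapolating.
- The hemoglobin solve refuses extinction matrices with |det| ≤ 1e-9.
- `kmua_from_gradient` treats gradients at the zero-absorption fixed point
  as valid (k μ_a = 0) and gradients below it as non-physical flagged
  samples.
- Monte Carlo and bioheat kernels are strictly sequential: identical seeds
  give bit-identical tallies and fields.
- CSV outputs use fixed float formatting, making repeated runs
  byte-identical.

## Problem sizes used in the packaged studies

Desk-scale defaults balance statistical precision against single-CPU
runtimes: 10⁶–2×10⁶ photon packets on 0.2 mm voxel grids for the
penetration/volume figures (MC jitter ≈ 0.05 mm and ≈ 2 mm³ at 10⁶), 3×10⁵
packets per wavelength and saturation level for the in-the-loop recovery
study, and the 0.1 mm / 2 cm / 300 s bioheat configuration. The
full-fidelity settings (11×10⁶ packets, 17 µm voxels) remain available
through `McConfig` and `VoxelGrid`.
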