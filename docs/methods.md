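# Methods

This note documents the models behind `dendrocalc`, the default
parameters and why they were chosen, the numerical decisions, and what
the synthetic-data studies do and do not demonstrate.

## Line-scan quantification

A line-scan recording is a time-major raster (rows = lines at the line
rate, columns = spatial pixels) per channel.  The analysis chain is:

1. **ROI extraction.**  Structure pixels are the contiguous run,
   containing the brightest pixel, where the time-averaged red
   (calcium-insensitive) profile is ≥ 50 % of its maximum; the remainder
   is background.  The red channel is used because it is independent of
   activity, and the same partition is applied to both channels.
2. **Ratio.**  R(t) = (Ḡ − Ḡ_bg)/(R̄ − R̄_bg).  Background subtraction
   is on by default and the ratio cancels any gain common to both
   channels (laser power, dye concentration, focus).  Lines whose
   corrected red mean is not positive are flagged invalid and filled by
   linear interpolation; a recording with more than 5 % invalid lines is
   rejected.
3. **ΔF/F.**  R₀ is the mean ratio over a 1.2 s window ending at
   stimulus onset; ΔF/F = (R − R₀)/R₀.  Division by the baseline (rather
   than bare subtraction) makes ΔF/F dimensionless and leaves every
   percent-change statistic identical to the subtractive convention,
   while absolute Peak ΔF/F values differ by the factor R₀.
4. **Smoothing.**  A 0.5 s Gaussian-weighted moving window, interpreted
   as support ± 0.25 s with σ = 0.125 s (support = ± 2σ).  Weights are
   renormalized over the available samples at the edges (no padding), so
   constants are preserved and the output length equals the input
   length.
5. **Peak ΔF/F.**  Maximum of the smoothed trace from stimulus onset to
   the end of the recording; pre-stimulus artifacts can never
   contribute.

Δ Peak ΔF/F across bath conditions is 100·(mean_after −
mean_before)/mean_before, with multiple sweeps per condition combined by
averaging their Peak ΔF/F values (not their traces).  Attenuation
profiles normalize each distance's mean peak to the most proximal
distance (= 100 %); the length constant is the least-squares fit of
100·exp(−(x−x₀)/λ) with x₀ the most proximal distance.  A best-fit λ
above 10⁴ µm is reported as *unbounded* — the signature of a flat
profile (axons, or dendrites whose leak channels are blocked).

Timing conventions: sample/line timestamps mark the start of their
acquisition interval; line 0 is the first acquired line; default
geometry is 85 Hz lines, 11.9 s total, stimulation at 2 s.

## Electrophysiology

Sweeps are uniformly sampled (20 kHz default); voltage-clamp signals are
in pA, current-clamp in mV.  Units package-wide: s, µm, mV, pA, MΩ, pF.

**Passive properties** use the two-resistor model of a patched cell: a
voltage step ΔV through access resistance R_a onto membrane R_m ∥ C_m
produces a steady current ΔV/(R_a+R_m) and a transient of initial
amplitude ΔV/R_a decaying with τ = R_a·C_m·R_m/(R_a+R_m).  From a 200 ms
−70→−100 mV step: R_a = ΔV/I_peak, R_input = ΔV/I_ss − R_a (steady state
= mean over the last 50 ms of the step), and C_m = Q/(ΔV·R_m/(R_m+R_a))
with Q the trapezoidal charge above the steady state.  If the transient
peak is below 5 % of the steady amplitude it is treated as undetectable:
R_access is reported 0 and C_m as NaN.

**I_A metric**: mean current over the first 100 ms after a −70→−50 mV
step minus the steady-state current at −50 mV (mean over the final
100 ms of the step).  Positive = transient outward (the magnocellular
signature); classification is OT-MCN iff the metric is strictly greater
than the threshold (default 0 pA) — a value exactly at threshold is
OT-PCN.  The mean (not the peak) over the window is the default; a
`use_peak` flag reports the signed extremum instead.  Note that with a
realistic uncompensated capacitive transient the metric carries a small
positive bias (a few pA for R_a ≈ 12 MΩ, C_m ≈ 30 pF), which is
negligible against magnocellular A-currents but argues for a
conservative threshold when transient inward currents are small.

**Spikes** are upward crossings of 0 mV with a 2 ms lockout — robust
for full-height somatic spikes; the threshold is configurable for
attenuated waveforms.  Firing-rate change is the post-window rate minus
the pre-window rate; time-to-first-spike is referenced to the current
injection onset and flagged (None) when no spike follows.

**Evoked responses**: signed peak deviation within 100 ms after the
stimulus relative to a 50 ms local pre-stimulus baseline.  The 100 ms
window covers EPSC and agonist-puff kinetics at ~28 °C.
**Train charge**: trapezoidal integral of baseline-subtracted current
over the last pulse of the train (pulse onset to the start of the
following inter-pulse interval), in pA·ms.
**Stability gate**: a cell is excluded when holding current or access
resistance changes by strictly more than 30 % (configurable) between
consecutive monitoring points.

## Statistics

All p-values are two-tailed.  Implemented directly (scipy supplies only
the t/F/χ² distribution functions):

- one-sample t (t = (mean − µ₀)/SEM, df = n − 1), usable directly on
  printed (mean, SEM, n) summaries;
- two-sample t with an automatic Welch decision: a two-sided F-ratio
  variance test at α = 0.05 selects pooled vs. Welch
  (Welch–Satterthwaite df); a `force` flag overrides the pre-test;
- paired t = one-sample t on the differences;
- Pearson r with the t-based p;
- one-way repeated-measures ANOVA (subjects × levels, complete cases
  required).  Mauchly's W is computed on the orthonormal-contrast
  covariance with the first-order Box χ² approximation (no higher-order
  small-sample terms); when it rejects at α = 0.05 both F dfs are
  multiplied by the Greenhouse–Geisser ε̂ = tr(S)²/((k−1)·tr(S²)),
  clipped to [1/(k−1), 1].  An `always`/`never` switch overrides the
  "correct only if necessary" rule.  ε̂ is consistent but biased
  downward in small samples, which the calibration tests account for;
- two-way designs: split-plot (between group × within factor, with the
  GG correction driven by the pooled within-group contrast covariance),
  fully-within (each effect tested against its own subject-interaction
  error), and purely between-subjects.  Unbalanced mixed designs use the
  weighted-means sums of squares, exact in the balanced case and
  verified against an independent implementation;
- Holm–Šídák step-down adjustment: ascending sort, a₍ᵢ₎ = 1 − (1 −
  p₍ᵢ₎)^(m−i+1), cumulative-maximum monotonicity, original order
  restored;
- Nernst shift |ΔE| = (R·T/zF)·|ln(c₁/c₂)| in mV at the bath
  temperature (28 °C default).

Sums of squares below 10⁻¹² of the total are treated as exact zeros so
that degenerate inputs (identical columns) yield F = 0 rather than a
ratio of rounding noise.  Rounding to printed precision happens only at
the reporting layer; internal values are full precision.

## Synthetic-data generator

The generator emulates the recording conditions the analyzers assume,
with every parameter stored as ground truth:

- **Line scans.**  The spatial profile is a Gaussian brightness bump
  (FWHM ≈ 30 % of the pixels) over a background at 10 % of structure
  brightness.  The calcium signal C(t) is a linear sum of per-pulse
  kernels a·exp(−(t−t_k)/τ_Ca) with a = a_soma·exp(−x/λ_eff)·[Ca]/2.4;
  the green channel mean is proportional to (1 + C(t)) on the structure,
  the red channel is constant in time, and with noise enabled every
  pixel of every line is an independent Poisson draw (PMT read noise is
  omitted as sub-dominant).  Noise-free mode returns the exact means.
- **Osmotic challenge** is modelled as a multiplicative dendritic leak
  factor g: λ_eff = λ/√g, so g > 1 (hyperosmotic) compresses distal
  responses more than proximal ones and g < 1 (hypoosmotic) does the
  reverse.  g is a generative knob, not a fitted quantity.
- **Calcium-to-fluorescence mapping is linear** (sub-saturating
  indicator regime); no indicator calibration is modelled.
- **Step responses** follow the two-resistor RC circuit above; step
  edges take effect strictly after their nominal time so the boundary
  sample reflects the preceding state.  C_m = 0 is allowed as the
  idealized transient-free mode used by closed-form checks.  The
  A-current adds g_A·(V − E_K)·exp(−t/τ_A) with E_K fixed at −90 mV
  (standard for the K-gluconate solutions); negative g_A reproduces the
  transient inward current of parvocellular cells.
- **Spiking** is an inhomogeneous Poisson process (thinning) with a 5 ms
  absolute refractory period — typical for magnocellular neurons — and a
  stereotyped template waveform.  The dead time makes the effective rate
  r/(1 + r·t_ref); tests compare counts against this corrected
  expectation, not the bare rate.
- **Evoked currents** are difference-of-exponentials waveforms
  (τ_rise 2 ms, τ_decay 12 ms) normalized so the peak equals the
  programmed amplitude, negative (inward) at −70 mV.

Default cell parameters (chosen once as representative of magnocellular
recordings at ~28 °C): λ = 75 µm, a_soma = 0.04 per pulse,
τ_Ca = 0.6 s, R_m = 1500 MΩ, C_m = 30 pF, R_a = 12 MΩ, g_A = 2 nS with
τ_A = 30 ms, photon budgets 200 (green) and 400 (red)
counts·pixel⁻¹·line⁻¹.  The λ default makes the distal (125 µm) response
roughly a quarter of the proximal (25 µm) one, matching the qualitative
steepness of measured attenuation profiles; the photon budgets give
baseline ΔF/F noise of a few percent per line, typical of
indicator-loaded dendrites at moderate laser power.

**What passing tests show — and not.**  The generator's passive
exponential attenuation omits frequency-dependent cable filtering,
dendritic nonlinearities, indicator saturation, bleaching, motion and
PMT read noise.  Parameter-recovery and pattern tests therefore
demonstrate that the analysis chain is unbiased and well-calibrated
*under the stated model*, not that real dendrites obey it; on real data
the chain's outputs inherit whatever deviations from these assumptions
the preparation introduces.

## Problem sizes and seeds

The simulation studies use: 100 seeded runs × 4 distances × 5 sweeps for
length-constant recovery; 100 random traces / 100 random paired datasets
for the oracle-equivalence checks; 10,000 null datasets per test for
type-I calibration; and 5 noiseless parameter variants plus 50 noisy
seeds for the proximal/distal modulation pattern.  All randomness flows
through `numpy.random.Generator` seeded from a single integer
(`--seed` on the CLI and acceptance script), and identical seeds give
bit-identical outputs.

## Known limitations

- No motion or bleaching correction, multi-ROI segmentation, or absolute
  calcium calibration.
- No spontaneous-PSC event detection, spike-waveform classification, or
  liquid-junction-potential correction.
- Mauchly's p uses the first-order χ² approximation; decisions at
  α = 0.05 agree with higher-order implementations except at marginal
  values.
- The unbalanced mixed-design ANOVA uses weighted-means sums of squares
  (Type-I-like); strongly unbalanced designs with correlated factors
  deserve a dedicated mixed model.
- Proprietary acquisition formats (PrairieView, pCLAMP/ABF) are not
  read; adapters would sit at the I/O boundary.
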