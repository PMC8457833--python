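# dendrocalc

Quantification toolkit for **activity-induced dendritic calcium influx**
measured with two-photon line scans, together with the supporting
patch-clamp measurements and the repeated-measures statistics used to
analyze such experiments.  It targets the experimental design used to
study dendritic conductivity in hypothalamic oxytocinergic magnocellular
neurons (OT-MCNs): somatic activity is driven by a 2 s train of
action-potential-like voltage steps (+50 mV for 5 ms at 20 Hz from
−70 mV) while 85 Hz line scans across a dendrite record a
calcium-sensitive (Fluo-5F-like, green) and a calcium-insensitive
(Alexa-594-like, red) channel simultaneously.

The package is a library first: everything is importable from
`dendrocalc`, with short narrative scripts in `examples/` and a thin
`dendrocalc` CLI for shell use.

## What it computes

**Line-scan ΔF/F** (`dendrocalc.linescan`).  Per line, the
background-corrected fluorescence ratio

&nbsp;&nbsp;&nbsp;&nbsp;R(t) = (Ḡ − Ḡ_bg) / (R̄ − R̄_bg)

is normalized against the mean over a 1.2 s baseline window immediately
before the stimulus, ΔF/F(t) = (R(t) − R₀)/R₀, smoothed with a 0.5 s
Gaussian-weighted moving window, and summarized by **Peak ΔF/F** (the
post-stimulus maximum).  Changes across bath conditions are expressed as
**Δ Peak ΔF/F** (% of the baseline-condition response); responses across
distances are normalized to the most proximal site and fit with
100·exp(−(x−x₀)/λ) to estimate the dendritic length constant λ.

**Electrophysiology** (`dendrocalc.ephys`).  Passive properties
(R_input, C_m, R_access) from the 200 ms −70→−100 mV monitoring step via
the two-resistor RC model; the transient outward-current metric (I_A)
after a −70→−50 mV step that separates magnocellular from parvocellular
oxytocin neurons; spike detection, firing-rate change, time to first
spike; evoked-response amplitudes; holding-current shifts; train-charge
monitoring; and the patch-stability exclusion gate.

**Statistics** (`dendrocalc.stats`).  Two-tailed one-sample, two-sample
(pooled/Welch with an automatic variance pre-test at α = 0.05) and paired
t tests; Pearson correlation; one-way and two-way (mixed, fully-within,
between) repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse–Geisser df correction; Holm–Šídák step-down adjustment; and
the Nernst driving-force shift (RT/zF)·ln(c₁/c₂).  Every test accepts raw
data or a printed `(mean, SEM, n)` summary.

**Synthetic data** (`dendrocalc.synth`).  A ground-truth generator for
all of the above: Poisson-noise dual-channel rasters whose calcium
kernel attenuates as exp(−x/λ_eff) with λ_eff = λ/√(leak factor),
RC step responses, A-current sweeps, inhomogeneous-Poisson spiking and
difference-of-exponentials evoked currents.  Noise-free mode produces the
exact closed forms the analysis chain is tested against.

## Worked example

```sh
python examples/attenuation_profile.py
```

simulates five noisy line scans at each of four distances and prints:

```
distance (um)   Peak dF/F (% of most proximal)
        25       100.0
        50        72.8
       100        37.8
       150        18.2

fitted length constant: 76.1 um (generator: 75 um)
```

The response at 150 µm is below 20 % of the proximal response — the
dendrite is a weak conductor of somatic voltage trains — and the fitted λ
recovers the generator's 75 µm within noise.  The other examples show the
distal-dominant effect of a hyperosmotic (leak-increasing) challenge on
Δ Peak ΔF/F, intrinsic-property extraction with MCN/PCN classification,
and reconstruction of published test statistics from printed summaries:

```
python examples/osmotic_challenge.py
proximal (25 um): delta Peak dF/F =  -12.8 +/-  0.8 %
distal (125 um):  delta Peak dF/F =  -51.6 +/-  2.0 %
paired t(7) = 15.31, p = 1.2e-06
```

## Command line

```sh
dendrocalc simulate linescan --seed 1 --distance 25 --out scan.tif
dendrocalc dff scan.tif --baseline 1.2 --smooth 0.5 --out trace.csv
dendrocalc stats ttest --mean -14.3 --sem 3.37 --n 13
dendrocalc stats nernst --c1 2.4 --c2 2.16
dendrocalc run --manifest manifest.csv --out results/ --seed 1
```

Line scans are two-page 16-bit TIFFs (green, red) with a JSON sidecar;
sweeps are two-column CSV tables with a JSON sidecar; batch runs consume
a CSV manifest (`file, cell_id, condition, compartment, distance_um`).

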