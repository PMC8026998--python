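# retinakit

Quantitative analysis toolkit for retinal neuroprotection studies in mouse
models of retinitis pigmentosa (RP): micro-electrode-array (MEA)
light-response analysis, cone-survival decay kinetics, and the expression
statistics used around such experiments.  It is written for researchers who
record retinal ganglion cell (RGC) activity from explants, count surviving
cone photoreceptors over time, or test treatment effects in small RNA-seq
and qPCR designs — and who want every step reproducible and testable on
synthetic data with known ground truth.

## What it computes

**MEA light-response pipeline** (`retinakit.mea`).  Raw multi-channel
voltage (25 kHz) is band-pass filtered (400–5000 Hz Butterworth, order 2),
spikes are detected as crossings of 5× the SD of the filtered signal with a
1.5 ms pause, and counted in 350 ms ON / OFF / spontaneous windows around
each light flash.  An electrode is *light-activated* at an intensity when a
two-tailed paired *t* test of ON vs spontaneous counts over the 20
repetitions gives *p* < 0.01 and *t* > 2, and is included in the analysis
when activated at ≥ 3 of the 5 photopic intensities.  The per-electrode
light response is the Michelson-style **response ratio**

    RR = (r_ON − r_spont) / (r_ON + r_spont)  ∈ [−1, 1],

with rates r = mean window count / 0.35 s; groups are compared per intensity
with a two-sided Wilcoxon rank-sum test (exact for ≤ 25 electrodes per
group, tie-corrected normal approximation otherwise).

**Cone-survival kinetics** (`retinakit.kinetics`).  Cone densities
(cones/100 µm of outer nuclear layer at eccentricities ±10°, ±80°) are
averaged per arm and age and fitted with an exponential decay parametrised
log2-linearly, log₂ N(t) = a − b·t, by ordinary least squares.  The
*extinction day* is the extrapolated crossing of a density threshold θ
(default 1 cone/100 µm): x = (a − log₂ θ)/b; the separation of the two
arms' extinction days measures how much degeneration is delayed.  Treatment
effects on per-animal log₂ survival ratios are quantified by Hedges' *g*
against a shared control group with BCa bootstrap confidence intervals
(5000 resamples) and unpaired two-sided permutation-*t* p values.

**Expression statistics** (`retinakit.degstats`).  Counts-per-million
normalisation, the expression filter (cpm > 1 in ≥ 2 samples of at least
one group), a two-tailed permutation-FDR Student's *t* test (FDR < 0.05,
250 randomizations) on log₂(cpm + 1), and ΔΔCT qPCR fold changes
(2^(−ΔΔCT) against a housekeeping reference).

**Synthetic data** (`retinakit.synth`).  Seeded generators for every input:
flash protocols, Poisson trial counts, full voltage traces with biphasic
spike waveforms in Gaussian noise (ground-truth timestamps returned),
log2-linear survival tables with lognormal noise, and negative-binomial
count matrices with a spiked, direction-balanced differential fraction.

`retinakit.io` serialises everything as HDF5 (voltage) and TSV/YAML/JSON;
`retinakit.pipeline` chains the stages into a reproducible run with a
manifest of seeds and output digests; the thin `crk` CLI exposes each stage
(`crk synth|mea|kin|deg|run`).

## Worked example

`examples/cone_survival_kinetics.py` simulates a control arm and a
slower-decaying treated arm (6 eyes per age, 10% measurement CV), fits both
decays and estimates stage-wise effect sizes:

```
control : log2 density = 5.503 - 0.05774 * day  (r2 = 0.9996), extinction day ~ 95.3
treated : log2 density = 5.557 - 0.04055 * day  (r2 = 0.9999), extinction day ~ 137.1
separation of the extinction days: 41.7 days

shared-control Hedges' g of log2 survival ratios vs PN26:
  PN30: g = +1.29 [+0.06, +2.95], p_perm = 0.045
  PN37: g = +1.25 [-0.19, +2.58], p_perm = 0.045
  PN45: g = +4.90 [+3.30, +8.00], p_perm = 0.004
  PN60: g = +6.64 [+4.82, +8.74], p_perm = 0.002
  PN90: g = +11.70 [+8.36, +15.22], p_perm = 0.003
```

The fitted lines recover the generating parameters (true slopes 0.0583 and
0.0400 log₂ units/day), the extinction-day separation says the treated
retina keeps cones ~42 days longer, and the growing Hedges' *g* quantifies
the widening of the survival-ratio distributions relative to the shared
early-stage control.  The other scripts in `examples/` walk through the MEA
pipeline on count- and trace-tier data, the permutation-FDR test, and ΔΔCT
fold changes, each printing what its numbers mean.

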