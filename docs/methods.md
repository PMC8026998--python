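# Methods

This note documents the models, estimators and numerical choices behind
retinakit, and what the synthetic-data generators do and do not emulate.

## MEA light-response pipeline

**Filtering.**  The 400–5000 Hz band-pass is a cascade of an order-2
Butterworth high-pass at 400 Hz and an order-2 low-pass at 5000 Hz, so each
skirt rolls off with the stated order; at 50 Hz the magnitude is
1/√(1 + (400/50)⁴) ≈ 0.0156.  The default direction is zero-phase
(forward–backward, doubling the effective order) because threshold-crossing
timestamps should not be delayed by filter group delay; a single-pass
variant is available and is the one the closed-form skirt value applies to.

**Detection.**  Per channel, the threshold is k × SD of that channel's
filtered trace (k = 5).  The default SD is the plain standard deviation of
the whole trace — the literal reading of the procedure — with a
MAD/0.6745 robust variant selectable (`sd_scope="robust"`); the plain SD is
inflated by the spikes themselves at high firing rates, which is a property
of the procedure, not of the implementation.  Default polarity is
`absolute` (either-sign crossings) since extracellular spike polarity
depends on electrode–soma geometry; `negative` is available.  After each
event, crossings within the 1.5 ms dead time are suppressed.  Zero-variance
channels are flagged and emit no spikes rather than raising.

**Windowing.**  ON = [onset, onset + 0.35 s), OFF = [offset,
offset + 0.35 s), spontaneous = the 350 ms immediately *before* onset.  The
spontaneous window length matching the stimulus windows makes the three
counts directly comparable; placements that would overlap a previous OFF
window are rejected with the offending epochs named.

**Activation and inclusion.**  The paired t statistic is computed on the
per-repetition ON − spontaneous differences (df = reps − 1).  Zero-variance
differences with nonzero mean give t = ±∞ (activated iff the mean increase
is positive — a perfectly consistent increase is the strongest possible
response); zero variance and zero mean give t = 0.  Because the signed t
must exceed +2, suppression never counts as ON activation.  Electrodes are
included when ON-activated at ≥ 3 of the 5 photopic intensities; for
protocols with fewer photopic tiers the threshold rescales to
⌈3/5 · n⌉ with a warning.

**Response ratio and comparison.**  Rates are repetition-mean counts /
0.35 s.  0/0 ratios are undefined and dropped from medians (a silent
electrode carries no light information) rather than set to 0.  The
rank-sum comparison uses an exact tie-aware null distribution when both
groups have ≤ 25 electrodes — computed by a shift-algorithm dynamic
programme over doubled midranks, which is the same distribution full subset
enumeration would give — and the tie-corrected normal approximation above
that.  Electrodes are pooled across retinas by default; the retina id is
carried in the tables for stratified reanalysis.

## Survival kinetics

**Model.**  Cone density follows N(t) = 2^(a − b t); the fit is unweighted
ordinary least squares of log₂(mean density per age) on age, matching an
aggregation in which all positions of all animals at a stage are averaged
with equal weight.  A pure exponential never reaches zero, so the
"extinction day" is defined as the crossing of a configurable density
threshold θ, default 1 cone/100 µm (log₂ θ = 0, consistent with the
log2-scaled axis); x = (a − log₂ θ)/b, undefined (flagged, not raised)
when b ≤ 0.  Ages with nonpositive mean density are excluded with a
warning.  SEM at n = 1 is reported as 0 with a warning.

**Effect sizes.**  Hedges' g uses the pooled-SD standardised mean
difference with the small-sample correction J = 1 − 3/(4 df − 1).
Shared-control estimation bootstraps both groups independently with
replacement (default 5000 resamples) and applies the BCa correction with a
delete-one jackknife acceleration estimate, falling back to the percentile
interval when the bias or acceleration term is degenerate.  The permutation
p value permutes group labels of the pooled sample, recomputes the unpaired
equal-variance t, and reports two-sided (b + 1)/(n_perm + 1); the
permutation count defaults to 5000, mirroring the bootstrap depth since no
separate figure is conventional.

## Expression statistics

**Permutation-FDR t test.**  Per gene, an equal-variance two-sample t on
log₂(cpm + 1) (any log-scale matrix is accepted).  The significance cutoff
c is the smallest observed |t| for which

    FDR(c) = mean over permutations of #{null |t| ≥ c} / max(1, #{observed |t| ≥ c})

is ≤ the target (default 0.05).  Null statistics come from distinct label
assignments: when the design is balanced, an assignment and its complement
yield identical |t|, so assignments are canonicalised to the subset
containing the first sample — without this the estimated FDR has a floor of
1/n_assignments and a 3 vs 3 design can never call anything significant.
When the canonical space (e.g. 9 assignments at 3 vs 3) is no larger than
the requested 250 randomizations it is enumerated exhaustively, excluding
the identity; otherwise assignments are sampled without replacement.  No
variance-stabilising S0 constant is added.  Constant genes get t = 0 and
are never significant.

**ΔΔCT.**  ΔCT = CT_target − CT_reference per sample; ΔΔCT is the
difference of group-mean ΔCTs against the control group; fold = 2^(−ΔΔCT).
Per-sample folds (against the control-group mean ΔCT) are also emitted so
group differences can be tested nonparametrically.  Technical duplicates
should be averaged before entry.

## Synthetic data: what it emulates, and what it does not

**Spike counts** are Poisson with mean rate × 0.35 s — the standard
physiological null for windowed spike counts; real RGC counts are often
modestly over-dispersed and temporally correlated (bursting, adaptation),
which the generator deliberately omits.  Passing count-tier tests therefore
demonstrates correctness of the statistics under Poisson firing, not
robustness to bursty firing.  **Traces** render an inhomogeneous Poisson
train (rate stepping at flash boundaries after an optional latency) as a
fixed biphasic waveform in white Gaussian noise.  The minimum inter-spike
interval defaults to max(template duration, 1.5 ms) so that every generated
spike is separable by the detector's dead time — with a shorter refractory
period a fraction of true spikes is unrecoverable by construction.  No
electrode crosstalk, drift, line noise or spike-amplitude variability is
simulated.

**Survival tables** multiply the deterministic 2^(a − b·age) curve by
LogNormal(0, σ) noise with σ chosen so the coefficient of variation equals
`noise_cv` (default condition 0.1); on the log2 scale this is additive
Gaussian noise with mean zero — exactly the error model the OLS fit
assumes.  All retinal positions share one expectation; the real
centre-to-periphery gradient of cone loss is not modelled (positional
gradients would be a config extension).

**Count matrices** are gamma–Poisson (negative binomial) with lognormal
gene means around exp(mean_log_mu), default dispersion 0.01 — a biological
CV of ~0.1, the conventional figure for genetically identical model
organisms.  A deterministic round(frac_de · n_genes) subset of genes is
spiked 2^±effect in group 2.  Spike directions are assigned greedily so the
spiked library mass is conserved (`de_direction="balanced"`): on the closed
counts-per-million scale a one-directional spike would shift *every*
unspiked gene and make truth-labelled FDR evaluation ill-posed unless a
composition-aware normalisation (TMM-like, deliberately out of scope here)
is run upstream.  `de_direction="single"` restores the one-directional
behaviour for users who do run such normalisation.

**Seeding.**  Every generator is a pure function of (parameters, seed).
Per-channel, per-gene and per-arm substreams are spawned from the top-level
seed by index, so channel k's data is identical whether 5 or 500 channels
are requested.

## Problem sizes and tolerances in the test suite

Statistical tests run at sizes chosen to keep the full suite fast while
leaving comfortable margins: 200 electrodes for median-response-ratio
recovery; 6000 null electrodes for the activation type-I bound (≤ 0.012 per
intensity; the 3-of-5 inclusion probability follows from the binomial tail
≤ 1e−4); 1000 simulations at n = 20 per group with 1000 bootstrap resamples
for the 93–97% CI-coverage band (the analysis default remains 5000
resamples); 2000-gene matrices over several seeds for FDR calibration.
Monte-Carlo assertions use fixed seeds and tolerances stated in each test
(typically 3 standard errors, or the 10% band appropriate to a stochastic
simulation quantity).

## Known limitations

- Electrode-level analysis only; no spike sorting into units.
- The intensity→rate mapping is supplied explicitly per intensity (a
  saturating Naka–Rushton-style helper exists but nothing fits one), so
  intensity-response curves are descriptive, not mechanistic.
- The decay model is a single exponential per arm; biphasic or plateauing
  degeneration would need a different model and makes the extrapolated
  extinction day an optimistic summary.
- The permutation-FDR test at 3 vs 3 rests on 9 distinct assignments; its
  FDR estimate is correspondingly coarse, and results at such sizes should
  be read as screening, not inference.
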