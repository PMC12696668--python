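# Methods

This note documents the models, rules and numerical choices behind
`tusmep`, and what the synthetic-data generator does and does not emulate.

## Study design being modelled

Two sessions (verum 5 Hz-rTUS vs sham, counterbalanced order), MEP measures
at Baseline, T5, T30 and T60 minutes post-sonication. Each measurement
block acquires 25 trials per measure: single-pulse MEPs at the SI_1mV
intensity, and a paired-pulse block interleaving test-stimulus-alone (TS),
SICI (2 ms interstimulus interval, conditioning at 80% resting motor
threshold) and ICF (10 ms ISI) trials. EMG is recorded at 5000 Hz from
three right-hand muscles (FDI primary, APB and ADM adjacent).

## Synthetic EMG cohort

Trial amplitudes are log-normal — the standard model for right-skewed MEP
amplitude distributions:

```
log A = mu + u_p + v_pc + w_pct + log m(measure) + log e_ct + eps
```

with participant intercepts `u_p ~ N(0, 0.30²)`, participant × condition
effects `v_pc ~ N(0, 0.12²)` (the random "condition slope"), block effects
`w_pct ~ N(0, 0.10²)` (participant × condition × timepoint), and trial
noise `eps ~ N(0, 0.45²)`. Measure multipliers are 1 for single/TS, 0.45
for SICI and 1.30 for ICF; the condition multiplier `e_ct` applies to verum
blocks per timepoint (all 1.0 by default — a true null). With
`mu = log-scale −0.10` these defaults put the grand-mean baseline
single-pulse amplitude at ≈ 1.05 mV (target band 1.0–1.1 mV) and the
SICI/ICF ratios at ≈ 0.45/1.30. The between-participant and block
variances are design choices (no variance components are available to fit
them against); they were picked once as typical for hand-muscle MEP data
and produce a realistic repeated-measures correlation.

The `original-study` preset sets the verum multiplier to 1.4 at T5 and T30
and 1.2 at T60, emulating an excitatory after-effect that outlasts
sonication by ~30 min with partial decay at one hour.

Waveforms (optional) are band-limited (20–450 Hz) unit-RMS noise scaled to
the trial's pre-stimulus RMS, plus a biphasic Gaussian-windowed deflection
with onset 22 ms post-stimulus whose peak-to-peak amplitude equals the
drawn amplitude. Only the peak-to-peak amplitude and the pre-stimulus
window feed the analysis, so no attempt is made to model MEP morphology,
latency jitter or motor-unit physiology. Every trial has 120 ms of
pre-stimulus data (the cleaning rules need 100 ms).

Artefact injection (mutually exclusive per trial, hidden ground-truth
columns):

* amplitude outliers (rate 0.016): the block-typical amplitude times
  U(4, 8) — an electrode/stimulator artefact, deliberately generated as a
  multiple of the block level rather than of the trial's own draw so that
  injected outliers are recoverable in principle;
* pre-contraction (rate 0.018): pre-stimulus RMS multiplied by
  15 × U(0.8, 1.5), i.e. ≈ 0.10–0.18 mV against a 0.008 mV resting floor —
  the level of overt voluntary pre-activation. The trace relaxes back to
  the resting floor after the stimulus;
* broadband noise (rate 0.0055): 0.18 mV RMS contamination across the whole
  sweep, swamping the response-to-background ratio.

The default rates are the exclusion percentages observed in this study
design at scale (≈1.6% / 1.8% / 0.55%).

## Cleaning rules

Within each block the rules are applied in a fixed order with disjoint
attribution (Grubbs → pre-contraction → noise); a trial is excluded if any
rule fired on the muscle channel in question.

* **Grubbs**: iterative, two-sided, α = 0.05, on raw (untransformed)
  amplitudes, per participant × condition × timepoint × muscle × pulse
  type. The critical value is the classical t-based form; iteration removes
  the most extreme value and repeats. A zero-variance block yields no
  outliers. On clean log-normal data the iterated test flags ~3% of trials
  — more than its nominal one-shot level, as expected for a normal-theory
  test applied to skewed data.
* **Pre-contraction**: pre-stimulus RMS > block mean + 2 SD, statistics
  computed once over all trials in the block (candidate included,
  non-iterative, n−1 denominator), per acquisition block (single-pulse
  block vs interleaved paired-pulse block) and muscle channel.
* **Noise**: a deterministic surrogate for manual inspection — flagged iff
  pre-stimulus RMS > 0.045 mV *and* MEP peak-to-peak < 2 × the pre-window
  peak-to-peak. Reproducibility requires removing the human step; both
  thresholds are exposed in `CleaningRules`. Injected broadband-noise
  trials usually also trip the pre-contraction rule, which fires first, so
  at default rates most of their exclusions are attributed there; the union
  of flags still removes ≥ 90% of them.

Cleaning never drops rows — flags are recomputed from the full table, so
re-running the cleaner is idempotent by construction, and Grubbs is at a
fixed point after flagged trials are removed.

The MEP search window is 15–60 ms post-stimulus (configurable): it brackets
hand-muscle MEP latencies and the generator's 22 ms onset.

## Summaries

Paired-pulse amplitudes are expressed as a ratio to the mean TS amplitude
of the same block; post-timepoint values as a ratio to the baseline mean
within participant × condition × muscle. Empty measures after cleaning
produce NaN (explicit missing), never silent zeros.

## Trial-level mixed model

Square-root-transformed trial amplitudes are modelled with fixed effects
Condition × Timepoint (sum-to-zero contrasts, so each Wald F is the Type
III test) and by-participant random effects. The fully maximal structure
(all slopes and interactions, correlated) is not estimable in a
two-condition, four-timepoint within-subject design with 15 participants,
so the ladder of structures is, from richest to simplest:

1. correlated intercept + condition + timepoint slopes **plus** an iid
   condition × timepoint cell effect (variance component) — the tractable
   analogue of the maximal structure, and the default;
2. intercept + condition slope + cell effect;
3. intercept + condition slope;
4. intercept only.

`random_structure="auto"` walks the ladder on non-convergence or a
boundary (singular) random-effects covariance; the structure actually used
is recorded in the result. The cell variance component matters: without
it, block-level variability in the generator inflates the interaction
type-I error to ~20%; with it the error is at the nominal level.

Denominator degrees of freedom:

* `satterthwaite` (default for reports): computed in-package from the REML
  log-likelihood curvature. The variance parameters are packed as the
  log-Cholesky factor of the random-effects covariance plus log variance
  components and log residual variance; the observed information is a
  central-difference Hessian, the contrast-variance gradient a central
  difference, and multi-df terms are pooled with the eigendecomposition
  recipe used by lmerTest. Against lmerTest on seeded fixtures the F, df
  and p values agree to ~3 decimals. If the fit sits on a variance
  boundary the computation falls back to the between-within df with a
  flag.
* `between-within`: denominator df = participants − 1 for every term —
  the convention behind printed F(1,14)-style statistics, and the
  package's choice for Monte-Carlo studies (hundreds of fits) where the
  Satterthwaite numerics would dominate runtime.

Estimated marginal means per condition are balanced averages over the
factorial cells on the model (square-root) scale, with delta-method
standard errors; squaring their ratio recovers an injected multiplicative
amplitude effect (verified to ±10% in simulation).

## Repeated-measures ANOVA

The replication analysis runs a two-way (Condition × Timepoint) fully
within-subject ANOVA on raw participant-level means via pingouin, reporting
uncorrected and Greenhouse–Geisser-corrected dfs and p-values plus partial
eta squared. A brute-force sums-of-squares oracle in the test suite pins
the F statistics.

## Power analysis

`rm_anova_power` implements the G*Power noncentral-F formulations for
repeated-measures designs with g groups, m measurements, repeated-measures
correlation ρ and nonsphericity ε:

* between factors: λ = f²·N·m/(1 + (m−1)ρ), df = (g−1, N−g);
* within factor: λ = f²·N·m·ε/(1−ρ), df = ((m−1)ε, (N−g)(m−1)ε);
* interaction: as within but df₁ = (g−1)(m−1)ε.

`required_sample_size` steps N by g (balanced groups) until the target
power is reached. For the design parameters used to plan this kind of
study (η²p = 0.602 → f = 1.2299, α = 0.05, power 0.8, g = 2, m = 4,
ρ = 0.5, ε = 1), only the **between-factors** family reproduces the
recommendation N = 6 (power 0.81 at N = 6, 0.41 at N = 4); the within and
interaction families are already over 0.8 at N = 4. The family is a config
switch with `between` as default.

## Synthetic acoustic fields and targeting metrics

World coordinates are RAS+ millimetres (+x right, +y anterior,
+z superior); for a left-hemisphere target (x < 0) "medial" is +x. The
default target (omega/hand-knob landmark) is (−38, −22, 54) with the scalp
30 mm above it and the gyral lip at 18 mm depth; the brain mask is the
half-space 8 mm below the scalp (a scalp+skull offset), and the M1 ROI is
a 15 mm sphere centred midway between omega and lip so it covers both
landmarks.

The field is a separable Gaussian ellipsoid in *intensity* with FWHM
(6, 6, 30) mm — lateral × lateral × axial, typical for a 500 kHz
single-focus transducer — not a solved wave field: every targeting metric
depends only on intensity geometry. The peak sits at the target plus a
placement bias of (medial 9.5, anterior 10.5, superior 0) mm and per-axis
jitter SD (5, 14.2, 7) mm, snapped to the nearest voxel centre (so the
stored maximum is exact) and clipped half a FWHM inside the 101³, 1 mm
grid and below the brain surface (<1% of draws at default SD). The
anterior axis reproduces the well-known anterior displacement of the TMS
motor hotspot (≈ 10.5 ± 14.2 mm); the medial bias and SDs were chosen so
the implied one-sample t on the medial axis is strongly significant and
the mean Euclidean peak-to-omega distance falls near 20 mm (15–27 mm
acceptance band). The in-brain peak intensity is drawn from
N(1.20, 0.43²) W/cm² truncated at 0.05, and the stored volume is pressure
(Pa) via the inverse plane-wave relation, so converting it back with the
dosimetry module returns the configured peak exactly.

The FWHM focus is purely threshold-based (≥ half the in-brain maximum,
voxels exactly at half-max included; no connected-component filtering) and
restricted to the brain mask so the overlap percentage is interpretable.
Peak ties break at the lowest linear voxel index. Note a voxelization
caveat: when the half-max surface passes exactly through lattice points
(an isotropic 6 mm FWHM on a 1 mm grid aligned to a voxel centre), the
voxel count is floating-point-sensitive; the default elongated focus does
not suffer from this and matches the analytic (π/6)·FWHMx·FWHMy·FWHMz
volume to well under 5%.

## Dosimetry conventions

Intensities cross module boundaries in W/cm², pressures in Pa (MPa only
inside the MI); the 10⁴ W/m²→W/cm² factor lives in one place. The peak
negative pressure for the MI is the plane-wave inversion of the in-situ
Isppa (for 1.20 W/cm² at 500 kHz: p = 0.190 MPa, MI = 0.268). Pulse counts
use round(PTD/PRI) to guard float representation of exact ratios. Thermal
modelling and transducer power calibration are out of scope.

## Monte-Carlo problem sizes

The stochastic suites use a single-muscle cohort on the amplitude fast
path (no waveform synthesis — the generator writes the same measured
quantities the waveform path would produce) with the `condition+cell`
random structure and between-within dfs: 200 replicates each for the
type-I error band ([0.02, 0.08] at α = 0.05) and the ≥80% detection of the
facilitation preset, 100 seeds for the baseline calibration means and 50
for filter-recovery and effect-recovery checks. These sizes give the
acceptance bands comfortable Monte-Carlo margins while keeping the suite
in minutes.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* the analysis assumes:
log-normal amplitudes with participant/condition/block structure,
calibrated baseline means and paired-pulse ratios, artefact trials the
filters can recover, and acoustic foci with realistic placement
dispersion. It does not emulate EMG morphology, electrode or stimulator
drift, skull-specific attenuation, non-Gaussian focus shapes from skull
refraction, or any dependence of MEP amplitude on actual acoustic dose.
Passing tests therefore demonstrate that the pipeline's rules, statistics
and geometry are implemented correctly and are calibrated under the
assumed generative model — not that the model captures every property of
real participant data.

## Known limitations

* Satterthwaite dfs rely on numerical differentiation; very flat or
  boundary likelihoods trigger the between-within fallback.
* The pre-contraction rule's literal form (block statistics including
  contaminated trials) loses sensitivity when a block contains several
  large artefacts; the generator's default rates keep this regime rare.
* The noise rule is a deterministic surrogate for human inspection and
  makes no attempt to mimic idiosyncratic rater decisions.
* Focus masks are computed on the generation grid; no resampling or
  standard-space registration is performed (synthetic cohorts share one
  grid by construction).
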