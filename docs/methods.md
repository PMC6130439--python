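# Methods

## The quantity under study

The analysis summarises, per resting-state scan, the anticorrelation
between the default-mode network (DMN) and the task-positive systems
(cingulo-opercular, salience, dorsal attention, ventral attention,
fronto-parietal) as one number: the arithmetic mean of Fisher-z
connectivity over a fixed set of reliably anticorrelated DMN-to-
task-positive edges, the *averaged negative-connectivity metric*. All
group-level statistics operate on this metric (and, edgewise, on its
constituent edges) on the z scale, where sampling variance is
approximately stabilised.

## Motion processing

Framewise displacement is the L1 sum of backward differences of the six
rigid-body realignment parameters, with the three rotations converted to
millimetres of arc on a 50 mm sphere (configurable radius). The first
frame is assigned FD = 0. Censoring drops frames whose FD *exceeds* the
threshold (default 0.2 mm) — the inequality is strict, so a frame at
exactly 0.2 mm survives. A scan is eligible only if strictly more than
the target duration (default 4 min) of clean data remains; eligible
scans then contribute exactly `ceil(240 s / TR)` frames sampled uniformly
without replacement, so every scan enters the correlation step with the
same amount of data. Censored frames are dropped and survivors
concatenated; no interpolation is attempted, since correlation over
retained samples is the standard scrubbing contract. TR is always an
explicit input — the package never assumes one.

A secondary, scan-level QC guards against residual motion artifact in
the metric itself: if mean FD correlates with the metric across scans,
scans are removed one at a time — each step removing the scan whose
leave-one-out deletion most shrinks the absolute Pearson correlation —
until the association is non-significant (default α = 0.05) or a removal
cap is reached. The stopping rule is a package design choice (published
pipelines state the outcome of such filters, not an algorithm);
both α and the cap are prominently configurable, and the procedure
refuses cohorts under 10 scans.

## Connectivity and the edge mask

Per scan, Pearson correlations between all ROI pairs over the retained
frames are Fisher transformed, z = atanh(r); the diagonal is undefined
and stored as NaN, constant ROIs yield flagged-undefined entries, and
|r| = 1 is capped at 1 − 1e−7 (z ≈ 8.4) with a warning — on real-scale
data this essentially never fires.

Not every DMN/task-positive pair is anticorrelated, so the analysis mask
is defined on an independent reference cohort: candidate edges (every
DMN ROI × every task-positive ROI; optionally × every non-DMN ROI) are
averaged across reference scans *on the z scale*, converted back by
tanh, and retained below a correlation cut (−0.35 main, −0.3 / −0.375
sensitivity) or as the `ceil(fraction · n_candidates)` most negative
(density rule, boundary ties broken lexicographically by (i, j) so the
mask is deterministic). Averaging in z and thresholding in r keeps the
variance-stabilised convention while letting the familiar r cuts apply
directly; averaging in r instead would shift borderline edges slightly,
which is why both the threshold value and the rule are first-class
configuration. The packaged 333-region network table reproduces the
community sizes of the standard 333-parcel cortical scheme (41 DMN, 123
task-positive regions → 5,043 candidate edges; 250 retained ≈ 5%
density); its per-ROI ordering is schematic (it is a synthetic stand-in,
flagged in the filename) and any user table with `roi_id`/`network`
columns substitutes for it.

Region importance is the per-ROI incidence count of mask edges — the
tabular equivalent of the usual cortical-surface rendering.

## Mixed-effects inference

Scans are nested in subjects, so all models include a subject-level
random intercept and are fit by maximum likelihood (statsmodels
`MixedLM`). ML rather than REML because AIC comparisons across
fixed-effect structures require comparable likelihoods. The three
standard structures are

- Model 1: `group + age + sex + meanFD` (7 parameters counting the two
  variance components),
- Model 2: Model 1 + group×age (8),
- Model 3: Model 1 + all two- and three-way interactions of group, age,
  sex (11).

Age is mean-centered before interaction models; this changes only the
interpretation of lower-order terms, never the tests of highest-order
terms. Mean FD is always carried as a nuisance covariate by default.
A random-intercept variance estimated at the zero boundary is flagged
`singular` and the fit is returned (fixed effects remain valid; with one
scan per subject they reduce exactly to OLS, a property the tests
exploit as an oracle). Rank-deficient designs are rejected with the
aliased terms named. The optimizer falls back through
BFGS → L-BFGS → Powell → CG because boundary solutions can leave one
method's Hessian singular.

Denominator degrees of freedom use the between-within (containment)
convention: terms constant within subject (group, sex, their products)
are tested against subject-level df, terms varying within subject (age,
FD) against observation-level df. This is a deliberate, simpler stand-in
for Satterthwaite approximation; at the cohort sizes this package
targets (hundreds of scans) the two are numerically indistinguishable,
and implementing Satterthwaite faithfully would require the variance-
component Hessian that the backend does not expose.

Edgewise analyses refit Model 1 per mask edge; Benjamini–Hochberg
step-up q-values are computed per term *across edges*, never pooled
across terms. Failed single-edge fits are recorded and skipped rather
than failing the batch. Region-level "summed-t" maps add each
significant (uncorrected p < 0.05) edge t of the requested sign to both
endpoint ROIs.

The sex-balanced permutation keeps the reference group intact, draws a
fixed number of male and female scans from the other group (defaulting
to the reference group's own sex counts, clamped to availability),
refits, and averages the per-term p-value distribution over iterations
(10,000 nominal; tests and the reproduction script use 500 and fewer,
which agrees with the long run to Monte-Carlo accuracy). With the full
sample selected and one iteration it reduces exactly to the direct fit.

## CPT scoring

The identical-pairs CPT presents 300 trials: 20% targets, 20% "catch"
near-miss nontargets (hard), 60% "stim" nontargets (easy). Sensitivity
is the equal-variance signal-detection index d′ = Φ⁻¹(H) − Φ⁻¹(F),
computed against stim false alarms (easy) and catch false alarms
(difficult). Degenerate rates (0 or 1) would give infinite quantiles;
the default correction replaces only such rates by (k + ½)/(n + 1)
(half-count), with log-linear and clamping alternatives available and
tagged in the result, since published practice varies and results near
ceiling are sensitive to the choice. The simulator's observer responds
with hit probability Φ(d′/2 − c) and false-alarm probability
Φ(−d′/2 − c); scoring expected counts recovers d′ exactly as counts grow.

## The synthetic cohort

The generator emulates the statistical structure the inference assumes,
not the physics of BOLD. Per scan *s* of subject *i*,

    ζ_s = z0 + δ_group·[ADHD] + δ_sex·[F] + β_age·(age − 10) + u_i + ε_s,
    u_i ~ N(0, τ²),  ε_s ~ N(0, σ_scan²),  ρ_s = tanh(ζ_s),

and each frame draws a bivariate standard normal (DMN factor,
task-positive factor) with correlation ρ_s plus an independent factor
for remaining ROIs; ROI signal = λ·(own-network factor) + N(0, σ_roi²).
Injecting the anticorrelation at the factor level gives every
between-network edge the same closed-form expectation
E[r] = ρ_s·λ²/(λ² + σ_roi²) — the oracle the connectivity tests check by
Monte Carlo — and mirrors the averaged-metric logic of the analysis.

Defaults describe the developmental cohort the package targets: 150
children per group, baseline ages uniform on 7–11 years, follow-up scans
with probability 0.30 (and 0.10 for a third, given a second) lagged
1.5 ± 0.2 years (clipped to [1, 2] so ages stay within 7–15), males 50%
of controls and 70% of the ADHD group. Latent-scale defaults: z0 = −0.60
(so the expected metric sits near −0.28 under λ = σ_roi = 1, matching
the magnitude such cohorts print), δ_group = +0.06 (ADHD shifted toward
zero; ≈ +0.023 on the metric scale after attenuation), δ_sex = −0.05,
β_age = −0.01/yr, τ = 0.08, σ_scan = 0.05. Motion: exponential per-frame
displacement (mean 0.10 mm) with 5%-rate spikes (mean 0.5 mm) split
randomly across the six parameters; spike frames add a global artifact
(gain × spike size) to all ROIs — exactly the FD-correlated global
signal that scrubbing exists to remove. Behavior: true
d′ = a + b·(−E[metric]) + N(0, 0.8²) per condition, with a_easy = 1.97,
a_difficult = 0.56, b = 2.8 and criterion c = 0, placing control/ADHD
means near the 2.8/2.2 (easy) and 1.3/1.0 (difficult) range typical of
this task. The config validates that
|z0| + |δ|'s + 3(τ + σ_scan) keeps |ρ| < 0.999.

A records-only fast path (`emit_timeseries=False`) draws the analysis
rows directly from the same latent model: the metric is its expectation
atanh(ρ_s·λ²/(λ²+σ²)) plus N(0, 0.02²) measurement noise standing in for
finite-frame, finite-edge estimation error, mean FD is drawn
independently (0.2·Beta(6,4), mean ≈ 0.12 mm — independent because the
generator models a cohort that *passes* motion QC), and d′ is scored
from binomially drawn trial counts. The large simulation studies (20-
seed power, 200-replicate type-I calibration) use this path; the full
time-series path is validated separately against the closed-form oracle.
All randomness fans out from a single seed through named substreams, so
identical configs are bit-identical.

What passing tests on this generator do **not** show: robustness to
hemodynamic autocorrelation (frames are i.i.d. here, so real effective
sample sizes are smaller), spatially structured or physiological noise,
distance-dependent motion artifact, missing-not-at-random dropout, or
diagnostic heterogeneity. They do show that the estimation chain is
unbiased and calibrated when its own assumptions hold, and that every
deterministic transformation (FD, censoring, masking, averaging,
scoring, FDR) is exact.

## Numerical choices and degenerate inputs

- Fisher cap |r| ≤ 1 − 1e−7; capped edges warn.
- Density-rule boundary ties break lexicographically by (i, j).
- Strict inequalities: FD censoring ("exceeding"), clean-data
  eligibility ("greater than").
- Half-count d′ correction applies only to rates exactly 0 or 1.
- AIC = −2ℓ + 2k with k = fixed effects + 2 variance components; ties in
  model selection return the first candidate and are reported.
- Empty masks, infeasible permutation draws, sub-10-scan QC cohorts,
  frame-count mismatches and duplicate (subject, wave) keys all raise
  typed errors naming the offender.

## Known limitations

The secondary-QC stopping rule and the containment df are documented
approximations (see above). The packaged network table reproduces
community sizes, not true region geometry, so region-level outputs on it
are schematic. The permutation averages p-values (following the field's
practice for this design) rather than building an exact permutation null
of the statistic; it balances the measured sex distribution only. The
brain–behavior repeated-measures model shares one residual variance
across difficulty conditions.
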