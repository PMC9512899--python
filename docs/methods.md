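# Methods

## The model

A patient's ALSFRS-R total (0–48) is modelled as a logistic decline in
months since symptom onset,

    F(t) = 48 / (1 + exp((t − D50) / dx)),

with two free parameters: D50, the months to 50% functionality loss, and
dx, the decline scale.  The curve approaches 48 asymptotically before
onset and 0 in late disease; F(D50) = 24 exactly, which is the model's
defining anchor and is asserted as an invariant in the test suite.  The
parameterization was chosen as the unique two-parameter logistic
satisfying the model's two stated anchors — full health as the upper
asymptote and half functionality at D50 — with dx as the time scale of
decline.  No onset constraint F(0) = 48 is imposed: forcing it would bias
D50 upward in aggressive patients, where a perfect-health anchor at t = 0
is least believable.  Fits with F(0) < 46 trigger a `PreOnsetLossWarning`
instead.

The relative scale rD50 = t / (2·D50) is the linear rescaling with rD50 = 0
at onset and rD50 = 0.5 at D50; it is not bounded above.  Phase boundaries
(0.25, 0.5) and aggressiveness boundaries (20, 40 months) are half-open on
the left, so a value sitting exactly on a boundary belongs to the later
phase / less aggressive tier.

## Estimation

Bounded nonlinear least squares (scipy's trust-region reflective), with
D50 ∈ [0.1, 300] months, dx ∈ [0.1, 100] months, and tolerances of 1e-12
on cost, step and gradient.  Two deterministic starting points are tried
and the lower-RSS solution kept:

1. D50 at the linear-interpolation crossing of 24 points (last observation
   time if the trajectory never crosses), dx = max(D50/4, 1);
2. a logit-linear start from regressing ln(48/y − 1) on t over interior
   scores, which linearizes the sigmoid exactly and is a strong start
   whenever at least two scores are off the ceiling/floor.

The procedure is deterministic, invariant to the input ordering of
observations, and equivariant under rescaling of the time axis.  Its
global optimality is audited in the tests against a brute-force grid
search (D50 0.5–120 × dx 0.5–30 at 0.05 steps) on randomly generated noisy
instances.

Degenerate inputs: fewer than two observations raise
`InsufficientDataError` (two assessments are the stated minimum for valid
modelling); a trajectory entirely at 48 carries no decline signal and
raises `IllPosedFitError` by default (optionally returning a flagged,
non-converged result pinned at the D50 bound); two-observation fits are
allowed but marked `low_information` — they interpolate exactly and carry
no redundancy.  Optimizer non-convergence is always surfaced in the
`converged` flag.  Standard errors come from the Gauss–Newton covariance
rss/(n−2)·(JᵀJ)⁻¹ and are reported as NaN when not estimable.

## Measurement processing

MUSIX (µV) = CMAP (mV) × 1000 / MUNIX; the conversion factor is exactly
1000.  The guideline floor replaces any record with CMAP < 0.5 mV, MUNIX
absent, or MUNIX < 2 by the full fixed triple (0.5 mV, 2, 250 µV) and
flags it `imputed`; the rule is idempotent and never alters passing
records.  MUNIX values in (0, 2) are floored together with their CMAP and
MUSIX — the triple is always set as a unit, so the MUSIX identity holds on
every non-imputed record and imputed records are exactly the fixed triple.

Per patient and muscle, analysis uses the first (earliest) measurement on
the less affected side.  "Less affected" is a clinical designation; when
an explicit per-patient side column is provided it wins, otherwise the
side with the higher CMAP at the first visit serves as a proxy so that
purely tabular cohorts remain analyzable.

## Statistics

All group comparisons are nonparametric: Kruskal–Wallis omnibus (tie
corrected) followed by Dunn's rank-based pairwise z tests with Bonferroni
multiplication over the pairwise family (3 tests for 3 strata, applied
within each muscle × variable family, not across muscles).  Dunn's test is
the post-hoc conventionally attached to a Kruskal–Wallis omnibus in
clinical statistics packages; pairwise Mann–Whitney is available as an
alternative (`posthoc="mannwhitney"`).  Adjusted p-values are
min(1, raw × k).  Medians and IQRs use linearly interpolated (type-7)
quantiles — note that some commercial packages default to a slightly
different quantile rule.  Significance is α = 0.05 throughout.

Categorical homogeneity uses Pearson chi-square when all expected counts
are ≥ 5 and the Fisher–Freeman–Halton exact test otherwise.  The exact
p-value is the total multivariate-hypergeometric probability of all
margin-fixed tables no more probable than the observed one; it is computed
by full enumeration when the table space is small (≤ 5×10⁵ tables by a
cheap upper bound) and otherwise by Monte Carlo over 10⁵ Patefield-sampled
tables with fixed seed 20220926, reporting the simulation standard error.
The path taken is always recorded in the result.  On 2×2 tables the exact
path reduces to the classical Fisher exact test, which is asserted against
scipy's hypergeometric implementation.

The Shapiro–Wilk gate documents why the nonparametric branch is taken
(clinical electrophysiology and D50 parameters are left-skewed); it does
not switch the pipeline to parametric tests.

## The synthetic cohort generator

The generator encodes the structural claim under test — MUNIX tracks
disease accumulation, not aggressiveness — as a data-generating process,
and is calibrated so its observable summaries land near the cohort values
the model was developed on:

* D50 ~ LogNormal(ln 29.2, 0.682): median 29.2 months, IQR ≈ 18.5–46.4.
* dx = 0.2·D50·exp(ε), ε ~ N(0, 0.17): squared dx–D50 correlation ≈ 0.93.
* rD50 at the electrophysiology visit ~ LogNormal(ln 0.27, 0.615), drawn
  independently of D50 (median 0.27, IQR ≈ 0.19–0.41); the visit time is
  then t = 2·D50·rD50.
* ALSFRS-R visits start at a uniform rD50 in [0.05, 0.45] and repeat every
  3 months; the visit count is 2 + Poisson(4) (configurable minimum),
  approximating routine-care schedules of 5–7 assessments.  Scores are the
  sigmoid plus N(0, 2) noise, rounded and clipped to [0, 48] — always
  integers.
* Per-muscle MUNIX declines as a delayed exponential in rD50,
  M_m(r) = M0_m · exp(−λ_m · max(0, r − δ_m)), with log-normal noise
  (σ = 0.9); baselines M0 are healthy-control medians (APB 158.7, ADM
  147.8, TA 132.6) and rates (APB λ=3.9 δ=0, ADM λ=2.6 δ=0.02, TA λ=2.4
  δ=0) were solved once from phase-stratified cohort medians.  λ_APB >
  λ_ADM with δ_APB < δ_ADM encodes the split-hand gradient: the thenar APB
  is hit earlier and harder than the hypothenar ADM.
* MUSIX trends upward with accumulation (reinnervation),
  S_m(r) = S0_m · exp(η_m · r), and CMAP is derived as MUNIX·MUSIX/1000,
  so the three quantities stay mutually consistent by construction.
* A "severe regional involvement" mixture — probability
  p_m·(1 + 3·rD50) with base p ∈ {0.10 APB, 0.06 ADM, 0.12 TA} and a
  ten-fold decline-rate multiplier — produces the floor drop-outs observed
  even in early phases, which pure log-normal noise around the median
  curve cannot; drop-out fractions are then monotone over phases for every
  muscle, steepest for APB.
* Both sides are generated; the more affected side carries an extra
  uniform(0.3, 1) MUNIX deficit.  Controls draw stationary values at the
  baselines; mimics draw a uniform(0.15, 0.9) severity fraction of
  baseline, unconnected to any D50 — intermediate lower-motor-neuron loss
  without a progression model.

Because MUNIX is a function of rD50 (plus muscle-local noise) and rD50 is
drawn independently of D50, MUNIX is conditionally independent of
aggressiveness given accumulation *by construction*; the tests audit this
with a partial correlation and with the rejection rates of the two
stratified comparisons (power > 0.9 over phases, ≈ 5% over tiers).

What the generator does **not** emulate: demographic confounding (age and
sex affect real MUNIX and are generated but unlinked), item-level ALSFRS-R
structure, calendar-time visit irregularity, repeated electrophysiology
visits, measurement-side clinical designations beyond the CMAP proxy, and
any survival process.  Passing tests therefore validate the pipeline's
logic and calibration, not clinical performance on real cohorts.

## Problem sizes

The validation studies use the sizes at which their conclusions are
stable: parameter recovery on 200 patients at noise sd 2 with at least 5
visits (median relative D50 error ≈ 3%, well under the 10% gate; mean bias
is dominated by slow-progressing patients observed only on their early
plateau, for which D50 is weakly identified — the median is the honest
location summary); the accumulation-vs-aggressiveness contrast on 500
replicate cohorts of 237 patients; grid-search audits on 20 random
instances; calibration checks on 10,000 parameter draws and one default
cohort.

## Known limitations

* The decline-scale parameterization of dx follows this package's logistic
  form; other implementations of D50-style models may normalize dx
  differently, so dx values are comparable within-package only.
* Two-observation fits interpolate exactly; their D50 is as fragile as the
  two scores behind it.  Treat `low_information` fits accordingly.
* D50 for patients whose observations all precede appreciable decline is
  bounded only by the optimizer box (300 months); such fits inflate
  mean-based recovery summaries.
* The Fisher–Freeman–Halton Monte-Carlo path has p-value resolution of
  about 1/√N tables; the reported `mc_se` quantifies it.
* `dropout_rate` reports per-stratum fractions without uncertainty;
  comparing them formally requires the categorical tests.
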