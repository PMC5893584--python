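# Methods

This note documents the statistical models implemented in `uromet`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Data model and preprocessing

A study is one wide table: one row per injection, reserved metadata
columns (sample, subject, intervention ∈ {vehicle, alcohol}, hour ∈
{0..4}, role ∈ {experimental, qc, repeat}, batch, injection order,
creatinine in mmol/L) followed by one column per metabolite.  Raw
concentrations are μmol/L; dividing by the sample's creatinine yields
μmol/mmol Cr, the dilution-corrected scale on which all statistics are
computed.  The table carries a forward-only transform state
(raw → imputed → log → scaled) so stages cannot be applied out of order,
and preprocessing is row-permutation-equivariant.

**Zero treatment.** GC–MS non-detects arrive as exact zeros.  Each zero
is replaced by half the smallest positive value of that metabolite over
the experimental samples — the common metabolomics half-minimum
convention, chosen because it keeps the subsequent log transform defined
while staying below the detection floor.  Metabolites that are zero in
every experimental sample carry no information and are dropped with a
warning, mechanically mirroring the panel reductions such studies
report.

**Transform and scaling.** Natural log, then column centering and
scaling estimated on experimental rows only (QC and repeat injections
are diagnostics, never part of a fit) and retained so held-out rows can
be projected identically.  Auto scaling (unit variance) is the default
because it makes VIP comparable across metabolites whose concentrations
span four orders of magnitude; Pareto (√SD) and centering-only are
configurable alternatives since published preprocessing choices in this
area are often underspecified.

**QC diagnostics.** Per batch, the relative standard deviation of each
metabolite over the post-conditioning pooled-QC injections (the first
five QCs of a batch condition the column and are excluded) and the
maximum absolute percent difference over repeat/original pairs, paired
by subject, arm and hour.

## Cross-sectional latent models

PCA is computed by SVD of the centered matrix; explained fractions are
squared singular values over the total, and requesting more components
than the rank is an error that reports the attainable rank.  Component
signs are fixed by making the largest-magnitude loading entry positive,
so repeated runs are bit-identical.

PLS-DA uses NIPALS PLS2 on the centered one-hot class indicator, the
reference algorithm in chemometrics.  Per-component explained response
variance SSYₐ = (tₐ'tₐ)(qₐ'qₐ)/‖Y‖² feeds the standard weight-based VIP

    VIP_j = sqrt( p · Σₐ SSYₐ (w_ja/‖wₐ‖)² / Σₐ SSYₐ ),

whose mean square is 1 by construction, so VIP ≥ 1 marks variables
carrying more than an average share of the discrimination.  Selection
uses a 3-component model by default and score plots 2 components; the
component count is configurable since no model-selection procedure is
prescribed for this workflow.

Each 0 h-vs-t h contrast model is fitted on its own two-group subset of
the intervention arm, autoscaled *within that subset*.  This is a
deliberate design choice: reusing the full-course scaling would divide a
metabolite's contrast separation by variation occurring at hours outside
the contrast (a metabolite that declines mostly after hour 1 would have
its 0–1 h importance diluted), whereas a cross-sectional two-group model
should weigh variables by their behaviour in those two groups.
Metabolites constant within a contrast subset are excluded from the fit
and assigned VIP 0.

Multilevel variants for the paired design split the matrix into
between-subject means and within-subject deviations
(x_it = x̄_i + (x_it − x̄_i)); fitting on the within part removes
subject-level offsets, which is appropriate when every subject is their
own control.

## ASCA

The centered matrix is partitioned by the design's main effects, time
and participant: the effect matrix of a factor assigns each sample the
mean profile of its factor level, and the residual is what remains.
For the balanced crossover these effect matrices are mutually orthogonal
and the sums of squares are additive, giving an ANOVA-style variation
partition across all metabolites at once.  An interaction term is not
included (main-effects model).  Simultaneous component analysis of an
effect matrix is its PCA — rank at most levels − 1, enforced — with
per-level centroids and 95 % chi-square confidence ellipses of the
centroid (covariance of the mean, S/n).  Projecting the residual onto
the effect loadings to scatter samples around their centroids is
available but off by default, since pure effect-matrix SCA is the
cleaner summary and either variant is defensible.

Significance of the time effect is assessed by permutation: hours are
permuted *within each subject* (respecting the nesting of repeated
measures), the statistic is the factor's effect sum of squares, and
p = (1 + #{null ≥ observed})/(n_perm + 1) with n_perm ≥ 99 enforced.
With 199 permutations the smallest attainable p is 1/200.  A subtlety
worth knowing: in very small designs a draw in which every subject
receives the *same* relabelling reproduces the observed statistic
exactly, so the attainable minimum is only reached once the design has
enough subjects/hours (negligible at 12 subjects × 5 hours).

## Unfolded PCA

The cases × metabolites × hours array of one intervention arm is
unfolded batch-wise to a cases × (metabolite·hour) matrix: each case
(subject) contributes a single row concatenating its full time course,
so PCA on this matrix respects the repeated-measures structure.  The
column blocks belonging to each hour define *block scores* — a case's
hour-t sub-profile times the hour-t loading block — which sum exactly to
the case's total score because the matrix is column-centered.  Block
scores in hour order are the per-case trajectories; their per-hour means
are the time centroids, drawn with 90 % score ellipses (versus 95 %
centroid ellipses in ASCA — the levels are per-plot-type defaults and
configurable).  The alternative observation-rows layout (one row per case and
hour) is available behind a flag, and both interventions can be
unfolded jointly (cases become subject × arm pairs).

Bi-plot ranking orders metabolites by loading₁² + loading₂², within one
hour's block for time-resolved plots or summed over blocks otherwise;
ties break lexicographically and the top 7 are emitted by default.

## Univariate statistics, selection, power

**Signed fold change** of a comparison mean versus a reference mean is
+ratio when ≥ 1 and −1/ratio otherwise, so increases and decreases have
symmetric magnitudes and |FC| ≥ 1 always.  Fold changes are computed
from arithmetic means of the creatinine-normalized, untransformed
concentrations — this is the convention that reproduces published
fold-change tables from their printed means (log-scale means would not).

**Wilcoxon signed-rank test**, two-sided, on within-subject differences:
zero differences dropped (at least 5 usable pairs required), ties
mid-ranked, exact p by dynamic-programming enumeration of all 2ⁿ sign
assignments for n ≤ 25 (mid-ranks are half-integers, so doubling them
makes the convolution integral), normal approximation with tie
correction beyond.  At n = 12 the exact two-sided test is conservative:
its attained size at the 0.05 gate is 0.0425, which is what a correctly
calibrated null simulation should reproduce — not 0.05 itself.

**Selection** is the conjunction VIP ≥ 1.0 ∧ p ≤ 0.05 ∧ |FC| ≥ 1.5 at
the 0 h vs 1 h contrast, output sorted by VIP.  No multiple-testing
correction gates the selection (matching the workflow this package
reproduces); a Benjamini–Hochberg column is emitted for reference only.

**Spearman correlations** are computed over all pooled (subject × hour)
observations of the intervention arm, optionally with the sampling hour
as a pseudo-variable so monotone drift over the study reads directly off
the matrix.  Colour bands use fixed thresholds: |r| ≥ 0.6 high,
0.2 ≤ |r| < 0.6 moderate, |r| < 0.2 neutral.  Constant variables yield
undefined (flagged) coefficients.

**Paired power** is the analytic power of the two-sided one-sample
t-test via the noncentral t distribution (df = n − 1, noncentrality
d√n); d = 0.9 with n = 12 pairs at α = 0.05 gives 0.81.  A Monte-Carlo
mode simulates either the t-test (cross-check of the formula) or the
exact Wilcoxon test under normal shifts.

## Synthetic-data generator

The generator is the package's test bed and defines the study
conditions.  Normalized concentrations follow

    c(s, m, t, arm) = baseline_m · exp(u_sm) · response_m(t, arm) · exp(ε),

with subject random effects u_sm ~ N(0, subject_sd²) shared across arms
(crossover), residual ε ~ N(0, ln² gsd_m), response ≡ 1 in the vehicle
arm and for unaffected metabolites, and raw μmol/L values back-computed
through per-void lognormal creatinine (median 10 mmol/L, log-SD 0.35) to
emulate dilution by water consumption.  Planted responses interpolate
log-linearly between hourly anchors; canonical shapes are early/late
peak with decay, persistent rise with plateau, and monotone decrease.

The `table1_preset` truth plants 13 affected metabolites whose hourly
anchors equal the published mean ratios of the reference study (e.g. a
lactic-like 27-fold 1 h spike, a tiglylglycine-like 7-fold persistent
rise from 2 h, a vanillylmandelic-like steady decline to ~1/9), with
baselines equal to the published hour-0 means.  Default noise,
subject_sd = 0.35 and noise_sd = 0.45, was chosen once so that simulated
per-hour SD/mean ratios fall in the middle of the published range
(~0.2–1.7; combined CV ≈ 0.6): the study's true variance decomposition
is unknown, so this is a documented package choice, not a claim about
the original data.

With the QC layout enabled, each subject's batch is emitted in the exact
25-injection order Q×6, then S/R/Q blocks totalling 11 pooled-QC
injections, 5 + 5 experimental samples per arm in random order, and
2 + 2 repeat injections — alcohol repeats duplicate samples from later
in the batch, vehicle repeats earlier ones, as exact re-injections.
QC injections are the pooled mean profile with 5 % lognormal analytical
noise.  Optional zero inflation plants non-detects at a configured rate.

What the generator does **not** emulate: instrument drift and
batch-to-batch effects (QC noise is i.i.d.), retention-time artifacts,
correlated metabolite panels (fillers are independent), heavy-tailed or
subject-specific response kinetics, and period/carry-over effects of the
crossover.  Passing tests therefore demonstrate correctness of the
statistical machinery under a clean multiplicative-lognormal model, not
robustness to every pathology of real GC–MS data.

## Numerical conventions and degenerate inputs

- Component signs: largest-|loading| entry positive; with NIPALS the
  weight/score/loading/y-loading columns flip together, so fits are
  bit-reproducible under fixed input order.
- Rank deficiency: direct PCA errors when more components than the rank
  are requested; derived analyses whose dimension is fixed by the design
  (SCA of an effect matrix, unfolded trajectory plots) pad missing
  components with zeros instead, so a zero effect yields centroids at
  the origin rather than an error.
- Degenerate PLS-DA (no class-correlated variation) stops extracting
  components; VIP is then undefined and requesting it is an error.
- All-zero differences in the paired test give p = 1 with a degeneracy
  flag; constant variables give flagged NaN correlations.
- Permutation seeds, generator seeds and pipeline seeds are explicit
  arguments; identical seed + configuration reproduces byte-identical
  output bundles (the configuration hash covers analysis parameters
  only, not filesystem paths).

## Problem sizes used by the validation scripts

The acceptance script and test suite validate at the study's own scale —
12 subjects × 5 hours × 2 arms × 120 metabolites — using 50 simulated
studies for selection sensitivity (planted responses of at least
four-fold at the contrast hour) and 200 null studies for the
false-positive calibration of the p-gate, with oracle equivalences
(eigendecomposition PCA, 2ⁿ sign enumeration, naive rank correlation)
checked on batches of randomized small instances.

## Known limitations

- Main-effects ASCA only; no interaction or covariate adjustment
  (ASCA+-style extensions are out of scope).
- No cross-validation or permutation-based validation statistics (Q²,
  CV-ANOVA) for PLS-DA component choice.
- The exact Wilcoxon implementation enumerates up to n = 25 pairs;
  beyond that the normal approximation is used.
- Ellipse parameters assume approximate bivariate normality of the
  score clouds; they are emitted as coordinates, not drawn.
- Repeat injections are treated as diagnostics only, never averaged into
  the experimental values.
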