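# Methods

This note describes the statistical procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that make results reproducible bit for bit.

## qPCR relative quantification

Each well's raw fluorescence trace F(c), c = 1..40, is processed as:

1. **Baseline correction.** The mean fluorescence over cycles 1–8 is
   subtracted from the whole trace. The baseline window is configurable
   (`QuantConfig.baseline_cycles`).
2. **Amplification efficiency E.** Least-squares of log10 F on cycle over
   the best "window of linearity": every run of ≥ 4 consecutive cycles
   whose corrected fluorescence lies between 5 % and 60 % of the well's
   plateau (its maximum corrected fluorescence) is scanned, and the window
   maximizing R² wins; E = 10^slope. For steep curves (E ≈ 2) the 5–60 %
   band spans only log_E(12) ≈ 3.6 cycles and can contain three integer
   cycles; in that case the band run is extended outward — earlier cycles
   first, where the curve is closest to exponential — until the four-cycle
   minimum is met. Ties between equal-R² windows resolve to the earliest,
   then longest, window by iteration order with a strict improvement test.
3. **Quantification cycle Ct.** The fractional cycle at which the
   corrected trace crosses an absolute threshold, interpolated on the log
   scale (exact for an exponential). The threshold defaults to 10 % of the
   median plateau across the plate; an absolute value can be configured.
4. **Melt QC.** The observed melting temperature is the global maximum of
   −dF/dT of the dissociation curve (60–95 °C). A well is flagged
   `low_tm` when its observed Tm falls more than 1 °C (configurable) below
   the expected product Tm — the signature of primer dimers or
   non-specific product — and `irregular_melt` when the derivative has two
   or more local maxima each above 30 % of the global maximum, when no
   peak reaches a minimum prominence, or when the melt curve is missing.
   Flagged wells are excluded. Wells whose estimated efficiency falls
   outside [1.5, 2.2] are *reported* but retained: that range describes
   primer validation on dilution series, not a per-well rejection rule.
5. **Relative quantity and normalization.** RQ = 1/E^Ct. Technical
   replicates are aggregated by the median RQ (median resists single-well
   dropouts; the aggregation is configurable). Within each accession ×
   treatment × biological replicate, the target RQ is divided by the
   geometric mean of the surviving reference-gene RQs — at least two of
   the three references must survive QC, which preserves replicates when a
   single reference well fails — and reported as log2. This value is
   scale-free: multiplying every RQ of a replicate by any constant leaves
   it unchanged.

## Variance decomposition by REML

The normalized log2 expression of target genes is modeled as

    y = Xβ + Σ_k Z_k b_k + ε,  b_k ~ N(0, σ²_k I),  ε ~ N(0, σ²_e I)

with accession, treatment and their interaction as fixed effects and
independent random intercepts for gene and gene × accession. Random
effects are uncorrelated within and across grouping factors (random
intercepts only; no slopes or correlation structure).

Variance components are estimated by restricted maximum likelihood. The
criterion is profiled over β and σ²_e, leaving only the variance ratios
θ_k = σ²_k/σ²_e, and is evaluated on the problem projected onto the
orthogonal complement of the fixed-effect column space (REML as the
marginal likelihood of error contrasts). With G = Z'(I − QQ')Z and
r = Z'(I − QQ')y for an orthonormal basis Q of the column space of X,

    −2 ℓ_R(θ) = log|Λ G Λ + I| + log|X'X| + (n−p)(1 + log 2π·pwrss/(n−p)),

where Λ = diag(√θ) and pwrss is the penalized residual sum of squares.
This is algebraically identical to the usual bordered-system formulation
but reduces the per-evaluation Cholesky from (p+q)² to q², which is what
makes 40 000 parametric-bootstrap refits affordable.

Numerical choices:

* optimization is over log θ with a deterministic multi-start (grid
  {0.01, 1, 100} per ratio, coarse Nelder–Mead per start, fine Nelder–Mead
  from the winner, then cyclic Brent line searches to ≈1e−11 per
  log-ratio); no randomness enters the fit;
* ratios are floored at 1e−10 and snapped to zero at the floor, which
  permits effectively-zero components without boundary pathologies;
* on balanced one-way designs with interior estimates the result equals
  the closed-form moment estimator (MSA−MSE)/n to better than 1e−6 (this
  is asserted in the acceptance suite over 100 random designs);
* an all-constant response yields all-zero variance estimates; a rank-
  deficient fixed design is repaired by dropping aliased columns, as R's
  `lm` does via QR pivoting — necessary for the unbalanced study design,
  where interaction dummies of accessions observed in only two treatments
  alias their accession main effect — and a term whose columns are all
  aliased raises an explicit error naming it.

**Fixed-effect ANOVA.** Sequential (Type I) sums of squares in the order
accession, treatment, interaction, computed on the response after
subtracting the predicted random effects (BLUPs); F is each term's mean
square over the residual mean square of the full fixed model. No
Satterthwaite or Kenward–Roger degree-of-freedom correction is applied —
a known limitation; the F values are descriptive.

**Variance proportions and bootstrap CIs.** Proportions are σ²_k/Σσ²_j
(residual included). Confidence intervals are percentile intervals over
parametric-bootstrap refits: data are simulated from the fitted model
(fixed effects plus Gaussian random effects at the estimated variances),
refitted warm-started from the parent fit at loosened tolerance (the CI
endpoints' Monte Carlo error dominates any refit imprecision), and
non-converging refits are dropped and counted. A seed is mandatory.
Percentile CIs for variance proportions are approximate; their coverage
degrades for small designs (few random-effect levels), which is why the
coverage simulation below uses a design close to the study's.

**Model comparison.** Likelihood-ratio tests and AIC on nested models;
models differing in fixed effects are refitted internally by ML, since
REML criteria are not comparable across fixed structures.

## Gene-set perturbation response

Per perturbation, (up, no-change, down) counts of the focal set and a
comparison set form a 2×3 table tested by Pearson's χ² without continuity
correction; recomputing the published statistics for this design confirms
the plain Pearson statistic is the right one. Zero-total columns are
dropped with the degrees of freedom reduced. A 2×2 collapse — up versus
(no-change + down) — isolates whether up-regulation drives a difference.
Benjamini–Hochberg correction is applied per comparison type across the
perturbation panel (one family per set pair); the family definition is
configurable since reasonable alternatives exist. The direction-bias
statistic |up − down|/(up + down) is purely descriptive and is never
tested for significance.

The positionally matched control set picks, for each focal gene, the
unused candidate gene nearest to the focal start shifted by a fixed
500 kb offset (sign chosen to stay on the chromosome). Focal genes closer
than 10 kb form clusters; each subsequent member's target preserves the
original spacing from the previously chosen control and chosen controls
must keep the cluster's positional order, so consecutive distances keep
their rank order. The procedure is deterministic (ties break on the
smaller start coordinate); offset and cluster threshold are configuration,
not fixed constants, because the matching procedure admits more than one
defensible reading. The stress set is a uniform sample without replacement
from genes annotated "response to stress" (GO:0006950), using the
annotation exactly as supplied; descendant expansion is the caller's
choice by passing an expanded term collection.

## Climate clines and resampled nulls

Per-accession basal expression for a treatment is the fixed accession
effect of a mixed model with gene as a random intercept, so constant
per-gene offsets (primer bias between accessions) cancel from every
accession contrast — asserted to 1e−9 in the tests. Basal expression
defaults to the short-day condition (the biologically relevant day length
for eight-leaf-stage material); long days are available by flag.
Plasticity is the difference of treatment and control model estimates in
log2 fold-change units.

Clines are OLS regressions of the per-accession value on one of four
climate covariates (latitude, minimum temperature of the coldest month,
precipitation of the driest month, temperature seasonality = warmest-month
maximum minus coldest-month minimum), reporting slope, R², adjusted R²,
F(1, n−2), t and p, Bonferroni-corrected ×4 for the covariate family.

The resampling null draws many gene sets of the focal set's size,
uniformly without replacement within a set and independently across sets,
averages each set's expression per accession, regresses on the covariate
and keeps the slope t-value. The pool excludes the focal genes by default
(a flag restores the whole-transcriptome pool). Extremeness is two-sided
on |t| by default, with a one-sided option; both the raw fraction and the
(1+count)/(n+1) pseudocount variant are reported. Note that t-values of
different sets are positively correlated through shared genes, so the
null's mean is only near zero when the pool is much larger than the set —
true for a transcriptome, not for toy matrices.

The two-population comparison applies Welch's unequal-variance t-test per
gene between populations (robust to the populations' unequal sizes; no
test is canonical here), Bonferroni-corrected over the tested genes, and
summarizes how many significant genes are higher in each population.

## Resistance (CFU) analysis

Titers are analyzed as log10 CFU. Fold changes are ratios of geometric
means, i.e. 10^(difference of mean log10 titers) — consistent with the
log-scale analysis; a median-based variant is reported alongside because
the choice between means and medians of log titers is not canonical.
Group comparisons are Welch tests of each treatment against the reference
per strain, BH-corrected across the strain × treatment family.

## The synthetic-data generator

The generator emulates the study design: 12 accessions (7 with 8
treatments, 5 with the control/short-day pair), 13 target genes, 3
reference genes, 3 biological × 3 technical replicates (9 504 wells).
True log2 expression is grand mean + gene + accession + treatment +
accession×treatment + gene×accession + residual, with the three
random-effect variances defaulting to the published point estimates
(11.21, 5.72, 3.35), an accession SD of 1, an interaction SD of 1 (both
unreported in the source and set to a plausible log2-scale magnitude),
and treatment effects of log2 2.5 for cold shock and log2 1.6 for the
other perturbations. Reference genes receive a stable per-gene baseline
and no treatment, accession or interaction effects — they emulate stably
expressed normalizers — with optional residual noise.

Expression converts to a quantification cycle via Ct = (offset − y)/log2 E
(offset 30, E 2.0). Fluorescence is a baseline-plus-generalized-logistic
(Richards) curve whose exponential phase has per-cycle ratio exactly E and
which crosses 10 % of its plateau exactly at the generating Ct; the shape
constant (default 8) controls how sharply the exponential turns into the
plateau. A plain logistic bends away from exponential growth well below
the plateau, which would make any window-of-linearity estimator
systematically underestimate E; the Richards form is the simplest curve
that saturates *and* is honestly exponential where the estimator looks.
This is a stand-in for instrument physics chosen for round-trip
testability — it does not model reagent depletion kinetics, ROX
normalization artifacts, or plate-position effects. Melt curves are
sigmoidal drops at the product Tm; an optional primer-dimer component adds
a dominant low-Tm peak. One RNG stream per logical component (effects,
curves, noise), all spawned from the master seed, so adding wells never
perturbs effect draws.

The clinal matrix generator drives all four climate covariates from one
latent gradient (they are strongly correlated in real origin climates),
maps the named covariate affinely onto its configured range, and gives
focal genes a common slope against it while background genes get slopes
drawn N(0, background_slope_sd²). It does not model population structure,
linkage between neighboring genes, or count-based sampling noise —
passing tests show the statistics behave correctly under the assumed
Gaussian model, not that real RNA-seq matrices satisfy that model.

## Problem sizes used in the test suite

Simulation-based checks are scaled to run on one CPU in minutes, as the
package's own test-size policy:

* parameter recovery: the full 12-accession design, 50 replicates;
* bootstrap coverage: 200 outer replicates × 200 bootstrap refits on a
  9-accession variant of the design (6 accessions with all 8 treatments,
  3 with 2; all 13 genes). Percentile CIs for variance proportions
  undercover when the design carries little information per component, so
  the coverage simulation stays as close to the study design as the
  suite's runtime allows — 9 accessions is the largest affordable
  variant;
* resampling-null calibration: 200 generator seeds × 200 null sets
  (uniformity), one run × 1000 sets (power);
* null calibrations for the resistance and LRT tests: 100–1000
  simulations each.

## Known limitations

* F statistics use no small-sample df correction; p-values from them are
  not reported by the ANOVA stage.
* Percentile bootstrap CIs for variance proportions undercover for
  designs with few random-effect levels.
* The automated melt QC (two-peak rule with a 30 % relative height) is a
  proxy for by-eye curation of dissociation curves; its thresholds are
  configuration, not derived quantities.
* The efficiency/Ct estimator assumes a single global threshold per
  plate; no per-well adaptive thresholding.
* Published regression tables that depend on the study's raw expression
  and climate data cannot be recomputed here; those stages are validated
  by oracle agreement and invariances instead.
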