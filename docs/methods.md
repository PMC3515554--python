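# Methods

This note documents the statistical models implemented in `bloodsig`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
recorded.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scales and conventions

Expression enters and leaves every stage on a positive linear intensity
scale (PLIER-like, motivating the ≥150 expression floor).  All internal
statistics run on log2 intensities; log2 is the field convention and makes
the additive batch/effect models natural.  Fold changes are case/control
ratios of *linear*-scale means, screened direction-agnostically as
max(fc, 1/fc) > threshold, so a 0.5-fold (halved) gene passes a 1.5-fold
screen via its reciprocal.

## Cross-platform harmonization

A many-to-one probeset map links the older array's source probesets to
gene-level target features.  For genes carried by ≥2 source probesets the
per-probeset case−control mean difference (log2) must share one sign —
the sign of the mean difference, not of a t statistic, is used, since the
two differ only when probeset variances differ wildly and the mean
difference is the quantity the fold change reports.  Retained genes take
the **median** across probesets: robust to one discordant-magnitude probe,
and the natural summary when no probe-affinity weights are available.
Features already in the target space pass through, making the operation
idempotent.

## Batch adjustment

Parametric empirical-Bayes location/scale adjustment (ComBat): per-gene
standardization against a design that contains batch indicators plus the
protected biological covariate (diagnosis — the original algorithm's
recommendation; without protection the case/control contrast is partly
absorbed when batches are imbalanced), normal prior on per-batch gene
locations, inverse-gamma prior on scales, method-of-moments
hyperparameters, iterative joint solution to 1e-6 relative tolerance.
With a single batch the model is exactly the identity.

Two behaviors worth knowing:

* the shrinkage leaves a residual per-gene batch-mean difference of about
  half the sampling noise of the batch means whenever the standardized
  batch effect varies across genes — this is inherent to the EB model, not
  an implementation artifact (the test suite's straight-line oracle and the
  calibration test sizes reflect it);
* per-gene overall means drift by < 0.02 log2 units on null data
  (asserted), so downstream fold changes are essentially untouched.

## Differential expression

Welch t with Satterthwaite df, two-sided, at a nominal p < 0.001.  Storey
q-values estimate pi0 on the λ grid 0.05…0.95 (step 0.05) with a cubic
smoother extrapolated to λ = 1, clipped into (0, 1]; forcing pi0 = 1
reduces exactly to Benjamini–Hochberg.  Subtype comparisons use pooled-
variance many-to-one t statistics with the Dunnett familywise adjustment
evaluated by seeded Monte Carlo over the joint multivariate-t null
(default 10⁵ draws) — Monte Carlo rather than numeric integration because
the number of comparisons varies and the two-group reduction to the pooled
t provides a sharp correctness oracle.  Diagnosis-by-sex effects use Type
II sums of squares, the standard convention for main effects under
observational imbalance; on balanced designs Type II coincides with the
sequential decomposition (asserted).  Spearman screens use midranks for
ties and Fisher's r-to-z (z = atanh ρ √(n−3)); |ρ| = 1 is clamped to
1 − 1e−12 before atanh, mapping to p = 0 numerically.  The r-to-z normal
approximation is accurate at moderate p but can deviate from a permutation
p by more than 2× in the far tail (p ≲ 10⁻⁴) — screens at p < 0.001 are
unaffected in practice.

## Overlap significance

The permutation null shuffles case/control labels independently within
each cohort, recomputes both Welch screens, and counts the intersection of
significant feature sets (gene space, post-collapse).  The reported
p-value is **exceedances / n_perm** — the convention under which 2/200,000
prints exactly 10⁻⁵; the never-zero (r+1)/(n+1) estimator is available
behind `add_one=True` and is the strictly valid choice when the observed
statistic is counted among the permutations.  The two-sided Fisher exact
test uses the probability-mass rule (sum of hypergeometric point
probabilities ≤ the observed table's), the common exact-test convention,
with the sample odds ratio ad/bc.  The hypergeometric overlap tail
requires the universe N explicitly, because the natural universe is
ambiguous between matched probesets and unique genes; reports print the
assumption used.

## Enrichment and pathway clustering

EASE score = one-tailed Fisher over-representation p with the hit cell
decremented by one; a single-hit set therefore scores p = 1, and EASE ≥
Fisher always.  Sets with fewer than 3 hits are skipped (2 post-decrement),
BH adjustment runs across tested sets, and the background defaults to the
collapsed feature space.  Enriched sets are clustered on the Cohen's kappa
of their membership vectors over the union of hit genes (the DAVID-style
convention of clustering on shared list genes).  Each set seeds a candidate
cluster of all sets with kappa above threshold (default 0.5); candidates
sharing more than 50% of members merge.  Greedy-with-merge was chosen over
connected components because the intended output allows one pathway to
belong to two clusters, which components cannot produce; the 50% merge
fraction is a documented free choice.  Output is deterministic and
invariant to input order (sets are processed in sorted name order).

## Robust subgroup discovery

Per-sample robust distances over each of two pathway gene sets, estimator
fit on cases and controls jointly (the common centroid), cutoff
√χ²₀.₉₇₅(df) per axis, quadrants I/II/III/IV = outlying in
both/second-only/neither/first-only.

The MCD estimator is an own FAST-MCD: 500 seeded random (p+1)-point
starts, two concentration steps each, the ten best iterated to
convergence, h = ⌊(n+p+1)/2⌋ (maximal breakdown), chi-squared consistency
factor on the raw estimate, then one reweighting step at the χ²₀.₉₇₅
cutoff with its own consistency factor.  Five hundred starts matter: with
a 20% outlier cluster and few starts the cluster can mask itself into the
estimate (observed with default-start library implementations).

Dimension policy: squared robust distances of points outside the h-subset
are markedly heavier-tailed than χ² when n/p is small, which inflates the
nominal 2.5% flag rate severely (~30% at n ≈ 3p on clean data, by
simulation).  The subspace is therefore reduced by PCA whenever
n < 10·p, to the fewest components explaining ≥90% of variance, capped at
n/10 components; the χ² reference df becomes the retained dimension and
the reduction is flagged in the output.  Residual over-flagging of ~10% on
clean data at n ≈ 100 remains — the same order as published analyses that
use the χ² cutoff at these sample sizes — and is shared by cases and
controls, so the Fisher comparison of outlier rates stays valid; it does
cost power, and a minority of simulated subgroup-recovery seeds miss
significance for that reason.

## Signature training

PLS1 by NIPALS on a 0/1 class code, predictors centered and unit-scaled by
training statistics, response centered; class call at score ≥ 0.5 (the
midpoint of the code — the threshold is a free choice, and the ROC/AUC
reporting does not depend on it).  Component score vectors are orthogonal
by construction (asserted to 1e-8); the implementation agrees with
standard PLS regression to machine precision on shared configurations and
reduces to ordinary least squares in the univariate single-component case.

Nested leave-group-out CV: "leave group out" is read as repeated
stratified 80/20 random splits (not exhaustive folds) — the reading that
matches "divided to 80%/20%, repeated 100 times".  The same outer split
sequence is reused across the top-N sweep so per-size AUC vectors are
comparable (`compare_model_sizes` runs a one-sided Welch t on two such
vectors).  The inner layer re-splits the outer training set identically
and picks the PLS component count from 1..10 maximizing mean inner test
AUC; 1..10 is a pragmatic grid, as the tuned range is otherwise
unconstrained.  Outer splits that draw a single-class test set are redrawn
(logged), preserving exactly `outer` valid splits.  Selected N = argmin of
the coefficient of variation sd/mean of outer AUCs, ties to the smaller N
(minimum description length).  A consequence worth knowing: once the
signal is strong enough that outer AUC saturates at 1.0 for every size,
all CVs tie at zero and the rule correctly selects the smallest size.

Two ranking modes: the default ranks genes by AUC once on the full
training cohort **before** CV — faithful to the protocol this pipeline
reproduces, but it leaks the ranking into the outer estimates, and on pure
noise it inflates mean outer AUC far above 0.5 (asserted).  The
`rank_in_fold` mode re-ranks inside each outer training split and stays at
chance on noise (asserted); it is the recommended mode for new analyses.

The random-signature null refits the same PLS protocol on k uniformly
drawn genes per draw and reports p = (#draws ≥ observed)/n_draws.  AUC
confidence intervals use the DeLong placement-value variance; the interval
is clipped to [0, 1] and degenerates to a point when scores are constant
within a class.

Pipeline candidate pool: the sweep runs over floor-passing DE-significant
genes; when the DE screen is under-powered (fewer candidates than the
sweep minimum) it falls back to all floor-passing genes with a logged
warning, letting the AUC ranking do the selection.

Heatmap views z-score genes before clustering samples on 1 − Pearson
correlation with average linkage (without standardization, absolute
baseline expression dominates every between-sample correlation); the
Fisher discriminant uses w ∝ S_w⁻¹(μ₁ − μ₀) with a trace-scaled ridge
fallback for singular pooled scatter, oriented so cases score higher.

## The synthetic-data generator

Defaults are the study-shaped desk-scale conditions: 2,000 genes; cohort 1
with 66 cases / 33 controls (all male, source-probeset feature space with
~30% of genes on 2–3 probesets, per-probe sd 0.1 log2); cohort 2 with 104
cases / 82 controls (mixed sex, gene-level feature space); per-gene log2
baselines from U(5, 12) with sd U(0.3, 0.8); two batches per cohort with
location shifts ~N(0, 0.3) and deviation scales U(0.8, 1.25); 5 near-binary
male-high sex genes (4 log2 units — emulating X/Y-linked transcripts);
30 age-sloped genes at ±U(0.02, 0.06) log2/year over ages 4–13.

The planted case effect adds δ·(per-gene sd) on the log2 scale to 55
signal genes (δ defaults to 1.0); additive-in-sd keeps the effect size
interpretable for power analysis and matches the ~1.5–3.8 linear fold
changes such studies report.  80% of signal genes concentrate in two
designated pathway sets ("cluster 1"/"cluster 2"); cases split into
subgroups perturbed in cluster 1 only (15%), cluster 2 only (10%), both
(25%), or neither (50%) — chosen so the cluster-2 perturbed fraction of
cases (~35%) matches the heterogeneous-subgroup geometry the analysis is
designed to detect, with controls never perturbed.  A consequence: under
these defaults roughly half the cases carry no expression signal at all,
capping the achievable held-out classification AUC near 0.75 — deliberately
in the range real blood-expression classifiers of heterogeneous disorders
achieve, and a reminder that a synthetic AUC near 1.0 would say nothing
about real data.  Recovery tests that state a per-gene effect size plant
the signal in **all** cases (`frac_both = 1`) so the stated δ is the
effective per-gene effect.

A `female_extra_sd` knob adds extra female-sample variance; its default is
0 because no quantitative model for the reported female RNA heterogeneity
is available — the knob exists for sensitivity analysis only.

Not emulated: probe-sequence affinity structure, RNA degradation,
gene–gene correlation beyond the planted clusters, cell-type composition
shifts, and population stratification.  Passing recovery tests therefore
demonstrate the *machinery* (given the assumed additive structure), not
performance on real cohorts.

Determinism: one `numpy` Generator seeded from the config; identical
config + seed yields bit-identical bundles.  The pipeline derives
per-stage seeds as SHA-256(stage name, global seed) mod 2³¹ so stages can
be re-run in isolation.

## Problem sizes

Desk-scale defaults keep every stage in seconds-to-minutes on one CPU:
2,000 genes, the cohort sizes above, 200–500 overlap permutations, 20
outer × 10 inner CV splits over a 10..100 sweep, 200 random-signature
draws.  The recovery test suite uses 10–20 seeds per property; calibration
fixtures that need tight tolerances (e.g. batch-shift removal) use larger
batch sizes (600 samples/batch) where the expected residual is pure
sampling noise.

## Known limitations

* The χ²-cutoff robust-distance flag rate stays above nominal at n ≈ 100
  even after dimension reduction (see above); an F-distribution cutoff
  would calibrate better but would change the published construction.
* The default full-cohort AUC ranking is optimistically biased by design;
  use `rank_in_fold` when the outer AUC itself is the quantity of
  interest.
* Storey's smoother-based pi0 is unstable below ~100 p-values; the
  implementation falls back to the conservative minimum-over-λ estimate
  there.
* The EB batch model assumes normal log2 intensities and batch effects
  exchangeable across genes; heavy-tailed genes violate the inverse-gamma
  scale prior and retain partial batch structure.
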