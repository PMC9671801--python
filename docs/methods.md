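# Methods

This note documents the models implemented in `metabotyper`, the defaults
and why they are set where they are, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Synthetic cohorts

**Genotypes.** Dosages come from a thresholded latent Gaussian: within a
chromosome, two haplotype latents per individual have correlation
`exp(-ld_decay * distance_bp)`; each latent is dichotomised at the normal
quantile of the variant's target minor-allele frequency and the two allele
indicators are summed, giving hard calls in {0, 1, 2} under Hardy–Weinberg.
This produces exactly the two genotype properties the downstream stages
consume — a tunable allele-frequency spectrum (common to rare, MAF ≥ 0.1%)
and monotone LD decay — without the cost or machinery of a coalescent
simulation.  It does **not** produce recombination hotspots, population
structure, relatedness, or imputation uncertainty; consequently ordinary
least squares replaces the mixed-model association engines used on real
cohort data (the random effect has nothing to absorb in unrelated,
unstructured samples).  This is the single largest simplification in the
package and the main caveat when transferring conclusions to real data.

**Metabolites.** On a standardized latent scale each causal variant
contributes `beta` s.d. per allele; `beta` is derived from a
variance-explained target via `beta² · 2·maf·(1−maf)`.  Unless a noise s.d.
is given explicitly, residual noise tops the latent variance up to 1, so
planted variance-explained fractions are realized on the analysis scale.
The latent (plus optional covariate main effects) is exponentiated to a
positive, log-normal abundance scale, emulating median-scaled platform
abundances.  Missingness is MCAR at a configurable rate (default 2%); a
`missing_fn` hook accepts arbitrary (e.g. MAR) mechanisms.  Real platform
features *not* emulated: run-day drift, limit-of-detection (left-censored)
missingness, heteroscedastic technical error, correlated measurement error
across metabolites.  Passing tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not robustness to these
artifacts.

**Phecodes.** Binary outcomes follow a logistic liability model with planted
log-odds per s.d. of metabolite liability; the intercept is calibrated
numerically (Brent root-finding on the empirical mean risk) so the realized
prevalence matches the requested one.

**Study layout.** `StudyConfig` defaults mirror the emulated two-stage
design: discovery cohorts of 8,455 and 5,841 samples plus 5,698 validation
samples; three regions on separate synthetic chromosomes, each with 2–3
planted GIMs of 1–2 causal variants × 2–3 metabolites; causal variants
spaced 500 kb apart (inter-signal dosage r² ≈ 10⁻⁴ at the default
`ld_decay = 1e-5`/bp) with four LD proxies within 30 kb of each; 2% of
causal variants rare (MAF 0.5%) with correspondingly larger per-allele
effects; per-variant variance explained 2%.  Every operation takes an
integer seed, and the per-operation RNG streams are salted so that reusing
one seed across operations can never correlate their draws (e.g. metabolite
noise with genotype latents).

## Preprocessing

Natural log → winsorize at mean ± 5 s.d. (statistics computed once on the
pre-winsorization values, not iterated) → per-metabolite complete-case
linear residualization on covariates (categoricals dummy-coded; samples
missing any covariate excluded for all metabolites) → standardize with the
sample s.d. (n − 1).  Metabolites observed in fewer than `min_n = 200`
samples, or constant, are dropped with provenance recorded.  Covariate lists
may differ across cohorts; residuals are standardized within cohort before
pooling.

## Association and meta-analysis

Per-cohort statistics are simple-regression slopes of the standardized
residual on dosage, with two-sided P from the t distribution (n − 2 df; this
converges to the normal P used on the meta scale).  Cohorts contribute to
the inverse-variance-weighted fixed-effect pool only where MAC > 10; records
with no contributing cohort are dropped rather than erroring.  The candidate
filter for region definition requires meta P < 5×10⁻⁸ plus P < 0.01,
MAC > 10 and sign consistency in both discovery cohorts.  Validation
re-meta-analyzes discovery + validation and requires combined
P < 5×10⁻⁸/913 ≈ 5.48×10⁻¹¹ with sign consistency in all three GWASs.  The
LD reference is the largest cohort (configurable).  A QC guard on extreme
effects (|β| > 10, SE outside (0, 10]) exists for real-data inputs but is
inert on synthetic data.

## Regions

Sentinel peeling per metabolite is iterative — select the candidate with the
largest −log₁₀ P, carve the interval spanned by its r² ≥ 0.1 partners
(±500 kb if none), remove the partners, repeat — which guarantees every
candidate is eventually covered.  Ties in −log₁₀ P break by smaller
position, then lexicographic variant id.  Pooled sentinel intervals merge
when sentinels are in LD (r² > 0.6, within chromosome), receive 250 kb
padding on both ends, and overlapping closed intervals merge until disjoint.
Interval endpoints clip at 1; there is no chromosome-length clipping
(synthetic chromosomes are unbounded).  Internally coordinates are 1-based
closed; BED export converts to 0-based half-open.

## Conditional analysis

Selection is exact (individual-level) forward stepwise regression on the
pooled discovery cohorts with an intercept and fixed cohort effects.  Each
step tests every remaining eligible variant conditional on the selection via
the Frisch–Waugh partial regression (numerically identical to the
coefficient t-test in the full OLS fit, computed with one QR factorization
per step); eligibility is re-checked conditionally each step (same
direction, P < 0.01 in both cohorts), with ineligible top candidates skipped
for the next best.  Selection stops below the regional Bonferroni threshold
0.05/(39,297 × 102) ≈ 1.25×10⁻⁸ (largest regional variant and metabolite
counts).  The final joint model drops selected variants with joint
P ≥ threshold; if none survive — including the lead — the lead alone is
retained with a fallback flag (the threshold is applied to the lead's
*joint* P, one of two defensible readings).  Perfectly collinear dosages
drop the later-selected member.

**Variance partition.** The grand total is the joint-model R² over all
retained variants of a metabolite (after partialling out covariates); each
variant's contribution is the leave-one-out decrease in R², with any shared
R² allocated proportionally so MAF-bin totals (rare ≤ 1%, low-frequency
1–5%, common > 5%) sum exactly to the grand total.  The partition formula is
a design choice: it is symmetric in the variants and exact for orthogonal
predictors.

## GIM definition

The greedy matrix procedure operates on the union of conditionally
independent variants across a region's metabolites.  All entries are refit
from individual-level data at every iteration (not approximated from
summary statistics).  When the top (variant, metabolite) pair fails the
two-cohort consistency check, the *pair* is masked and the next-largest
entry considered — masking the whole variant would discard its associations
with other metabolites on the evidence of one.  Matrix rows record signed
−log₁₀ P conditional on exactly the lower-marker-order variants; display
output caps |entries| at 50.  Clustering takes connected components of the
bipartite graph over entries exceeding −log₁₀(5×10⁻⁸), enumerated by
ascending marker order.  "Adjacent" regions for the merge step are
consecutive same-chromosome regions with gap ≤ 1 Mb sharing at least one
significantly associated metabolite (a quantitative stand-in for a manual
review step; configurable); merged regions are fully re-analyzed and the
loop iterates to a fixed point.

## Causal-gene evidence and IEM enrichment

Candidate genes are the 20 protein-coding genes closest to the GIM's lead
variant (gene-body distance, 0 inside; ties by name).  Seven evidence
channels run against user-supplied flat tables: fuzzy matches of metabolite
synonyms to gene names, protein names, disease names (after removing IEM
nomenclature stop words as whole tokens and token affixes) and GO biological
processes (< 500 member genes, generic substrings removed); metabolite class
vs protein name; interacting-protein lookup; and KEGG-style pathway-map
co-occurrence (shared map membership, no direct connection required).  The
fuzzy metric is defined explicitly — Dice coefficient over character
trigrams of case-folded alphanumeric-only strings, cutoff 0.5 — so scores
are reproducible; metric and cutoff are configurable.  The final
causal-or-not call is deliberately left to manual review; the module emits
the evidence table that review consumes.  IEM enrichment uses a two-tailed
binomial test (minimum-likelihood method: summing probabilities of all
outcomes no more likely than the observed count) against the background
785/19,817 ≈ 4%.

## Phenome scan and Mendelian randomization

Scores are weighted dosage sums over a metabolite's conditionally
independent variants that reach marginal meta P < 5×10⁻⁸ and associate with
fewer than five metabolites; metabolites with fewer than two surviving
variants get no score.  Scores are standardized before logistic regression
so odds ratios are per 1 s.d.; phecodes with fewer than 50 cases (default,
configurable — no principled floor exists) are skipped, and failed fits
(separation) are flagged with missing P rather than dropped silently.
Benjamini–Hochberg controls the FDR at 5% across all score–phecode pairs.
MR pools per-variant Wald ratios by inverse variance with **first-order**
ratio SEs (SE_outcome/|β_exposure|); Cochran's Q uses the same weights, and
MR-Egger regresses outcome on exposure effects (exposure-sign oriented,
weights 1/SE_outcome²).  "Strong evidence" requires ≥ 3 variants and Q
heterogeneity P > 0.05.  On synthetic data the two-sample design is emulated
by cohort splitting; instruments are strong enough that weak-instrument bias
is negligible (asserted in tests).

## Metabolic network

Metabolites with < 30% missingness are multiply imputed per cohort (m = 30
imputations × 50 chain iterations by default) by chained equations with
Bayesian normal linear models: each sweep regresses one incomplete
metabolite on all others, draws σ² from its scaled inverse-χ² posterior and
coefficients from their normal, and replaces missing cells with predictive
draws.  Partial correlations come from the Ledoit–Wolf shrinkage covariance
(analytic shrinkage toward the identity on standardized data), inverted and
rescaled; symmetry and unit diagonal are enforced exactly.  Per-edge Fisher
z estimates pool by Rubin's rules, T = W + (1 + 1/m)B, with the
within-imputation variance W = 1/(n − k − 3) for partial correlations of
order k = p − 2 and the complete-sample n (the between-imputation term B
carries the missing-data uncertainty); cohorts combine by fixed-effect IVW
on the z scale and back-transform via tanh.  Edges enter the network only
with |r| **strictly** greater than the cutoff (0.10, 0.12 or 0.15); signs
are retained and candidate-gene links attach as a second edge type.

## Benchmark problem sizes

The recovery benchmarks (`metabotyper.evaluation`, driven by the acceptance
script and tests) run at: GIM recovery — 20 replicate studies, 8,000 samples
per discovery cohort, 3 regions of 2–3 GIMs, ≥ 1% variance per causal
variant (scored by adjusted Rand index on metabolite partitions);
stepwise-oracle agreement — 8 regions of ≤ 6 variants at n = 4,000 against a
naive statsmodels-refitting forward search; cross-cohort concordance — 40
shared effects (including rare, large-effect variants) at 5,000
samples/cohort; variance recovery — one metabolite with rare, low-frequency
and common causal variants at n = 10,000; FDR control — 1,000 null phecodes
× 100 replicates at n = 2,000, prevalence 10%; MR — 6 instruments × 100
replicates; GGM structure — 20 metabolites, 25 true edges, n = 3,000 at
cutoff 0.10.  These sizes were chosen to give each statistic comfortable
power on a single CPU while keeping the full run in minutes.

## Known limitations

- No mixed models: relatedness and population structure are out of scope by
  construction of the generator.
- Genotypes are hard calls; dosage uncertainty and imputation INFO filtering
  are not represented.
- The GIM marker-order output depends on deterministic tie-breaking
  (position, then allele); real analyses with duplicated positions should
  verify id uniqueness.
- The phenome stage assumes phecodes arrive as binary columns; clinical-code
  mapping is out of scope.
- Fuzzy gene-evidence scoring is a screen, not an assignment: precision
  depends entirely on the supplied annotation tables.
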