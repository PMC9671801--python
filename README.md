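# metabotyper

A tested, reusable implementation of the statistical-genetics pipeline behind
large untargeted-metabolomics GWAS: per-cohort marginal association and
fixed-effect meta-analysis, LD-based definition of genomic regions, **exact
forward stepwise conditional analysis** on pooled individual-level data,
partitioning of each region's variant–metabolite associations into
**genetically influenced metabotypes (GIMs)**, causal-gene evidence scoring,
variance-explained partitioning by allele-frequency class, metabolite genetic
scores with phenome-wide association and Mendelian-randomization follow-up,
and Gaussian-graphical-model reconstruction of the metabolic network.  A
first-class synthetic-data module generates two discovery cohorts plus a
validation cohort with planted genetic architecture, so every stage is
testable end to end without access-controlled cohort data.

It is written for statistical geneticists and computational biologists who
want the bespoke parts of such an analysis — the conditional selection, the
GIM partitioning, the score-based phenome scan — as an importable, seeded,
unit-tested library rather than a one-off script stack.

## The statistics in brief

**Association and meta-analysis.** Within each cohort, metabolite residuals
(natural-log transformed, winsorized at ±5 s.d., covariate-residualized,
standardized) are regressed on allele dosage; cohort estimates are pooled by
inverse-variance weighting, β̂ = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/SEᵢ², after a
minor-allele-count filter (MAC > 10 per cohort).

**Regions.** Candidate associations (meta P < 5×10⁻⁸; P < 0.01, MAC > 10 and
sign-consistent in both cohorts) are peeled per metabolite into sentinel
intervals spanning LD partners (r² ≥ 0.1; ±500 kb for isolated sentinels);
sentinel intervals merge when sentinels are in LD (r² > 0.6), gain 250 kb of
padding, and are re-merged until disjoint.

**Conditional analysis.** Per (region, metabolite), forward selection over
regional variants at the Bonferroni threshold 0.05/(39 297 × 102) ≈
1.25×10⁻⁸, with per-step two-cohort consistency checks, followed by a joint
refit that drops variants not significant in the full model (falling back to
the lead variant alone when nothing survives).  The retained, conditionally
independent variants define a leave-one-out variance-explained partition
summed within MAF bins (rare ≤ 1% < low-frequency ≤ 5% < common).

**GIMs.** A matrix of conditional −log₁₀ P values over (variant, metabolite)
pairs is consumed greedily: the strongest pair (verified sign-consistent at
P < 0.01 in both cohorts) moves its variant to the output with the next
marker order, all entries are re-estimated conditional on the selection, and
the loop stops below −log₁₀(5×10⁻⁸).  GIMs are the connected components of
the bipartite significant-association graph; adjacent regions sharing a
metabolite are merged and recomputed.

**Follow-up.** Metabolite scores (weighted dosage sums over ≥ 2 genome-wide
significant, non-pleiotropic variants) enter logistic phecode regressions
under Benjamini–Hochberg FDR control at 5%; dose–response is assessed by IVW
pooling of per-variant Wald ratios with Cochran's Q and MR-Egger.  The
metabolic network is built from shrinkage partial correlations on multiply
imputed data (chained equations, 30 × 50), pooled by Rubin's rules on the
Fisher-z scale, meta-analyzed across cohorts, and thresholded at
|r| > 0.10/0.12/0.15.

## Worked example

```python
import metabotyper as mt
from metabotyper.synthetic_data import StudyConfig, simulate_study

cfg = StudyConfig(cohort_sizes=(4000, 3500, 2000), n_regions=2,
                  variance_explained=0.03)
study = simulate_study(cfg, seed=11)          # planted truth in study.truth
res = mt.run_discovery(study.cohorts)

print(f"regions: {len(res.regions)}   "
      f"conditional models: {len(res.models)}   GIMs: {len(res.gims)}")
for g in res.gims:
    print(f"  {g.id}: variants={sorted(g.variants)} "
          f"metabolites={list(g.metabolites)}")
rep = res.variance_report(res.models[0].metabolite)
print(f"variance explained for {res.models[0].metabolite}: "
      f"{100 * rep.grand_total:.1f}%")
```

prints

```
regions: 2   conditional models: 11   GIMs: 4
  R1_G1: variants=['1:1500000:A:G', '1:2000000:A:G'] metabolites=['M004', 'M005', 'M006']
  R1_G2: variants=['1:1000000:A:G'] metabolites=['M001', 'M002', 'M003']
  R2_G1: variants=['2:1000000:A:G', '2:1500000:A:G'] metabolites=['M007', 'M008', 'M009']
  R2_G2: variants=['2:2000000:A:G'] metabolites=['M010', 'M011']
variance explained for M001: 2.5%
```

Two regions are recovered, each partitioned into two GIMs whose variant and
metabolite sets match the planted architecture exactly; the fitted variance
explained (2.5%) recovers the planted 3% within sampling error.  The same
stages are scriptable from the shell (`metabotyper simulate / prep / assoc /
meta / discover / network`); see `metabotyper --help`.

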