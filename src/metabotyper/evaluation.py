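"""Recovery benchmarks scoring the pipeline against planted architecture.

Each routine simulates data under the study conditions, runs the relevant
pipeline stage, and scores the result against the simulation truth table:
GIM partition recovery (adjusted Rand index), stepwise-selection agreement
with a naive exhaustive forward-search oracle, cross-cohort effect-size
concordance, variance-explained recovery, false-discovery control of the
phenome scan under a global null, Mendelian-randomization effect recovery,
and sparse-structure recovery of the Gaussian graphical model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import association, conditional, network, phewas_mr, pipeline
from .preprocess import preprocess_metabolites
from .synthetic_data import (CausalEntry, PhecodeEffect, StudyConfig,
                             TruthTable, VariantSpec, beta_for_variance,
                             simulate_genotypes, simulate_metabolites,
                             simulate_phecodes, simulate_study, split_cohorts)

__all__ = [
    "gim_recovery_ari",
    "stepwise_oracle_agreement",
    "cross_cohort_concordance",
    "variance_recovery",
    "phewas_null_fdp",
    "mr_recovery",
    "ggm_structure_f1",
]


def _partition_labels(groups, metabolites):
    label = {}
    for k, mets in enumerate(groups):
        for m in mets:
            label[m] = k
    return [label.get(m, -1) for m in metabolites]


def gim_recovery_ari(n_replicates: int = 20,
                     n_per_cohort: int = 8000,
                     n_regions: int = 3,
                     seed: int = 0) -> float:
    """Mean adjusted Rand index between recovered and planted metabolite
    partitions over replicate two-cohort simulations."""
    scores = []
    for rep in range(n_replicates):
        cfg = StudyConfig(cohort_sizes=(n_per_cohort, n_per_cohort, 2),
                          n_regions=n_regions, gims_per_region=(2, 3),
                          variance_explained=0.02, n_phecodes=0)
        study = simulate_study(cfg, seed=seed * 10_000 + rep)
        res = pipeline.run_discovery(study.cohorts)
        mets = study.truth.metabolites
        planted = _partition_labels(
            [g.metabolites for g in study.truth.planted_gims], mets)
        got = _partition_labels([g.metabolites for g in res.gims], mets)
        scores.append(adjusted_rand_score(planted, got))
    return float(np.mean(scores))


def _naive_forward_search(pooled, metabolite, variants, threshold):
    """Brute-force forward selection refitting full OLS models with
    statsmodels at every step (independent of the QR-based implementation)."""
    import statsmodels.api as sm

    y_full = pooled.residuals[metabolite].to_numpy()
    ok = np.isfinite(y_full)
    y = y_full[ok]
    base = pooled.covariates[ok]
    path, remaining = [], list(variants)
    while remaining:
        best = None
        for cand in remaining:
            X = np.column_stack(
                [base, pooled.dosages.loc[:, path + [cand]].to_numpy()[ok]])
            fit = sm.OLS(y, X).fit()
            p = fit.pvalues[-1]
            if best is None or p < best[1]:
                best = (cand, p)
        if best[1] >= threshold:
            break
        path.append(best[0])
        remaining.remove(best[0])
    return path


def stepwise_oracle_agreement(n_regions: int = 8, seed: int = 0) -> float:
    """Fraction of small (<= 6 variant) regions where the stepwise selection
    path equals the exhaustive forward-search oracle's path."""
    rng = np.random.default_rng(seed)
    agree = 0
    for rep in range(n_regions):
        k = int(rng.integers(3, 7))
        variants = [VariantSpec("1", 500_000 + i * 150_000,
                                maf_target=float(rng.uniform(0.1, 0.45)))
                    for i in range(k)]
        dosages = simulate_genotypes(variants, 4000, ld_decay=5e-6,
                                     seed=seed * 1000 + rep)
        n_causal = int(rng.integers(1, 3))
        picks = rng.choice(k, size=n_causal, replace=False)
        entries = [CausalEntry(variants[j].vid, "M1",
                               beta_for_variance(0.03, variants[j].maf_target),
                               0.03) for j in picks]
        mets = simulate_metabolites(dosages, TruthTable(causal_entries=entries),
                                    seed=seed * 1000 + rep)
        cov = pd.DataFrame({"age": np.zeros(len(dosages))},
                           index=dosages.index)
        cohorts = split_cohorts(dosages, mets, cov, (2000, 2000, 0),
                                seed=seed * 1000 + rep)
        residuals = {c: preprocess_metabolites(cohorts[c].metabolites,
                                               min_n=10).residuals
                     for c in ("discovery1", "discovery2")}
        pooled = conditional.pool_cohorts(
            {c: cohorts[c] for c in ("discovery1", "discovery2")}, residuals)
        model = conditional.stepwise_conditional(
            "R", "M1", [v.vid for v in variants], pooled, check_cohorts=False)
        oracle = _naive_forward_search(pooled, "M1", [v.vid for v in variants],
                                       conditional.CONDITIONAL_P)
        if model.fallback and not oracle:
            agree += 1
        elif model.variant_ids == oracle:
            agree += 1
    return agree / n_regions


def cross_cohort_concordance(n_per_cohort: int = 5000,
                             n_variants: int = 40,
                             seed: int = 0) -> tuple[float, float, int]:
    """(slope, R^2, n_pairs) of cohort-2 effect estimates regressed on
    cohort-1 estimates over genome-wide-significant shared true effects,
    spanning common to rare (large-effect) variants."""
    rng = np.random.default_rng(seed)
    variants, entries = [], []
    for i in range(n_variants):
        rare = i % 4 == 0
        maf = float(rng.uniform(0.005, 0.012)) if rare \
            else float(rng.uniform(0.05, 0.45))
        v = VariantSpec(str(i + 1), 1_000_000, maf_target=maf)
        variants.append(v)
        ve = float(rng.uniform(0.015, 0.05))
        sign = float(rng.choice([-1.0, 1.0]))
        entries.append(CausalEntry(v.vid, f"M{i:03d}",
                                   sign * beta_for_variance(ve, maf), ve))
    dosages = simulate_genotypes(variants, 2 * n_per_cohort, seed=seed)
    mets = simulate_metabolites(dosages, TruthTable(causal_entries=entries),
                                seed=seed)
    cov = pd.DataFrame({"age": np.zeros(len(dosages))}, index=dosages.index)
    cohorts = split_cohorts(dosages, mets, cov,
                            (n_per_cohort, n_per_cohort, 0), seed=seed)
    per = {}
    for cid in ("discovery1", "discovery2"):
        c = cohorts[cid]
        prep = preprocess_metabolites(c.metabolites, min_n=100)
        per[cid] = association.cohort_marginal_stats(c, prep.residuals)
    meta = association.ivw_meta(per)
    sig = meta.loc[meta["pval_meta"] < association.GENOME_WIDE_P]
    fit = stats.linregress(sig["beta_discovery1"], sig["beta_discovery2"])
    return float(fit.slope), float(fit.rvalue**2), int(len(sig))


def variance_recovery(n_samples: int = 10_000,
                      seed: int = 0) -> tuple[float, float, float, dict]:
    """(relative error of the total variance explained, planted total,
    fitted grand total, MAF-bin totals).

    One metabolite with rare, low-frequency and common causal variants;
    the stepwise + joint model is fitted and its leave-one-out variance
    partition compared with the planted variance-explained targets.
    """
    layout = [(0.008, 0.02), (0.03, 0.02), (0.30, 0.04)]  # (maf, VE)
    variants = [VariantSpec("1", 1_000_000 + 2_000_000 * i, maf_target=maf)
                for i, (maf, _) in enumerate(layout)]
    entries = [CausalEntry(v.vid, "M1", beta_for_variance(ve, maf), ve)
               for v, (maf, ve) in zip(variants, layout)]
    dosages = simulate_genotypes(variants, n_samples, ld_decay=1e-4, seed=seed)
    mets = simulate_metabolites(dosages, TruthTable(causal_entries=entries),
                                seed=seed)
    cov = pd.DataFrame({"age": np.zeros(n_samples)}, index=dosages.index)
    half = n_samples // 2
    cohorts = split_cohorts(dosages, mets, cov, (half, n_samples - half, 0),
                            seed=seed)
    residuals = {c: preprocess_metabolites(cohorts[c].metabolites,
                                           min_n=100).residuals
                 for c in ("discovery1", "discovery2")}
    pooled = conditional.pool_cohorts(
        {c: cohorts[c] for c in ("discovery1", "discovery2")}, residuals)
    model = conditional.stepwise_conditional(
        "R", "M1", [v.vid for v in variants], pooled)
    model = conditional.final_joint(model, pooled)
    freq = pooled.dosages.mean(axis=0) / 2
    mafs = pd.concat([freq, 1 - freq], axis=1).min(axis=1)
    report = conditional.variance_partition([model], "M1", pooled, mafs)
    planted = sum(ve for _, ve in layout)
    rel_err = abs(report.grand_total - planted) / planted
    return (float(rel_err), float(planted), float(report.grand_total),
            report.bin_totals)


def phewas_null_fdp(n_phecodes: int = 1000,
                    n_replicates: int = 100,
                    n_samples: int = 2000,
                    prevalence: float = 0.1,
                    seed: int = 0) -> float:
    """Mean false-discovery proportion of the BH-controlled phenome scan on a
    fully null phenome (every discovery is false by construction)."""
    rng = np.random.default_rng(seed)
    score = phewas_mr.MetaboliteScore(
        metabolite="M0", weights=pd.Series({"v1": 1.0, "v2": 1.0}),
        scores=pd.Series(rng.standard_normal(n_samples)))
    fdps = []
    for rep in range(n_replicates):
        codes = pd.DataFrame(
            (rng.random((n_samples, n_phecodes)) < prevalence).astype(np.int8),
            columns=[f"P{j}" for j in range(n_phecodes)])
        out = phewas_mr.phewas(score, codes)
        pv = out["pval"].dropna()
        _, sig = phewas_mr.bh_fdr(pv, q=0.05)
        n_disc = int(np.asarray(sig).sum())
        fdps.append(n_disc / max(n_disc, 1) if n_disc else 0.0)
    return float(np.mean(fdps))


def mr_recovery(true_effect: float = 0.25,
                n_instruments: int = 6,
                n_replicates: int = 100,
                seed: int = 0):
    """(mean |estimate - truth| / SE over replicates, fraction within 3 SE,
    Egger intercept false-positive rate under no pleiotropy)."""
    rng = np.random.default_rng(seed)
    zs, within, egger_fp = [], 0, 0
    for rep in range(n_replicates):
        be = rng.uniform(0.2, 0.6, n_instruments)
        se_b = np.full(n_instruments, 0.01)
        se_o = np.full(n_instruments, 0.02)
        bo = true_effect * be + rng.normal(0, se_o)
        res = phewas_mr.mr_dose_response(be, se_b, bo, se_o)
        zs.append(abs(res.estimate - true_effect) / res.se)
        within += int(abs(res.estimate - true_effect) <= 3 * res.se)
        egger_fp += int(res.egger_intercept_pval < 0.05)
    return (float(np.mean(zs)), within / n_replicates,
            egger_fp / n_replicates)


def ggm_structure_f1(n_metabolites: int = 20,
                     n_edges: int = 25,
                     n_samples: int = 3000,
                     cutoff: float = 0.10,
                     seed: int = 0) -> float:
    """F1 of edge recovery for a planted sparse precision matrix."""
    rng = np.random.default_rng(seed)
    p = n_metabolites
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = [pairs[k] for k in rng.choice(len(pairs), n_edges, replace=False)]
    prec = np.eye(p)
    for i, j in chosen:
        w = float(rng.choice([-1.0, 1.0])) * 0.28
        prec[i, j] = prec[j, i] = w
    # enforce positive definiteness by diagonal loading
    lam = np.linalg.eigvalsh(prec).min()
    if lam < 0.3:
        prec += (0.3 - lam) * np.eye(p)
    cov = np.linalg.inv(prec)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n_samples)
    df = pd.DataFrame(X, columns=[f"M{j:02d}" for j in range(p)])
    pc = network.partial_correlations(df).to_numpy()
    got = {(i, j) for i, j in pairs if abs(pc[i, j]) > cutoff}
    truth = set(chosen)
    tp = len(got & truth)
    prec_ = tp / len(got) if got else 0.0
    rec = tp / len(truth)
    return 2 * prec_ * rec / (prec_ + rec) if (prec_ + rec) else 0.0
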