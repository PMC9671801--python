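"""Stepwise conditional analysis, joint pruning, variance partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metabotyper as mt
from metabotyper.conditional import (CONDITIONAL_P, conditional_threshold,
                                     final_joint, maf_bin, pool_cohorts,
                                     stepwise_conditional, variance_partition)
from metabotyper.synthetic_data import (CausalEntry, StudyConfig, TruthTable,
                                        VariantSpec, beta_for_variance,
                                        simulate_genotypes,
                                        simulate_metabolites, simulate_study,
                                        split_cohorts)


def test_threshold_is_bonferroni_over_regional_tests():
    # 0.05 / (39,297 variants x 102 metabolites), 3 significant figures
    assert conditional_threshold(39_297, 102) == pytest.approx(1.25e-8)
    assert CONDITIONAL_P == pytest.approx(1.25e-8)


def _pooled_from(dosages, truth, mets, seed, sizes=None):
    met = simulate_metabolites(dosages, truth, metabolites=mets, seed=seed)
    cov = pd.DataFrame({"age": np.zeros(len(dosages))}, index=dosages.index)
    n = len(dosages)
    sizes = sizes or (n // 2, n - n // 2, 0)
    cohorts = split_cohorts(dosages, met, cov, sizes, seed=seed)
    from metabotyper.preprocess import preprocess_metabolites
    residuals = {}
    for cid in ("discovery1", "discovery2"):
        prep = preprocess_metabolites(cohorts[cid].metabolites,
                                      min_n=10)
        residuals[cid] = prep.residuals
    return pool_cohorts({c: cohorts[c] for c in ("discovery1", "discovery2")},
                        residuals)


def _locus(n_proxies=10, n=8000, ve=0.02, seed=0, maf=0.3):
    rng = np.random.default_rng(seed)
    variants = [VariantSpec("1", 1_000_000, maf_target=maf)]
    offsets = rng.choice(np.arange(1000, 40_000, 1000), n_proxies,
                         replace=False)
    for off in np.sort(offsets):
        variants.append(VariantSpec("1", 1_000_000 + int(off),
                                    maf_target=maf))
    variants.sort(key=lambda v: v.pos)
    dosages = simulate_genotypes(variants, n, ld_decay=1e-5, seed=seed)
    causal = "1:1000000:A:G"
    truth = TruthTable(causal_entries=[
        CausalEntry(causal, "M1", beta_for_variance(ve, maf), ve)])
    return variants, dosages, causal, truth


def test_single_causal_variant_recovered_alone():
    variants, dosages, causal, truth = _locus(seed=1)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=1)
    model = stepwise_conditional("R1", "M1", [v.vid for v in variants], pooled)
    model = final_joint(model, pooled)
    assert len(model.variants) == 1
    picked = model.variants[0].variant
    from metabotyper.association import ld_r2
    r2 = ld_r2(pooled.dosages)
    assert r2.loc[picked, causal] > 0.9


def test_two_independent_causal_variants_selected_stronger_first():
    variants = [VariantSpec("1", 1_000_000, maf_target=0.3),
                VariantSpec("1", 9_000_000, maf_target=0.3)]
    dosages = simulate_genotypes(variants, 8000, ld_decay=1e-5, seed=2)
    truth = TruthTable(causal_entries=[
        CausalEntry(variants[0].vid, "M1",
                    beta_for_variance(0.04, 0.3), 0.04),
        CausalEntry(variants[1].vid, "M1",
                    beta_for_variance(0.02, 0.3), 0.02)])
    pooled = _pooled_from(dosages, truth, ["M1"], seed=2)
    model = stepwise_conditional("R1", "M1", [v.vid for v in variants], pooled)
    model = final_joint(model, pooled)
    assert model.variant_ids == [variants[0].vid, variants[1].vid]
    assert not model.fallback


def test_joint_model_prunes_subthreshold_variants():
    # second variant independent but too weak for the joint threshold
    variants = [VariantSpec("1", 1_000_000, maf_target=0.3),
                VariantSpec("1", 9_000_000, maf_target=0.3)]
    dosages = simulate_genotypes(variants, 6000, ld_decay=1e-5, seed=3)
    truth = TruthTable(causal_entries=[
        CausalEntry(variants[0].vid, "M1",
                    beta_for_variance(0.05, 0.3), 0.05),
        CausalEntry(variants[1].vid, "M1",
                    beta_for_variance(0.002, 0.3), 0.002)])
    pooled = _pooled_from(dosages, truth, ["M1"], seed=3)
    model = stepwise_conditional("R1", "M1", [v.vid for v in variants],
                                 pooled, threshold=1e-4, check_cohorts=False)
    assert len(model.variant_ids) == 2
    model = final_joint(model, pooled, threshold=CONDITIONAL_P)
    assert model.variant_ids == [variants[0].vid]


def test_fallback_retains_lead_when_nothing_reaches_threshold():
    variants, dosages, causal, truth = _locus(n_proxies=3, n=2000, ve=0.005,
                                              seed=4)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=4)
    model = stepwise_conditional("R1", "M1", [v.vid for v in variants], pooled)
    model = final_joint(model, pooled)
    assert model.fallback
    assert len(model.variants) == 1


def test_no_eligible_variants_yields_empty_model():
    variants, dosages, _, truth = _locus(n_proxies=2, seed=5)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=5)
    model = stepwise_conditional("R1", "M1", [], pooled)
    assert model.variants == []


def test_selection_path_matches_exhaustive_forward_oracle():
    """On small regions the stepwise path must equal a brute-force forward
    search that refits every candidate model with plain least squares."""
    rng = np.random.default_rng(6)
    for rep in range(4):
        variants = [VariantSpec("1", 500_000 + i * 120_000,
                                maf_target=float(rng.uniform(0.1, 0.45)))
                    for i in range(6)]
        dosages = simulate_genotypes(variants, 4000, ld_decay=5e-6,
                                     seed=60 + rep)
        picks = rng.choice(6, size=2, replace=False)
        entries = [CausalEntry(variants[j].vid, "M1",
                               beta_for_variance(0.03, variants[j].maf_target),
                               0.03) for j in picks]
        pooled = _pooled_from(dosages, TruthTable(causal_entries=entries),
                              ["M1"], seed=60 + rep)
        model = stepwise_conditional("R", "M1", [v.vid for v in variants],
                                     pooled, check_cohorts=False)

        # oracle: naive forward search with statsmodels OLS at every step
        import statsmodels.api as sm
        y = pooled.residuals["M1"].to_numpy()
        ok = np.isfinite(y)
        base = pooled.covariates[ok]
        path, remaining = [], [v.vid for v in variants]
        while remaining:
            best = None
            for cand in remaining:
                cols = path + [cand]
                X = np.column_stack(
                    [base, pooled.dosages.loc[:, cols].to_numpy()[ok]])
                fit = sm.OLS(y[ok], X).fit()
                p = fit.pvalues[-1]
                if best is None or p < best[1]:
                    best = (cand, p)
            if best[1] >= CONDITIONAL_P:
                break
            path.append(best[0])
            remaining.remove(best[0])
        assert model.variant_ids == path or (model.fallback and not path)


def test_joint_r2_monotone_during_selection():
    variants, dosages, _, truth = _locus(n_proxies=6, seed=7, ve=0.03)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=7)
    y = pooled.residuals["M1"].to_numpy()
    ok = np.isfinite(y)
    model = stepwise_conditional("R1", "M1",
                                 [v.vid for v in variants], pooled,
                                 threshold=1e-3, check_cohorts=False)
    r2s = []
    for k in range(1, len(model.variants) + 1):
        cols = model.variant_ids[:k]
        X = np.column_stack([pooled.covariates[ok],
                             pooled.dosages.loc[:, cols].to_numpy()[ok]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        r2s.append(1 - resid.var() / y[ok].var())
    assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


def test_null_regions_select_nothing():
    variants = [VariantSpec("1", 1_000_000 + i * 400_000, maf_target=0.3)
                for i in range(5)]
    dosages = simulate_genotypes(variants, 3000, ld_decay=1e-4, seed=8)
    pooled = _pooled_from(dosages, TruthTable(), ["Mnull"], seed=8)
    selected = 0
    for rep in range(20):
        model = stepwise_conditional("R", "Mnull",
                                     [v.vid for v in variants], pooled)
        if not model.fallback:
            selected += len(model.variants)
    assert selected == 0


def test_variance_partition_single_variant_matches_planted():
    variants, dosages, causal, truth = _locus(n_proxies=0, n=10_000, ve=0.05,
                                              seed=9)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=9)
    model = stepwise_conditional("R1", "M1", [causal], pooled)
    model = final_joint(model, pooled)
    mafs = pd.Series({causal: 0.3})
    rep = variance_partition([model], "M1", pooled, mafs)
    assert abs(rep.grand_total - 0.05) / 0.05 < 0.20
    assert rep.bin_totals["common"] == pytest.approx(rep.grand_total)
    assert sum(rep.bin_totals.values()) == pytest.approx(rep.grand_total,
                                                         abs=1e-10)


def test_variance_partition_orthogonal_contributions_sum_exactly():
    variants = [VariantSpec("1", 1_000_000, maf_target=0.2),
                VariantSpec("1", 50_000_000, maf_target=0.4)]
    dosages = simulate_genotypes(variants, 6000, ld_decay=1e-4, seed=10)
    truth = TruthTable(causal_entries=[
        CausalEntry(variants[0].vid, "M1", beta_for_variance(0.03, 0.2), 0.03),
        CausalEntry(variants[1].vid, "M1", beta_for_variance(0.03, 0.4), 0.03)])
    pooled = _pooled_from(dosages, truth, ["M1"], seed=10)
    model = stepwise_conditional("R1", "M1", [v.vid for v in variants], pooled)
    model = final_joint(model, pooled)
    mafs = pd.Series({variants[0].vid: 0.2, variants[1].vid: 0.005})
    rep = variance_partition([model], "M1", pooled, mafs)
    assert rep.per_variant.sum() == pytest.approx(rep.grand_total, abs=1e-10)
    assert sum(rep.bin_totals.values()) == pytest.approx(rep.grand_total,
                                                         abs=1e-10)
    assert rep.bin_totals["rare"] > 0  # MAF 0.005 counted in the rare bin


@pytest.mark.parametrize("maf,expected", [
    (0.005, "rare"), (0.01, "rare"), (0.03, "low_frequency"),
    (0.05, "low_frequency"), (0.2, "common")])
def test_maf_bins(maf, expected):
    assert maf_bin(maf) == expected


def test_empty_model_gives_zero_report():
    variants, dosages, causal, truth = _locus(n_proxies=0, seed=11)
    pooled = _pooled_from(dosages, truth, ["M1"], seed=11)
    rep = variance_partition([], "M1", pooled, pd.Series({causal: 0.3}))
    assert rep.grand_total == 0.0
    assert sum(rep.bin_totals.values()) == 0.0
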