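"""Marginal regression, IVW meta-analysis, filters, validation and LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabotyper.association import (candidate_filter, cohort_marginal_stats,
                                     ivw_meta, ld_r2, marginal_assoc,
                                     validate_association,
                                     validation_threshold)


def _records(**overrides):
    base = {
        "variant": "1:100:A:G", "metabolite": "M1",
        "beta_discovery1": 0.5, "se_discovery1": 0.05,
        "pval_discovery1": 1e-5, "mac_discovery1": 100, "n_discovery1": 1000,
        "beta_discovery2": 0.5, "se_discovery2": 0.05,
        "pval_discovery2": 1e-5, "mac_discovery2": 100, "n_discovery2": 1000,
        "pval_meta": 1e-9, "beta_meta": 0.5, "se_meta": 0.04,
        "direction_consistent": True,
    }
    base.update(overrides)
    return pd.DataFrame([base])


def test_marginal_beta_recovery():
    rng = np.random.default_rng(0)
    n = 5000
    g = rng.binomial(2, 0.3, n).astype(float)
    gz = (g - g.mean()) / g.std(ddof=1)
    y = 0.3 * gz + rng.normal(0, 0.1, n)
    rec = marginal_assoc(gz, y)
    assert rec["valid"]
    assert abs(rec["beta"] - 0.3) < 3 * rec["se"]


def test_marginal_p_matches_independent_regression_oracle():
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.2, 200).astype(float)
    y = rng.standard_normal(200)
    rec = marginal_assoc(g, y)
    oracle = stats.linregress(g, y)
    assert rec["beta"] == pytest.approx(oracle.slope, rel=1e-12)
    assert rec["se"] == pytest.approx(oracle.stderr, rel=1e-10)
    assert rec["pval"] == pytest.approx(oracle.pvalue, rel=1e-10)


def test_marginal_null_type_one_error():
    rng = np.random.default_rng(2)
    n = 400
    y = rng.standard_normal(n)
    pvals = []
    for _ in range(1000):
        g = rng.binomial(2, 0.3, n).astype(float)
        pvals.append(marginal_assoc(g, y)["pval"])
    frac = np.mean(np.array(pvals) < 0.05)
    assert 0.03 <= frac <= 0.07


def test_marginal_degenerate_inputs():
    assert not marginal_assoc(np.zeros(100), np.random.default_rng(0)
                              .standard_normal(100))["valid"]
    assert not marginal_assoc(np.ones(10), np.ones(10), min_n=30)["valid"]


def test_ivw_equal_weights_is_mean():
    stats_by = {
        "a": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.5,
                            "se": 0.1, "pval": 1e-6, "mac": 50, "n": 100}]),
        "b": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.5,
                            "se": 0.1, "pval": 1e-6, "mac": 50, "n": 100}]),
    }
    out = ivw_meta(stats_by)
    assert out["beta_meta"].iloc[0] == pytest.approx(0.5)
    assert out["se_meta"].iloc[0] == pytest.approx(0.1 / np.sqrt(2))


def test_ivw_hand_computed_example():
    stats_by = {
        "a": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.2,
                            "se": 0.1, "pval": 0.05, "mac": 50, "n": 100}]),
        "b": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.6,
                            "se": 0.2, "pval": 0.01, "mac": 50, "n": 100}]),
    }
    out = ivw_meta(stats_by)
    assert out["beta_meta"].iloc[0] == pytest.approx(0.28)
    assert out["se_meta"].iloc[0] == pytest.approx(1 / np.sqrt(125))


def test_ivw_single_contributing_cohort_is_identity():
    stats_by = {
        "a": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.4,
                            "se": 0.08, "pval": 1e-5, "mac": 50, "n": 100}]),
        "b": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": -0.9,
                            "se": 0.5, "pval": 0.2, "mac": 5, "n": 100}]),
    }
    out = ivw_meta(stats_by)  # cohort b fails MAC > 10
    assert out["beta_meta"].iloc[0] == pytest.approx(0.4)
    assert out["se_meta"].iloc[0] == pytest.approx(0.08)
    assert bool(out["direction_consistent"].iloc[0])  # only one sign present


def test_ivw_drops_records_failing_mac_everywhere():
    stats_by = {
        "a": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.4,
                            "se": 0.08, "pval": 1e-5, "mac": 3, "n": 100}]),
        "b": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.5,
                            "se": 0.1, "pval": 1e-4, "mac": 2, "n": 100}]),
    }
    assert len(ivw_meta(stats_by)) == 0


def test_meta_se_never_exceeds_best_cohort_se(small_study):
    from metabotyper.preprocess import preprocess_metabolites
    per = {}
    for cid in ("discovery1", "discovery2"):
        c = small_study.cohorts[cid]
        prep = preprocess_metabolites(c.metabolites, c.covariates, min_n=100)
        per[cid] = cohort_marginal_stats(c, prep.residuals)
    out = ivw_meta(per)
    ses = out[["se_discovery1", "se_discovery2"]].min(axis=1)
    assert (out["se_meta"] <= ses + 1e-12).all()


def test_candidate_filter_requires_both_cohorts_nominal():
    rec = _records(pval_discovery2=0.02)
    assert len(candidate_filter(rec)) == 0


def test_candidate_filter_requires_direction_consistency():
    rec = _records(beta_discovery2=-0.5, pval_discovery2=0.005)
    assert len(candidate_filter(rec)) == 0


def test_candidate_filter_meta_threshold_boundary():
    assert len(candidate_filter(_records(pval_meta=4e-8))) == 1
    assert len(candidate_filter(_records(pval_meta=6e-8))) == 0


def test_validation_threshold_is_bonferroni_over_metabolites():
    thr = validation_threshold(913)
    assert thr == pytest.approx(5.48e-11, rel=0.01)


def test_validation_verdicts():
    disc = {
        "d1": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.5,
                             "se": 0.05, "pval": 1e-20, "mac": 60, "n": 2000}]),
        "d2": pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.45,
                             "se": 0.05, "pval": 1e-18, "mac": 60, "n": 2000}]),
    }
    pairs = pd.DataFrame([{"variant": "v", "metabolite": "m"}])
    val_ok = pd.DataFrame([{"variant": "v", "metabolite": "m", "beta": 0.5,
                            "se": 0.06, "pval": 1e-15, "mac": 60, "n": 2000}])
    out = validate_association(disc, val_ok, pairs)
    assert bool(out["validated"].iloc[0])

    val_flip = val_ok.assign(beta=-0.5)
    out = validate_association(disc, val_flip, pairs)
    assert not bool(out["validated"].iloc[0])

    val_absent = pd.DataFrame([{"variant": "other", "metabolite": "m",
                                "beta": 0.5, "se": 0.06, "pval": 1e-15,
                                "mac": 60, "n": 2000}])
    out = validate_association(disc, val_absent, pairs)
    assert bool(out["untestable"].iloc[0])


def test_ld_identity_and_sign_invariance():
    rng = np.random.default_rng(3)
    g = pd.DataFrame({"a": rng.binomial(2, 0.3, 500).astype(float)})
    g["b"] = 2 - g["a"]
    r2 = ld_r2(g)
    assert r2.loc["a", "a"] == pytest.approx(1.0)
    assert r2.loc["a", "b"] == pytest.approx(1.0)


def test_ld_matches_pearson_oracle_on_toy_vectors():
    g = pd.DataFrame({"g1": [0, 1, 2, 0, 1], "g2": [0, 1, 1, 1, 0]},
                     dtype=float)
    r2 = ld_r2(g)
    oracle = stats.pearsonr(g["g1"], g["g2"])[0] ** 2
    assert r2.loc["g1", "g2"] == pytest.approx(oracle, rel=1e-12)


def test_ld_zero_variance_column_flagged():
    g = pd.DataFrame({"a": [0.0, 1, 2, 1], "flat": [1.0, 1, 1, 1]})
    r2 = ld_r2(g)
    assert np.isnan(r2.loc["flat", "a"])
    assert np.isnan(r2.loc["flat", "flat"])
    assert r2.loc["a", "a"] == pytest.approx(1.0)


def test_validation_stage_confirms_planted_sentinels(small_study):
    """Sentinel pairs from the discovery stage validate in the held-out
    cohort: combined three-GWAS meta P below the Bonferroni threshold with
    sign consistency everywhere."""
    import metabotyper as mt
    from metabotyper.preprocess import preprocess_metabolites

    res = mt.run_discovery(small_study.cohorts)
    per = {}
    for cid in ("discovery1", "discovery2", "validation"):
        c = small_study.cohorts[cid]
        prep = preprocess_metabolites(c.metabolites, c.covariates, min_n=100)
        per[cid] = cohort_marginal_stats(c, prep.residuals)
    pairs = pd.DataFrame(
        [{"variant": s.sentinel, "metabolite": s.metabolite}
         for r in res.regions for s in r.sentinels]).drop_duplicates()
    verdicts = validate_association(
        {c: per[c] for c in ("discovery1", "discovery2")}, per["validation"],
        pairs, n_metabolites=per["discovery1"]["metabolite"].nunique())
    assert not verdicts["untestable"].any()
    assert verdicts["validated"].mean() >= 0.9
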