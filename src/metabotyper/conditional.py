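"""Exact forward stepwise conditional analysis on pooled individual-level data.

For each (region, metabolite), forward selection over the region's candidate
variants: at every step, each remaining eligible variant is tested conditional
on the variants already selected (plus a cohort-indicator covariate), and the
variant with the smallest conditional P enters the model; selection stops when
no conditional P falls below the region-wide Bonferroni threshold
0.05 / (39,297 x 102) ~= 1.25e-8 (the largest variant and metabolite counts
tested at any region).  Eligibility is re-checked at every step: the candidate
must have the same direction of effect with conditional P < 0.01 in both
discovery cohorts.  A final joint model refits all selected variants and drops
those not significant at the same threshold; if nothing (including the lead)
survives, the lead variant alone is retained with a fallback flag.

Variance explained by the retained (conditionally independent) variants is
partitioned per variant by leave-one-out from the joint model, any shared R^2
being allocated proportionally, and summed within MAF bins (rare <= 1%,
low-frequency (1%, 5%], common > 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CohortData

__all__ = [
    "CONDITIONAL_P",
    "conditional_threshold",
    "PooledCohorts",
    "pool_cohorts",
    "SelectedVariant",
    "ConditionalModel",
    "VarianceReport",
    "conditional_scan",
    "stepwise_conditional",
    "final_joint",
    "variance_partition",
    "maf_bin",
]


def conditional_threshold(n_variants: int = 39_297,
                          n_metabolites: int = 102) -> float:
    """Region-wide Bonferroni threshold 0.05 / (n_variants * n_metabolites),
    rounded to 3 significant figures (1.25e-8 at the default counts)."""
    raw = 0.05 / (n_variants * n_metabolites)
    from math import floor, log10
    exp = floor(log10(raw))
    return round(raw, -exp + 2)


CONDITIONAL_P = conditional_threshold()


@dataclass
class PooledCohorts:
    """Discovery cohorts stacked, with a cohort-indicator design matrix."""

    dosages: pd.DataFrame
    residuals: pd.DataFrame
    cohort_labels: np.ndarray
    covariates: np.ndarray  # intercept + cohort dummies (+ optional PCs)
    cohort_ids: tuple[str, ...]

    def cohort_mask(self, cohort_id: str) -> np.ndarray:
        return self.cohort_labels == cohort_id


def pool_cohorts(cohorts: dict[str, CohortData],
                 residuals: dict[str, pd.DataFrame],
                 extra_covariates: pd.DataFrame | None = None) -> PooledCohorts:
    """Stack discovery cohorts for exact conditional analysis.

    Residuals are the per-cohort preprocessed (already standardized,
    covariate-adjusted) metabolite matrices; the pooled design retains an
    intercept and fixed cohort effects, mirroring adjustment for study.
    """
    ids = tuple(cohorts)
    dos = pd.concat([cohorts[c].dosages for c in ids], axis=0,
                    keys=ids, names=["cohort", "sample"])
    res = pd.concat([residuals[c] for c in ids], axis=0,
                    keys=ids, names=["cohort", "sample"])
    res = res.reindex(dos.index)
    labels = dos.index.get_level_values("cohort").to_numpy()
    design = [np.ones(len(dos))]
    for c in ids[1:]:
        design.append((labels == c).astype(float))
    if extra_covariates is not None:
        design.extend(np.asarray(extra_covariates[c], dtype=float)
                      for c in extra_covariates.columns)
    return PooledCohorts(dosages=dos, residuals=res, cohort_labels=labels,
                         covariates=np.column_stack(design), cohort_ids=ids)


@dataclass
class SelectedVariant:
    variant: str
    step: int
    beta_cond: float
    se_cond: float
    p_cond: float
    beta_joint: float = np.nan
    se_joint: float = np.nan
    p_joint: float = np.nan


@dataclass
class ConditionalModel:
    region_id: str
    metabolite: str
    variants: list[SelectedVariant] = field(default_factory=list)
    fallback: bool = False

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant for v in self.variants]


def _partial_regression(y: np.ndarray, G: np.ndarray, X: np.ndarray):
    """Conditional slope/SE/P of each column of G given X (Frisch-Waugh).

    Returns (beta, se, pval) arrays; the t test uses n - rank(X) - 1 df,
    identical to the candidate's coefficient test in the full OLS fit.
    """
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    RG = G - Q @ (Q.T @ G)
    sxx = (RG**2).sum(axis=0)
    df = len(y) - Q.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (RG.T @ ry) / sxx
        ss_res = np.maximum(ry @ ry - beta * (RG.T @ ry), 0.0)
        se = np.sqrt(ss_res / df / sxx)
        t = beta / se
    pval = 2 * stats.t.sf(np.abs(t), df)
    bad = (sxx <= 1e-12) | ~np.isfinite(se) | (se == 0)
    beta[bad], se[bad], pval[bad] = np.nan, np.nan, 1.0
    return beta, se, pval


def conditional_scan(pooled: PooledCohorts, metabolite: str,
                     candidates: list[str], selected: list[str]):
    """Pooled conditional statistics for each candidate given the selection."""
    y_full = pooled.residuals[metabolite].to_numpy(dtype=float)
    ok = np.isfinite(y_full)
    y = y_full[ok]
    G = pooled.dosages.loc[:, candidates].to_numpy(dtype=float)[ok]
    X = pooled.covariates[ok]
    if selected:
        X = np.column_stack([X, pooled.dosages.loc[:, selected]
                             .to_numpy(dtype=float)[ok]])
    return _partial_regression(y, G, X)


def _cohort_conditional(pooled: PooledCohorts, metabolite: str,
                        candidate: str, selected: list[str],
                        cohort_id: str) -> tuple[float, float]:
    """(beta, p) for the candidate's conditional test within one cohort."""
    mask = pooled.cohort_mask(cohort_id)
    y_full = pooled.residuals[metabolite].to_numpy(dtype=float)[mask]
    ok = np.isfinite(y_full)
    y = y_full[ok]
    g = pooled.dosages[candidate].to_numpy(dtype=float)[mask][ok, None]
    X = np.ones((len(y), 1))
    if selected:
        X = np.column_stack([X, pooled.dosages.loc[:, selected]
                             .to_numpy(dtype=float)[mask][ok]])
    beta, _, p = _partial_regression(y, g, X)
    return float(beta[0]), float(p[0])


def _eligible_in_cohorts(pooled: PooledCohorts, metabolite: str,
                         candidate: str, selected: list[str],
                         cohort_p: float = 0.01) -> bool:
    betas = []
    for cid in pooled.cohort_ids:
        b, p = _cohort_conditional(pooled, metabolite, candidate, selected, cid)
        if not np.isfinite(b) or p >= cohort_p:
            return False
        betas.append(np.sign(b))
    return len(set(betas)) == 1


def stepwise_conditional(region_id: str,
                         metabolite: str,
                         region_variants: list[str],
                         pooled: PooledCohorts,
                         threshold: float = CONDITIONAL_P,
                         cohort_p: float = 0.01,
                         check_cohorts: bool = True,
                         max_steps: int | None = None) -> ConditionalModel:
    """Forward stepwise selection phase.

    Candidates failing the per-step two-cohort consistency check are skipped
    in favor of the next-best conditional P.  If no variant reaches the
    threshold at the first step, the lead (best conditional P) is retained
    with the fallback flag (pruned later by :func:`final_joint`).
    """
    model = ConditionalModel(region_id=region_id, metabolite=metabolite)
    remaining = list(region_variants)
    step = 0
    while remaining and (max_steps is None or step < max_steps):
        beta, se, pval = conditional_scan(pooled, metabolite, remaining,
                                          model.variant_ids)
        order = np.argsort(pval, kind="stable")
        chosen = None
        for k in order:
            if not np.isfinite(beta[k]) or pval[k] >= threshold:
                break
            if check_cohorts and not _eligible_in_cohorts(
                    pooled, metabolite, remaining[k], model.variant_ids,
                    cohort_p):
                continue
            chosen = int(k)
            break
        if chosen is None and step == 0:
            # no regional variant reaches the threshold: condition on the
            # lead variant anyway and mark the model as a fallback
            for k in order:
                if np.isfinite(beta[k]):
                    chosen = int(k)
                    model.fallback = True
                    break
        if chosen is None:
            break
        step += 1
        model.variants.append(SelectedVariant(
            variant=remaining[chosen], step=step,
            beta_cond=float(beta[chosen]), se_cond=float(se[chosen]),
            p_cond=float(pval[chosen])))
        remaining.pop(chosen)
    return model


def _joint_fit(pooled: PooledCohorts, metabolite: str, variants: list[str]):
    """Joint OLS of the metabolite on all variants + covariates.

    Returns (kept_variants, beta, se, pval); perfectly collinear dosage
    columns are dropped later-selected-first with a warning.
    """
    y_full = pooled.residuals[metabolite].to_numpy(dtype=float)
    ok = np.isfinite(y_full)
    y = y_full[ok]
    C = pooled.covariates[ok]
    kept = list(variants)
    while kept:
        G = pooled.dosages.loc[:, kept].to_numpy(dtype=float)[ok]
        X = np.column_stack([C, G])
        rank = np.linalg.matrix_rank(X)
        if rank == X.shape[1]:
            break
        warnings.warn(f"collinear selected variant {kept[-1]!r} dropped")
        kept.pop()
    if not kept:
        return [], np.array([]), np.array([]), np.array([])
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se_all = np.sqrt(sigma2 * np.diag(XtX_inv))
    k0 = C.shape[1]
    beta = coef[k0:]
    se = se_all[k0:]
    pval = 2 * stats.t.sf(np.abs(beta / se), df)
    return kept, beta, se, pval


def final_joint(model: ConditionalModel,
                pooled: PooledCohorts,
                threshold: float = CONDITIONAL_P) -> ConditionalModel:
    """Joint refit of selected variants; prune those with joint P >= threshold.

    If zero variants pass (including the lead), the lead alone is retained
    and the fallback flag set.
    """
    if not model.variants:
        return model
    kept, beta, se, pval = _joint_fit(pooled, model.metabolite,
                                      model.variant_ids)
    by_id = {v.variant: v for v in model.variants}
    for vid, b, s, p in zip(kept, beta, se, pval):
        rec = by_id[vid]
        rec.beta_joint, rec.se_joint, rec.p_joint = float(b), float(s), float(p)
    surviving = [by_id[vid] for vid, p in zip(kept, pval) if p < threshold]
    if not surviving:
        lead = model.variants[0]
        if lead.variant not in kept or not np.isfinite(lead.p_joint):
            k, b, s, p = _joint_fit(pooled, model.metabolite, [lead.variant])
            if k:
                lead.beta_joint, lead.se_joint, lead.p_joint = (
                    float(b[0]), float(s[0]), float(p[0]))
        model.variants = [lead]
        model.fallback = True
        return model
    model.variants = surviving
    model.fallback = False
    if len(surviving) < len(kept) or len(kept) < len(by_id):
        # refit the pruned model so reported joint stats match what is kept
        kept2, beta2, se2, pval2 = _joint_fit(
            pooled, model.metabolite, [v.variant for v in surviving])
        for vid, b, s, p in zip(kept2, beta2, se2, pval2):
            rec = by_id[vid]
            rec.beta_joint, rec.se_joint, rec.p_joint = (float(b), float(s),
                                                         float(p))
    return model


def maf_bin(maf: float) -> str:
    """rare: MAF <= 1%; low-frequency: 1% < MAF <= 5%; common: MAF > 5%."""
    if maf <= 0.01:
        return "rare"
    if maf <= 0.05:
        return "low_frequency"
    return "common"


@dataclass
class VarianceReport:
    metabolite: str
    per_variant: pd.Series
    bin_totals: dict[str, float]
    grand_total: float


def _r2(y: np.ndarray, G: np.ndarray, C: np.ndarray) -> float:
    """R^2 attributable to G after partialling out C (covariates)."""
    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    if G.shape[1] == 0:
        return 0.0
    RG = G - Q @ (Q.T @ G)
    coef, *_ = np.linalg.lstsq(RG, ry, rcond=None)
    fitted = RG @ coef
    tss = float(ry @ ry)
    return float(fitted @ fitted) / tss if tss > 0 else 0.0


def variance_partition(models: list[ConditionalModel],
                       metabolite: str,
                       pooled: PooledCohorts,
                       mafs: pd.Series) -> VarianceReport:
    """Leave-one-out partition of the joint-model R^2 by variant and MAF bin.

    The grand total is the joint R^2 over all retained variants across the
    metabolite's regions; each variant's contribution is the decrease in R^2
    when it is dropped; any shared R^2 (grand total minus the sum of
    contributions) is allocated proportionally so bin totals sum exactly to
    the grand total.
    """
    variants: list[str] = []
    for m in models:
        if m.metabolite == metabolite:
            variants.extend(v for v in m.variant_ids if v not in variants)
    if not variants:
        return VarianceReport(metabolite, pd.Series(dtype=float),
                              {"rare": 0.0, "low_frequency": 0.0,
                               "common": 0.0}, 0.0)
    y_full = pooled.residuals[metabolite].to_numpy(dtype=float)
    ok = np.isfinite(y_full)
    y = y_full[ok]
    C = pooled.covariates[ok]
    G = pooled.dosages.loc[:, variants].to_numpy(dtype=float)[ok]
    grand = _r2(y, G, C)
    loo = np.empty(len(variants))
    for j in range(len(variants)):
        loo[j] = grand - _r2(y, np.delete(G, j, axis=1), C)
    loo = np.maximum(loo, 0.0)
    total_loo = loo.sum()
    if total_loo > 0:
        contrib = loo * (grand / total_loo)
    else:
        contrib = np.full(len(variants), grand / len(variants))
    per_variant = pd.Series(contrib, index=variants, name="r2")
    bins = {"rare": 0.0, "low_frequency": 0.0, "common": 0.0}
    for vid, c in per_variant.items():
        bins[maf_bin(float(mafs[vid]))] += float(c)
    return VarianceReport(metabolite=metabolite, per_variant=per_variant,
                          bin_totals=bins, grand_total=float(grand))


def models_to_frame(models: list[ConditionalModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for v in m.variants:
            rows.append({"region": m.region_id, "metabolite": m.metabolite,
                         "variant": v.variant, "step": v.step,
                         "beta_cond": v.beta_cond, "se_cond": v.se_cond,
                         "p_cond": v.p_cond, "beta_joint": v.beta_joint,
                         "se_joint": v.se_joint, "p_joint": v.p_joint,
                         "fallback": m.fallback})
    return pd.DataFrame(rows)
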