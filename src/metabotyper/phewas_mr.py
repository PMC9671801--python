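"""Metabolite genetic scores, phenome-wide association, and MR follow-up.

For each metabolite with at least two associated, non-pleiotropic variants
(marginal meta P < 5e-8; associated with fewer than five metabolites), a
per-sample weighted score sums allele dosages weighted by the marginal effect.
Standardized scores are tested against binary phecodes by logistic regression
(odds ratio per 1 s.d. of score), with Benjamini-Hochberg control of the
false discovery rate at 5% across all score-phecode pairs.  Dose-response is
assessed in a two-sample-style MR framework: inverse-variance weighted
pooling of per-variant Wald ratios, Cochran's Q for heterogeneity
(first-order ratio SEs), and MR-Egger regression for directional pleiotropy;
"strong evidence" requires >= 3 variants in the score and no heterogeneity
(Q P > 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteScore",
    "MRResult",
    "build_score",
    "pleiotropy_counts",
    "phewas",
    "bh_fdr",
    "mr_dose_response",
]

SCORE_P = 5e-8
MAX_METABOLITES_PER_VARIANT = 5
MIN_SCORE_VARIANTS = 2


@dataclass
class MetaboliteScore:
    metabolite: str
    weights: pd.Series                   # variant -> marginal beta
    scores: pd.Series                    # per-sample weighted dosage sum
    n_variants: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_variants = len(self.weights)


def pleiotropy_counts(marginal: pd.DataFrame,
                      p_threshold: float = SCORE_P) -> pd.Series:
    """Number of metabolites each variant is associated with at P < threshold."""
    sig = marginal.loc[marginal["pval_meta"] < p_threshold]
    return sig.groupby("variant")["metabolite"].nunique()


def build_score(metabolite: str,
                variants: list[str],
                marginal: pd.DataFrame,
                dosages: pd.DataFrame,
                p_threshold: float = SCORE_P,
                max_metabolites: int = MAX_METABOLITES_PER_VARIANT,
                min_variants: int = MIN_SCORE_VARIANTS) -> MetaboliteScore | None:
    """Weighted genetic score for one metabolite, or None if underpowered.

    ``variants`` are the metabolite's conditionally independent variants;
    each must reach marginal meta P < ``p_threshold`` for the metabolite and
    be associated with fewer than ``max_metabolites`` metabolites overall.
    Weights are the marginal meta-analysis effects.
    """
    counts = pleiotropy_counts(marginal, p_threshold)
    own = marginal.loc[marginal["metabolite"] == metabolite].set_index("variant")
    weights = {}
    for v in variants:
        if v not in own.index or own.loc[v, "pval_meta"] >= p_threshold:
            continue
        if counts.get(v, 0) >= max_metabolites:
            continue
        if v not in dosages.columns:
            continue
        weights[v] = float(own.loc[v, "beta_meta"])
    if len(weights) < min_variants:
        return None
    w = pd.Series(weights, name=metabolite)
    score = dosages[w.index].to_numpy(dtype=float) @ w.to_numpy()
    return MetaboliteScore(metabolite=metabolite, weights=w,
                           scores=pd.Series(score, index=dosages.index,
                                            name=metabolite))


def phewas(score: MetaboliteScore,
           phecodes: pd.DataFrame,
           covariates: pd.DataFrame | None = None,
           min_cases: int = 50) -> pd.DataFrame:
    """Logistic regressions of each phecode on the standardized score.

    Returns one row per tested phecode: metabolite, phecode, or (per 1 s.d.
    of score), log_or, se, pval, n_cases, n_controls, flagged (True when the
    fit failed, e.g. perfect separation; pval is then NaN).  Phecodes with
    fewer than ``min_cases`` cases are skipped.
    """
    z = score.scores
    z = (z - z.mean()) / z.std(ddof=1)
    base = [pd.Series(1.0, index=z.index, name="const"), z.rename("score")]
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if pd.api.types.is_numeric_dtype(s):
                base.append(s.astype(float))
            else:
                d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
                base.extend(d[c] for c in d.columns)
    X = pd.concat(base, axis=1)

    rows = []
    for code in phecodes.columns:
        y = phecodes[code].reindex(z.index)
        ok = y.notna() & X.notna().all(axis=1)
        yv = y[ok].to_numpy(dtype=float)
        n_cases = int(yv.sum())
        n_controls = int(len(yv) - n_cases)
        if n_cases < min_cases or n_controls < min_cases:
            continue
        row = {"metabolite": score.metabolite, "phecode": code,
               "or_per_sd": np.nan, "log_or": np.nan, "se": np.nan,
               "pval": np.nan, "n_cases": n_cases, "n_controls": n_controls,
               "flagged": False}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yv, X[ok].to_numpy(dtype=float)).fit(disp=0)
            j = list(X.columns).index("score")
            if not np.isfinite(fit.bse[j]) or fit.bse[j] > 100:
                raise ValueError("unstable fit (quasi-separation)")
            row.update(log_or=float(fit.params[j]),
                       or_per_sd=float(np.exp(fit.params[j])),
                       se=float(fit.bse[j]), pval=float(fit.pvalues[j]))
        except Exception:
            row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(pvals: pd.Series | np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up: (q values, boolean discovery mask)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    if isinstance(pvals, pd.Series):
        return (pd.Series(qvals, index=pvals.index, name="qval"),
                pd.Series(reject, index=pvals.index, name="significant"))
    return qvals, reject


@dataclass
class MRResult:
    estimate: float
    se: float
    pval: float
    cochran_q: float
    het_pval: float
    n_variants: int
    egger_intercept: float = np.nan
    egger_intercept_pval: float = np.nan
    egger_slope: float = np.nan
    strong_evidence: bool = False


def mr_dose_response(beta_exposure: np.ndarray,
                     se_exposure: np.ndarray,
                     beta_outcome: np.ndarray,
                     se_outcome: np.ndarray) -> MRResult:
    """IVW pooling of Wald ratios with Cochran's Q and MR-Egger.

    Per-variant causal estimates are Wald ratios beta_outcome /
    beta_exposure with first-order SEs se_outcome / |beta_exposure|.  With a
    single variant the IVW estimate is that ratio.  Egger fields require
    >= 3 variants.  ``strong_evidence`` is True iff n >= 3 and the Q
    heterogeneity P exceeds 0.05.
    """
    be = np.asarray(beta_exposure, dtype=float)
    bo = np.asarray(beta_outcome, dtype=float)
    so = np.asarray(se_outcome, dtype=float)
    if be.size < 1:
        raise ValueError("at least one variant required")
    if np.any(be == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    ratios = bo / be
    se_r = so / np.abs(be)
    w = 1.0 / se_r**2
    est = float((w * ratios).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    pval = float(2 * stats.norm.sf(abs(est / se)))
    q = float((w * (ratios - est) ** 2).sum())
    k = be.size
    het_pval = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0

    res = MRResult(estimate=est, se=se, pval=pval, cochran_q=q,
                   het_pval=het_pval, n_variants=int(k))
    if k >= 3:
        # orient exposure effects positive, as in standard MR-Egger
        sign = np.sign(be)
        X = sm.add_constant(be * sign)
        fit = sm.WLS(bo * sign, X, weights=1.0 / so**2).fit()
        res.egger_intercept = float(fit.params[0])
        res.egger_intercept_pval = float(fit.pvalues[0])
        res.egger_slope = float(fit.params[1])
    res.strong_evidence = bool(k >= 3 and het_pval > 0.05)
    return res
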