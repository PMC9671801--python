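"""Per-cohort marginal association, IVW meta-analysis, filtering and LD.

Per-cohort tests are simple linear regressions of the standardized metabolite
residual on allele dosage (slope in s.d. per allele, two-sided P from the t
distribution with n - 2 df).  Cohort estimates are pooled by inverse-variance
weighted fixed-effect meta-analysis after a minor-allele-count (MAC > 10)
filter per cohort.  Candidate associations for region definition must reach
P < 5e-8 in the meta-analysis with P < 0.01, MAC > 10 and a consistent
direction of effect in both discovery cohorts; validation re-meta-analyzes
discovery plus validation at the Bonferroni threshold 5e-8 / n_metabolites
(5.48e-11 for 913 metabolites) requiring sign consistency in all three GWASs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import CohortData

__all__ = [
    "GENOME_WIDE_P",
    "validation_threshold",
    "marginal_assoc",
    "cohort_marginal_stats",
    "ivw_meta",
    "candidate_filter",
    "validate_association",
    "ld_r2",
]

GENOME_WIDE_P = 5e-8


def validation_threshold(n_metabolites: int = 913) -> float:
    """Bonferroni validation threshold: genome-wide 5e-8 over all metabolites."""
    return GENOME_WIDE_P / n_metabolites


def marginal_assoc(dosage: np.ndarray | pd.Series,
                   metabolite: np.ndarray | pd.Series,
                   min_n: int = 30) -> dict:
    """Simple-regression association of one metabolite on one dosage column.

    Returns a dict with beta, se, pval, mac, n; ``valid`` is False (with NaN
    statistics) for zero dosage variance or fewer than ``min_n`` complete
    observations.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(metabolite, dtype=float)
    ok = np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    n = g.size
    out = {"beta": np.nan, "se": np.nan, "pval": np.nan,
           "mac": 0, "n": n, "valid": False}
    if n < min_n:
        return out
    ac = g.sum()
    out["mac"] = int(round(min(ac, 2 * n - ac)))
    sxx = ((g - g.mean()) ** 2).sum()
    if sxx == 0:
        return out
    sxy = ((g - g.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    beta = sxy / sxx
    ss_res = max(syy - beta * sxy, 0.0)
    se = np.sqrt(ss_res / (n - 2) / sxx)
    if se == 0:
        return out
    t = beta / se
    out.update(beta=float(beta), se=float(se),
               pval=float(2 * stats.t.sf(abs(t), n - 2)), valid=True)
    return out


def cohort_marginal_stats(cohort: CohortData,
                          residuals: pd.DataFrame,
                          min_n: int = 30) -> pd.DataFrame:
    """All variant x metabolite marginal regressions for one cohort.

    Vectorized over variants within each metabolite's complete-case sample
    set.  Returns a long DataFrame (variant, metabolite, beta, se, pval, mac,
    n); invalid records (zero dosage variance, n < min_n) are excluded.
    """
    G_all = cohort.dosages.to_numpy(dtype=float)
    variants = cohort.dosages.columns.to_numpy()
    frames = []
    for met in residuals.columns:
        y_full = residuals[met].reindex(cohort.dosages.index).to_numpy(dtype=float)
        ok = np.isfinite(y_full)
        n = int(ok.sum())
        if n < min_n:
            continue
        y = y_full[ok]
        G = G_all[ok]
        gm = G.mean(axis=0)
        Gc = G - gm
        sxx = (Gc ** 2).sum(axis=0)
        valid = sxx > 0
        yc = y - y.mean()
        sxy = Gc.T @ yc
        syy = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(valid, sxy / np.where(sxx == 0, np.nan, sxx), np.nan)
            ss_res = np.maximum(syy - beta * sxy, 0.0)
            se = np.sqrt(ss_res / (n - 2) / np.where(sxx == 0, np.nan, sxx))
        valid &= np.nan_to_num(se) > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            pval = 2 * stats.t.sf(np.abs(beta / se), n - 2)
        ac = G.sum(axis=0)
        mac = np.minimum(ac, 2 * n - ac).round().astype(int)
        frames.append(pd.DataFrame({
            "variant": variants[valid], "metabolite": met,
            "beta": beta[valid], "se": se[valid], "pval": pval[valid],
            "mac": mac[valid], "n": n}))
    if not frames:
        return pd.DataFrame(columns=["variant", "metabolite", "beta", "se",
                                     "pval", "mac", "n"])
    return pd.concat(frames, ignore_index=True)


def ivw_meta(cohort_stats: dict[str, pd.DataFrame],
             mac_threshold: int = 10) -> pd.DataFrame:
    """Inverse-variance weighted fixed-effect meta-analysis across cohorts.

    Cohorts with MAC <= ``mac_threshold`` for a record are excluded before
    pooling; records with no contributing cohort are dropped.  Output columns:
    variant, metabolite, beta_meta, se_meta, pval_meta, n_meta,
    direction_consistent, plus beta/se/pval/mac per cohort (suffixed).
    """
    if not cohort_stats:
        raise ValueError("at least one cohort required")
    merged: pd.DataFrame | None = None
    names = list(cohort_stats)
    for name in names:
        df = cohort_stats[name].rename(columns={
            c: f"{c}_{name}" for c in ("beta", "se", "pval", "mac", "n")})
        merged = df if merged is None else merged.merge(
            df, on=["variant", "metabolite"], how="outer")
    assert merged is not None

    betas = merged[[f"beta_{n}" for n in names]].to_numpy(dtype=float)
    ses = merged[[f"se_{n}" for n in names]].to_numpy(dtype=float)
    macs = merged[[f"mac_{n}" for n in names]].to_numpy()
    ns = merged[[f"n_{n}" for n in names]].to_numpy()
    contributing = (np.nan_to_num(macs, nan=0.0) > mac_threshold) & np.isfinite(ses)
    w = np.where(contributing, 1.0 / ses**2, 0.0)
    wsum = w.sum(axis=1)
    any_contrib = wsum > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_meta = (w * np.nan_to_num(betas)).sum(axis=1) / wsum
        se_meta = 1.0 / np.sqrt(wsum)
    z = beta_meta / se_meta
    pval_meta = 2 * stats.norm.sf(np.abs(z))

    signs = np.sign(np.where(contributing, betas, np.nan))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        smax, smin = np.nanmax(signs, axis=1), np.nanmin(signs, axis=1)
    direction = (smax == smin) & np.isfinite(smax)

    out = merged.copy()
    out["beta_meta"] = beta_meta
    out["se_meta"] = se_meta
    out["pval_meta"] = pval_meta
    out["n_meta"] = np.where(contributing, np.nan_to_num(ns), 0).sum(axis=1).astype(int)
    out["direction_consistent"] = direction
    out["mlog10p"] = -np.log10(np.clip(pval_meta, 1e-320, None))
    return out.loc[any_contrib].reset_index(drop=True)


def candidate_filter(records: pd.DataFrame,
                     discovery_cohorts: tuple[str, str] = ("discovery1", "discovery2"),
                     meta_p: float = GENOME_WIDE_P,
                     cohort_p: float = 0.01,
                     mac_threshold: int = 10) -> pd.DataFrame:
    """Associations taken forward to region definition.

    Retains records with meta P < ``meta_p`` AND, in *both* discovery cohorts,
    P < ``cohort_p``, MAC > ``mac_threshold`` and the same direction of effect.
    """
    keep = records["pval_meta"] < meta_p
    c1, c2 = discovery_cohorts
    for c in discovery_cohorts:
        keep &= records[f"pval_{c}"].fillna(1.0) < cohort_p
        keep &= records[f"mac_{c}"].fillna(0) > mac_threshold
    keep &= (np.sign(records[f"beta_{c1}"]) == np.sign(records[f"beta_{c2}"]))
    return records.loc[keep.fillna(False)].reset_index(drop=True)


def validate_association(
    discovery_stats: dict[str, pd.DataFrame],
    validation_stats: pd.DataFrame,
    pairs: pd.DataFrame,
    validation_cohort: str = "validation",
    threshold: float | None = None,
    n_metabolites: int = 913,
    mac_threshold: int = 10,
) -> pd.DataFrame:
    """Validation verdicts for sentinel variant-metabolite pairs.

    Re-meta-analyzes discovery + validation per pair; a pair is ``validated``
    iff the combined P is below the Bonferroni threshold (default
    5e-8 / n_metabolites) and all three per-cohort effects share a sign.
    Pairs whose variant is absent from the validation statistics are marked
    ``untestable``.
    """
    if threshold is None:
        threshold = validation_threshold(n_metabolites)
    all_stats = dict(discovery_stats)
    all_stats[validation_cohort] = validation_stats
    combined = ivw_meta(all_stats, mac_threshold=mac_threshold)
    idx = combined.set_index(["variant", "metabolite"])
    names = list(all_stats)

    rows = []
    for _, p in pairs.iterrows():
        key = (p["variant"], p["metabolite"])
        row = {"variant": key[0], "metabolite": key[1],
               "validated": False, "untestable": False,
               "pval_combined": np.nan}
        if key not in idx.index:
            row["untestable"] = True
        else:
            rec = idx.loc[key]
            row["pval_combined"] = float(rec["pval_meta"])
            betas = [rec.get(f"beta_{n}", np.nan) for n in names]
            if any(not np.isfinite(b) for b in betas):
                row["untestable"] = True
            else:
                signs = set(np.sign(betas))
                row["validated"] = (rec["pval_meta"] < threshold
                                    and len(signs) == 1 and 0.0 not in signs)
        rows.append(row)
    return pd.DataFrame(rows)


def ld_r2(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of dosage columns (complete-case).

    Zero-variance columns get NaN rows/columns (flagged); the diagonal is 1
    for well-defined columns.
    """
    X = dosages.to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    X = X[ok]
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r2 = r**2
    np.fill_diagonal(r2, np.where(bad, np.nan, 1.0))
    return pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns)
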