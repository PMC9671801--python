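"""Metabolite preprocessing: log-transform, winsorize, residualize, standardize.

Raw abundances are natural-log-transformed, winsorized at ``mean +/- k * s.d.``
(statistics computed once on the pre-winsorization log values), residualized on
the covariates by per-metabolite complete-case linear regression, and
standardized to mean 0, s.d. 1 (sample s.d., n - 1 denominator).  Metabolites
observed in fewer than ``min_n`` samples, or constant, are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PreparedMetabolites", "preprocess_metabolites", "standardize"]


@dataclass
class PreparedMetabolites:
    """Analysis-ready residuals with per-metabolite provenance.

    ``residuals`` has mean 0 and unit sample s.d. per retained metabolite over
    its non-missing entries; missing entries stay NaN.  ``inclusion_mask`` is
    indexed by the raw metabolite universe; ``provenance`` records the number
    of winsorized values and the complete-case n used per metabolite.
    """

    residuals: pd.DataFrame
    inclusion_mask: pd.Series
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def standardize(x: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Center and scale to unit sample s.d. (n - 1) over non-missing entries."""
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    return (x - mu) / sd


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    return pd.concat(parts, axis=1)


def preprocess_metabolites(
    raw: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    winsor_k: float = 5.0,
    min_n: int = 200,
) -> PreparedMetabolites:
    """Transform raw abundances into standardized covariate residuals.

    Parameters
    ----------
    raw : samples x metabolites abundances, strictly positive where observed.
    covariates : samples x covariates; categoricals are dummy-coded.  Samples
        missing any covariate are excluded for all metabolites.
    winsor_k : cap post-log values at mean +/- winsor_k * s.d.
    min_n : minimum non-missing sample count for a metabolite to be retained.

    Raises
    ------
    ValueError if any observed abundance is non-positive (the offending
    metabolite is named).
    """
    for col in raw.columns:
        vals = raw[col]
        if (vals.dropna() <= 0).any():
            raise ValueError(
                f"metabolite {col!r} has non-positive abundance values; "
                f"raw abundances must be strictly positive where observed"
            )

    logged = np.log(raw)

    if covariates is not None:
        design = _design(covariates)
        cov_complete = design.notna().all(axis=1)
    else:
        design = None
        cov_complete = pd.Series(True, index=raw.index)

    residuals = {}
    included = {}
    prov_rows = {}
    for col in logged.columns:
        x = logged[col].where(cov_complete)
        obs = x.notna()
        n_obs = int(obs.sum())
        if n_obs < min_n:
            included[col] = False
            prov_rows[col] = {"n": n_obs, "n_winsorized": 0, "reason": "min_n"}
            continue
        mu = x.mean()
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"metabolite {col!r} is constant; dropped")
            included[col] = False
            prov_rows[col] = {"n": n_obs, "n_winsorized": 0, "reason": "constant"}
            continue
        lo, hi = mu - winsor_k * sd, mu + winsor_k * sd
        n_wins = int(((x < lo) | (x > hi)).sum())
        x = x.clip(lo, hi)

        if design is not None:
            sub = design.loc[obs]
            # drop constant-within-subset dummies to keep X full rank
            keep = [c for c in sub.columns
                    if c == "const" or sub[c].nunique() > 1]
            X = sub[keep].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, x.loc[obs].to_numpy(), rcond=None)
            resid = x.loc[obs].to_numpy() - X @ beta
        else:
            resid = x.loc[obs].to_numpy() - x.loc[obs].mean()
        sd_r = resid.std(ddof=1)
        if sd_r == 0:
            warnings.warn(f"metabolite {col!r} has zero residual variance; dropped")
            included[col] = False
            prov_rows[col] = {"n": n_obs, "n_winsorized": n_wins,
                              "reason": "constant_residual"}
            continue
        out = pd.Series(np.nan, index=raw.index, name=col)
        out.loc[obs[obs].index] = (resid - resid.mean()) / sd_r
        residuals[col] = out
        included[col] = True
        prov_rows[col] = {"n": n_obs, "n_winsorized": n_wins, "reason": ""}

    res_df = (pd.DataFrame(residuals, index=raw.index)
              if residuals else pd.DataFrame(index=raw.index))
    return PreparedMetabolites(
        residuals=res_df,
        inclusion_mask=pd.Series(included, name="included"),
        provenance=pd.DataFrame.from_dict(prov_rows, orient="index"),
    )
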