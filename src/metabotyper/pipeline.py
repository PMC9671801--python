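"""End-to-end discovery pipeline tying the analysis stages together.

Runs preprocessing, per-cohort marginal GWAS, IVW meta-analysis, candidate
filtering, LD-based region definition, exact stepwise conditional analysis,
and GIM partitioning (with adjacent-region merging) on a set of cohorts.
This is the orchestration layer used by the CLI, the acceptance script and
the recovery tests; each stage is importable on its own from its module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, conditional, gim, preprocess, regions
from .synthetic_data import CohortData

__all__ = ["DiscoveryResult", "run_discovery", "regional_metabolites"]


@dataclass
class DiscoveryResult:
    residuals: dict[str, pd.DataFrame]
    marginal: pd.DataFrame                      # meta-analyzed records
    candidates: pd.DataFrame
    ld: pd.DataFrame
    regions: list[regions.Region]
    pooled: conditional.PooledCohorts
    models: list[conditional.ConditionalModel]
    gim_matrices: dict[str, gim.GimMatrix]
    gims: list[gim.GIM] = field(default_factory=list)

    @property
    def mafs(self) -> pd.Series:
        freq = self.pooled.dosages.mean(axis=0) / 2.0
        return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)

    def variance_report(self, metabolite: str) -> conditional.VarianceReport:
        return conditional.variance_partition(self.models, metabolite,
                                              self.pooled, self.mafs)


def _attach_positions(records: pd.DataFrame) -> pd.DataFrame:
    parsed = records["variant"].map(regions.parse_vid)
    records = records.copy()
    records["chrom"] = [c for c, _ in parsed]
    records["pos"] = [p for _, p in parsed]
    return records


def regional_metabolites(region: regions.Region,
                         candidates: pd.DataFrame) -> list[str]:
    """Metabolites with a candidate association inside the region."""
    inside = candidates["variant"].isin(region.members)
    return sorted(candidates.loc[inside, "metabolite"].unique())


def _eligible_region_variants(region: regions.Region,
                              marginal: pd.DataFrame,
                              metabolite: str,
                              discovery_ids: tuple[str, str],
                              cohort_p: float = 0.01) -> list[str]:
    """Region variants with consistent direction and P < 0.01 in both cohorts
    (marginal screen; the stepwise procedure re-checks conditionally)."""
    sub = marginal[(marginal["metabolite"] == metabolite)
                   & marginal["variant"].isin(region.members)]
    c1, c2 = discovery_ids
    ok = ((sub[f"pval_{c1}"].fillna(1.0) < cohort_p)
          & (sub[f"pval_{c2}"].fillna(1.0) < cohort_p)
          & (np.sign(sub[f"beta_{c1}"]) == np.sign(sub[f"beta_{c2}"])))
    keep = sub.loc[ok.fillna(False)]
    return sorted(keep["variant"], key=regions.parse_vid)


def run_discovery(cohorts: dict[str, CohortData],
                  discovery_ids: tuple[str, str] = ("discovery1", "discovery2"),
                  min_n: int = 200,
                  conditional_p: float = conditional.CONDITIONAL_P,
                  gim_stop_p: float = gim.GIM_STOP_P,
                  merge_adjacent_regions: bool = True,
                  check_cohorts: bool = True) -> DiscoveryResult:
    """Full discovery-stage analysis on the named discovery cohorts."""
    residuals: dict[str, pd.DataFrame] = {}
    stats: dict[str, pd.DataFrame] = {}
    for cid in discovery_ids:
        c = cohorts[cid]
        prep = preprocess.preprocess_metabolites(
            c.metabolites, c.covariates, min_n=min(min_n, c.n_samples // 2))
        residuals[cid] = prep.residuals
        stats[cid] = association.cohort_marginal_stats(c, prep.residuals)

    marginal = association.ivw_meta(stats)
    candidates = association.candidate_filter(marginal,
                                              discovery_cohorts=discovery_ids)
    candidates = _attach_positions(candidates)

    # LD reference: the largest discovery cohort
    ld_ref = max(discovery_ids, key=lambda cid: cohorts[cid].n_samples)
    ld = association.ld_r2(cohorts[ld_ref].dosages)

    region_list = regions.define_regions(candidates, ld)
    pooled = conditional.pool_cohorts(
        {cid: cohorts[cid] for cid in discovery_ids},
        {cid: residuals[cid] for cid in discovery_ids})

    def analyze_region(region: regions.Region):
        models = []
        for met in regional_metabolites(region, candidates):
            eligible = _eligible_region_variants(region, marginal, met,
                                                 discovery_ids)
            if not eligible:
                continue
            model = conditional.stepwise_conditional(
                region.id, met, eligible, pooled, threshold=conditional_p,
                check_cohorts=check_cohorts)
            model = conditional.final_joint(model, pooled,
                                            threshold=conditional_p)
            if model.variants:
                models.append(model)
        matrix = gim.gim_select(region, models, pooled,
                                stop_threshold=gim_stop_p,
                                check_cohorts=check_cohorts)
        gims = gim.cluster_gims(matrix, threshold=gim_stop_p)
        return models, matrix, gims

    all_models: list[conditional.ConditionalModel] = []
    matrices: dict[str, gim.GimMatrix] = {}
    all_gims: list[gim.GIM] = []
    for region in region_list:
        models, matrix, gims_r = analyze_region(region)
        all_models.extend(models)
        matrices[region.id] = matrix
        all_gims.extend(gims_r)

    if merge_adjacent_regions:
        def recompute(region: regions.Region):
            models, matrix, gims_r = analyze_region(region)
            nonlocal all_models, matrices
            all_models = [m for m in all_models if m.region_id != region.id]
            all_models.extend(models)
            matrices[region.id] = matrix
            return models, matrix, gims_r

        region_list, all_gims = gim.merge_adjacent(region_list, all_gims,
                                                   recompute)

    return DiscoveryResult(residuals=residuals, marginal=marginal,
                           candidates=candidates, ld=ld, regions=region_list,
                           pooled=pooled, models=all_models,
                           gim_matrices=matrices, gims=all_gims)
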