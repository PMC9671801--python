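"""Genetically influenced metabotypes (GIMs) within a genomic region.

A region's variant-metabolite associations are partitioned by a greedy
matrix-based procedure followed by bipartite clustering:

1. ``matrix.ref`` holds signed -log10(P) for the conditional association of
   every not-yet-selected variant (union of the conditionally independent
   variants over all regional metabolites) with every regional metabolite,
   conditioning on the variants already moved to ``matrix.out``.
2. The (variant, metabolite) pair with the largest -log10(P) is selected,
   after verifying the pair has the same direction of effect with P < 0.01 in
   both discovery cohorts (a failing pair is masked and the next-best entry
   considered).  The variant moves to ``matrix.out`` with the next marker
   order, its row recording conditional associations with *all* regional
   metabolites given only lower-marker-order variants; ``matrix.ref`` is then
   recomputed from individual-level data.  The loop stops when no entry
   exceeds -log10(5e-8).
3. GIMs are the connected components of the bipartite graph over significant
   ``matrix.out`` entries: starting from a variant, take all metabolites it
   associates with, then all variants associated with any of those
   metabolites, until closure.

Adjacent regions (same chromosome, gap <= 1 Mb) that share a significantly
associated metabolite are merged and their GIMs recomputed, iterating to a
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .conditional import (ConditionalModel, PooledCohorts, _cohort_conditional,
                          conditional_scan)
from .regions import Region

__all__ = [
    "GIM_STOP_P",
    "GimMatrix",
    "GIM",
    "gim_select",
    "cluster_gims",
    "merge_adjacent",
]

GIM_STOP_P = 5e-8


@dataclass
class GimMatrix:
    """matrix.out: signed -log10(P) per selected variant x regional metabolite.

    Rows are ordered by marker order (selection rank); each row's entries are
    conditional on exactly the variants with lower marker order.
    """

    region_id: str
    entries: pd.DataFrame                 # variants (marker order) x metabolites
    marker_order: dict[str, int]

    def significant(self, threshold: float = GIM_STOP_P) -> pd.DataFrame:
        return self.entries.abs() > -np.log10(threshold)


@dataclass
class GIM:
    id: str
    region_id: str
    variants: dict[str, int]              # variant id -> marker order
    metabolites: tuple[str, ...]
    submatrix: pd.DataFrame = field(default_factory=pd.DataFrame)


def _signed_mlog10p(beta: np.ndarray, pval: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        m = -np.log10(np.clip(pval, 1e-320, None))
    return np.sign(np.nan_to_num(beta)) * m


def gim_select(region: Region,
               models: list[ConditionalModel],
               pooled: PooledCohorts,
               stop_threshold: float = GIM_STOP_P,
               cohort_p: float = 0.01,
               check_cohorts: bool = True) -> GimMatrix:
    """Greedy matrix.ref -> matrix.out selection for one region.

    ``models`` are the region's final conditional models (one per regional
    metabolite); their variant union forms the matrix.ref row universe.
    """
    metabolites: list[str] = []
    variants: list[str] = []
    for m in models:
        if m.region_id != region.id or not m.variants:
            continue
        if m.metabolite not in metabolites:
            metabolites.append(m.metabolite)
        for v in m.variant_ids:
            if v not in variants:
                variants.append(v)
    stop_mlog = -np.log10(stop_threshold)
    if not metabolites or not variants:
        return GimMatrix(region.id, pd.DataFrame(columns=metabolites), {})

    remaining = list(variants)
    selected: list[str] = []
    out_rows: dict[str, pd.Series] = {}
    masked: set[tuple[str, str]] = set()

    while remaining:
        ref = pd.DataFrame(index=remaining, columns=metabolites, dtype=float)
        for met in metabolites:
            beta, _, pval = conditional_scan(pooled, met, remaining, selected)
            ref[met] = _signed_mlog10p(beta, pval)
        flat = ref.abs().stack()
        flat = flat.drop(index=[k for k in masked if k in flat.index])
        chosen = None
        while len(flat):
            (var, met) = flat.idxmax()
            if flat.loc[(var, met)] <= stop_mlog:
                break
            if check_cohorts:
                ok = True
                signs = []
                for cid in pooled.cohort_ids:
                    b, p = _cohort_conditional(pooled, met, var, selected, cid)
                    if not np.isfinite(b) or p >= cohort_p:
                        ok = False
                        break
                    signs.append(np.sign(b))
                ok = ok and len(set(signs)) == 1
                if not ok:
                    masked.add((var, met))
                    flat = flat.drop(index=[(var, met)])
                    continue
            chosen = var
            break
        if chosen is None:
            break
        out_rows[chosen] = ref.loc[chosen]
        selected.append(chosen)
        remaining.remove(chosen)

    entries = (pd.DataFrame(out_rows).T.reindex(columns=metabolites)
               if out_rows else pd.DataFrame(columns=metabolites))
    marker_order = {v: k + 1 for k, v in enumerate(selected)}
    return GimMatrix(region_id=region.id, entries=entries,
                     marker_order=marker_order)


def cluster_gims(gim_matrix: GimMatrix,
                 threshold: float = GIM_STOP_P) -> list[GIM]:
    """Bipartite connected components over significant matrix.out entries.

    Components are enumerated seeded by ascending marker order of their
    variants; variants or metabolites with no significant entry fall into no
    GIM.
    """
    sig = gim_matrix.significant(threshold)
    g = nx.Graph()
    for var in sig.index:
        for met in sig.columns:
            if bool(sig.loc[var, met]):
                g.add_edge(("v", var), ("m", met))
    comps = []
    for comp in nx.connected_components(g):
        vs = {n[1] for n in comp if n[0] == "v"}
        ms = tuple(sorted(n[1] for n in comp if n[0] == "m"))
        if vs and ms:
            comps.append((vs, ms))
    comps.sort(key=lambda c: min(gim_matrix.marker_order[v] for v in c[0]))
    out = []
    for k, (vs, ms) in enumerate(comps, start=1):
        orders = {v: gim_matrix.marker_order[v] for v in sorted(vs)}
        sub = gim_matrix.entries.loc[sorted(vs, key=orders.get), list(ms)]
        out.append(GIM(id=f"{gim_matrix.region_id}_G{k}",
                       region_id=gim_matrix.region_id,
                       variants=orders, metabolites=ms, submatrix=sub))
    return out


def _gim_metabolites(gims: list[GIM], region_id: str) -> set[str]:
    out: set[str] = set()
    for g in gims:
        if g.region_id == region_id:
            out.update(g.metabolites)
    return out


def merge_adjacent(
    regions: list[Region],
    gims: list[GIM],
    recompute: Callable[[Region], tuple[list[ConditionalModel], GimMatrix, list[GIM]]],
    max_gap: int = 1_000_000,
) -> tuple[list[Region], list[GIM]]:
    """Merge adjacent regions sharing a significantly associated metabolite.

    ``recompute(region)`` reruns conditional analysis + GIM selection +
    clustering within a (merged) region and returns its models, matrix and
    GIMs.  Merging iterates until no adjacent same-chromosome pair with gap
    <= ``max_gap`` shares a metabolite.
    """
    regions = list(regions)
    gims = list(gims)
    changed = True
    while changed:
        changed = False
        regions.sort(key=lambda r: (r.chrom, r.start))
        for i in range(len(regions) - 1):
            a, b = regions[i], regions[i + 1]
            if a.chrom != b.chrom or b.start - a.end > max_gap:
                continue
            shared = (_gim_metabolites(gims, a.id)
                      & _gim_metabolites(gims, b.id))
            if not shared:
                continue
            merged = Region(id=a.id, chrom=a.chrom, start=a.start,
                            end=max(a.end, b.end),
                            sentinels=a.sentinels + b.sentinels,
                            members=sorted(set(a.members) | set(b.members)))
            _, _, new_gims = recompute(merged)
            gims = [g for g in gims if g.region_id not in (a.id, b.id)]
            gims.extend(new_gims)
            regions = [r for r in regions if r.id not in (a.id, b.id)]
            regions.append(merged)
            changed = True
            break
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions, gims
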