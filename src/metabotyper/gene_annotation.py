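"""Candidate causal-gene evidence near GIM variants, and IEM-gene enrichment.

Gene and protein names often encode their biochemical substrate (e.g.
phenylalanine hydroxylase), so candidate genes around a lead variant are
scored by fuzzy text matching of metabolite names/synonyms against gene,
protein, disease and GO-process names, plus exact pathway co-occurrence and
interacting-protein lookups.  The fuzzy metric is the Dice coefficient over
character trigrams of case-folded, alphanumeric-only strings, thresholded at
0.5.  Disease names are cleaned of IEM-nomenclature stop words (suffixes and
tokens such as "uria", "emia", "deficiency") before matching; GO biological
process names are cleaned of generic substrings ("metabolic process", ...)
and terms with >= 500 member genes are excluded.

Enrichment of genes known to cause inborn errors of metabolism (IEMs) among a
tested gene set is assessed against the genome-wide background proportion
785 / 19,817 (~4%) with a two-tailed binomial test (minimum-likelihood
method).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import pandas as pd
from scipy import stats

__all__ = [
    "GeneEvidence",
    "EnrichmentResult",
    "AnnotationResources",
    "load_disease_stopwords",
    "load_go_stop_substrings",
    "normalize_text",
    "trigrams",
    "fuzzy_score",
    "strip_disease_stopwords",
    "strip_go_substrings",
    "rank_nearest_genes",
    "annotate_gim",
    "iem_enrichment",
]

N_PROTEIN_CODING_GENES = 19_817
N_IEM_GENES = 785
GO_MAX_GENES = 500
FUZZY_CUTOFF = 0.5
N_CLOSEST_GENES = 20

EVIDENCE_SOURCES = ("gene_name", "protein_name", "class_name", "disease_name",
                    "interacting_protein", "pathway_map", "go_bp")


def _load_lines(name: str) -> list[str]:
    text = (importlib_resources.files("metabotyper") / "data" / name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_disease_stopwords() -> list[str]:
    return _load_lines("disease_stopwords.txt")


def load_go_stop_substrings() -> list[str]:
    return _load_lines("go_stop_substrings.txt")


def normalize_text(s: str) -> str:
    """Case-fold and drop every non-alphanumeric character."""
    return "".join(ch for ch in s.casefold() if ch.isalnum())


def trigrams(s: str) -> frozenset[str]:
    """Character trigrams of the normalized string (whole string if < 3)."""
    norm = normalize_text(s)
    if not norm:
        return frozenset()
    if len(norm) < 3:
        return frozenset({norm})
    return frozenset(norm[i:i + 3] for i in range(len(norm) - 2))


def fuzzy_score(a: str, b: str) -> float:
    """Symmetric trigram Dice similarity in [0, 1]; 0 if either is empty."""
    ta, tb = trigrams(a), trigrams(b)
    if not ta or not tb:
        return 0.0
    return 2.0 * len(ta & tb) / (len(ta) + len(tb))


def strip_disease_stopwords(name: str,
                            stopwords: list[str] | None = None) -> str:
    """Remove IEM-nomenclature stop words from a disease name.

    Stop words are removed as whole tokens and as token prefixes/suffixes
    (the list contains affixes like "uria", "emia", "hyper"), repeatedly
    until stable; e.g. "hypermethioninemia" -> "methionin".
    """
    sw = [w.casefold() for w in (stopwords or load_disease_stopwords())]
    out_tokens = []
    for tok in re.split(r"[^0-9a-zA-Z]+", name.casefold()):
        t = tok
        changed = True
        while changed and t:
            changed = False
            for w in sw:
                if t == w:
                    t = ""
                    changed = True
                    break
                if t.startswith(w) and len(t) > len(w):
                    t = t[len(w):]
                    changed = True
                    break
                if t.endswith(w) and len(t) > len(w):
                    t = t[:-len(w)]
                    changed = True
                    break
        if t:
            out_tokens.append(t)
    return " ".join(out_tokens)


def strip_go_substrings(term: str,
                        substrings: list[str] | None = None) -> str:
    """Remove generic substrings from a GO biological-process name."""
    out = term.casefold()
    for sub in (substrings or load_go_stop_substrings()):
        out = out.replace(sub.casefold(), " ")
    return " ".join(out.split())


def rank_nearest_genes(variant_chrom: str, variant_pos: int,
                       gene_table: pd.DataFrame,
                       n: int = N_CLOSEST_GENES) -> pd.DataFrame:
    """The ``n`` closest protein-coding genes to a variant, ascending distance.

    ``gene_table`` needs columns chrom, start, end, gene, protein_coding;
    distance to the gene body (start..end, 1-based closed) is 0 when the
    variant lies inside it.  Ties break by gene name; fewer than ``n`` genes
    on the chromosome returns all available.
    """
    sub = gene_table[(gene_table["chrom"].astype(str) == str(variant_chrom))
                     & gene_table["protein_coding"].astype(bool)].copy()
    inside = (sub["start"] <= variant_pos) & (variant_pos <= sub["end"])
    dist = pd.concat([(sub["start"] - variant_pos).abs(),
                      (sub["end"] - variant_pos).abs()], axis=1).min(axis=1)
    sub["distance"] = dist.where(~inside, 0).astype(int)
    sub = sub.sort_values(["distance", "gene"], kind="stable").head(n)
    sub["rank"] = range(1, len(sub) + 1)
    return sub.reset_index(drop=True)


@dataclass
class AnnotationResources:
    """Flat annotation tables; any table left None skips its channel.

    Schemas (all long-format DataFrames):
      metabolite_synonyms:   metabolite, synonym
      metabolite_classes:    metabolite, class_name
      gene_names:            gene, name
      protein_names:         gene, name
      gene_diseases:         gene, disease
      interacting_metabolites: gene, metabolite
      gene_pathways:         gene, map
      metabolite_pathways:   metabolite, map
      go_bp:                 gene, term, n_genes
    """

    metabolite_synonyms: pd.DataFrame | None = None
    metabolite_classes: pd.DataFrame | None = None
    gene_names: pd.DataFrame | None = None
    protein_names: pd.DataFrame | None = None
    gene_diseases: pd.DataFrame | None = None
    interacting_metabolites: pd.DataFrame | None = None
    gene_pathways: pd.DataFrame | None = None
    metabolite_pathways: pd.DataFrame | None = None
    go_bp: pd.DataFrame | None = None


@dataclass
class GeneEvidence:
    gim_id: str
    gene: str
    distance_rank: int
    hits: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    flagged_causal: str = "none"   # "single" | "multiple" | "none", set by review


def _synonyms(resources: AnnotationResources, metabolite: str) -> list[str]:
    syn = [metabolite]
    if resources.metabolite_synonyms is not None:
        tbl = resources.metabolite_synonyms
        syn += tbl.loc[tbl["metabolite"] == metabolite, "synonym"].tolist()
    return list(dict.fromkeys(syn))


def annotate_gim(gim,
                 gene_table: pd.DataFrame,
                 resources: AnnotationResources,
                 cutoff: float = FUZZY_CUTOFF,
                 go_max_genes: int = GO_MAX_GENES,
                 n_genes: int = N_CLOSEST_GENES) -> list[GeneEvidence]:
    """Evidence table for a GIM: candidate genes x seven evidence channels.

    Candidate genes are the ``n_genes`` protein-coding genes closest to the
    GIM's lead (lowest marker order) variant.  Fuzzy channels require a score
    strictly greater than ``cutoff``; the pathway channel requires only
    co-occurrence on a shared map; GO terms with >= ``go_max_genes`` member
    genes are excluded.  ``flagged_causal`` is left at "none" for downstream
    manual review.
    """
    from .regions import parse_vid

    lead = min(gim.variants, key=gim.variants.get)
    chrom, pos = parse_vid(lead)
    ranked = rank_nearest_genes(chrom, pos, gene_table, n=n_genes)
    stop_disease = load_disease_stopwords()
    stop_go = load_go_stop_substrings()

    out: list[GeneEvidence] = []
    for _, grow in ranked.iterrows():
        gene = str(grow["gene"])
        ev = GeneEvidence(gim_id=gim.id, gene=gene,
                          distance_rank=int(grow["rank"]))
        for met in gim.metabolites:
            syns = _synonyms(resources, met)

            def fuzzy_channel(source: str, targets: list[str],
                              queries: list[str] = syns) -> None:
                for q in queries:
                    for t in targets:
                        s = fuzzy_score(q, t)
                        if s > cutoff:
                            ev.hits.append((source, (q, t), s))

            if resources.gene_names is not None:
                tbl = resources.gene_names
                fuzzy_channel("gene_name",
                              tbl.loc[tbl["gene"] == gene, "name"].tolist())
            else:
                _warn_once("gene_names")
            if resources.protein_names is not None:
                tbl = resources.protein_names
                pnames = tbl.loc[tbl["gene"] == gene, "name"].tolist()
                fuzzy_channel("protein_name", pnames)
                if resources.metabolite_classes is not None:
                    ctbl = resources.metabolite_classes
                    classes = ctbl.loc[ctbl["metabolite"] == met,
                                       "class_name"].tolist()
                    fuzzy_channel("class_name", pnames, queries=classes)
            else:
                _warn_once("protein_names")
            if resources.gene_diseases is not None:
                tbl = resources.gene_diseases
                diseases = tbl.loc[tbl["gene"] == gene, "disease"].tolist()
                for q in syns:
                    for d in diseases:
                        residual = strip_disease_stopwords(d, stop_disease)
                        if not residual:
                            continue
                        s = fuzzy_score(q, residual)
                        if s > cutoff:
                            ev.hits.append(("disease_name", (q, d), s))
            else:
                _warn_once("gene_diseases")
            if resources.interacting_metabolites is not None:
                tbl = resources.interacting_metabolites
                hit = ((tbl["gene"] == gene) & (tbl["metabolite"] == met)).any()
                if hit:
                    ev.hits.append(("interacting_protein", (met, gene), 1.0))
            else:
                _warn_once("interacting_metabolites")
            if (resources.gene_pathways is not None
                    and resources.metabolite_pathways is not None):
                gmaps = set(resources.gene_pathways.loc[
                    resources.gene_pathways["gene"] == gene, "map"])
                mmaps = set(resources.metabolite_pathways.loc[
                    resources.metabolite_pathways["metabolite"] == met, "map"])
                for shared in sorted(gmaps & mmaps):
                    ev.hits.append(("pathway_map", (met, shared), 1.0))
            else:
                _warn_once("pathways")
            if resources.go_bp is not None:
                tbl = resources.go_bp
                terms = tbl.loc[(tbl["gene"] == gene)
                                & (tbl["n_genes"] < go_max_genes)]
                for q in syns:
                    for t in terms["term"]:
                        residual = strip_go_substrings(t, stop_go)
                        if not residual:
                            continue
                        s = fuzzy_score(q, residual)
                        if s > cutoff:
                            ev.hits.append(("go_bp", (q, t), s))
            else:
                _warn_once("go_bp")
        out.append(ev)
    return out


_warned: set[str] = set()


def _warn_once(channel: str) -> None:
    if channel not in _warned:
        _warned.add(channel)
        warnings.warn(f"annotation resource {channel!r} missing; channel skipped")


@dataclass
class EnrichmentResult:
    observed: int
    tested: int
    background_proportion: float
    fold_enrichment: float
    pval: float


def iem_enrichment(tested_genes: list[str] | set[str],
                   iem_gene_list: list[str] | set[str],
                   n_background: int = N_PROTEIN_CODING_GENES,
                   n_iem_background: int = N_IEM_GENES) -> EnrichmentResult:
    """Two-tailed binomial enrichment of IEM genes among the tested set.

    The background proportion is the fraction of known IEM genes among all
    protein-coding genes (785 / 19,817 ~= 4%); the two-tailed P sums the
    probabilities of all outcomes no more likely than the observed count.
    """
    tested = set(tested_genes)
    if not tested:
        raise ValueError("tested_genes must be non-empty")
    k = len(tested & set(iem_gene_list))
    n = len(tested)
    p0 = n_iem_background / n_background
    fold = (k / n) / p0
    pval = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    return EnrichmentResult(observed=k, tested=n, background_proportion=p0,
                            fold_enrichment=fold, pval=float(pval))
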