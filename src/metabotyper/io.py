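"""Flat-file input/output: TSV matrices, variant maps, truth JSON, GraphML."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .regions import Region, regions_to_bed
from .synthetic_data import CohortData, TruthTable

__all__ = [
    "write_cohort", "read_cohort",
    "write_truth", "read_truth",
    "write_matrix", "read_matrix",
    "write_regions_bed", "write_graphml",
]


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Dosage TSV + variant map + metabolite and covariate TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.dosages, out / "dosages.tsv")
    rows = []
    for vid in cohort.dosages.columns:
        chrom, pos, ref, alt = vid.split(":")
        freq = cohort.dosages[vid].mean() / 2.0
        rows.append({"variant": vid, "chrom": chrom, "pos": int(pos),
                     "ref": ref, "alt": alt, "maf": min(freq, 1 - freq)})
    pd.DataFrame(rows).to_csv(out / "variants.tsv", sep="\t", index=False)
    write_matrix(cohort.metabolites, out / "metabolites.tsv")
    write_matrix(cohort.covariates, out / "covariates.tsv")
    if cohort.phecodes is not None:
        write_matrix(cohort.phecodes, out / "phecodes.tsv")


def read_cohort(in_dir: str | Path, cohort_id: str) -> CohortData:
    d = Path(in_dir)
    phe = d / "phecodes.tsv"
    return CohortData(
        dosages=read_matrix(d / "dosages.tsv"),
        metabolites=read_matrix(d / "metabolites.tsv"),
        covariates=read_matrix(d / "covariates.tsv"),
        cohort_id=cohort_id,
        phecodes=read_matrix(phe) if phe.exists() else None,
    )


def write_truth(truth: TruthTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path: str | Path) -> TruthTable:
    return TruthTable.from_dict(json.loads(Path(path).read_text()))


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
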